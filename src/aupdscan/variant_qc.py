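"""Exome variant quality control, rare-variant filtering, and VAF-based
confirmation of aUPD regions.

QC rules are all inclusive (>=) thresholds; a variant passes only if every
rule is met, and each rejection is attributed to the first violated rule in
the fixed rule order. The variant allele frequency alt_depth/depth stands in
for array BAF when confirming aUPD regions, with the copy-number (LRR) gate
skipped because exome coverage carries no usable dosage signal.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .aupd_detection import DetectionParams, call_aupd, snp_qc_filter
from .errors import InsufficientDataError
from .types import GenomicInterval, Segment, SNPRecord, VariantRecord


@dataclass
class QcThresholds:
    """Inclusive lower bounds for each QC quantity, plus the rare-variant cap."""

    min_depth: int = 4
    min_alt_depth: int = 2
    min_qual: float = 20.0
    min_base_call_qual: float = 10.0
    min_strand_bias_p: float = 1e-4
    min_baseq_bias_p: float = 1e-100
    min_tail_bias_p: float = 1e-4
    min_hwe_p: float = 1e-4
    max_pop_af: float = 0.01


#: rule order used to attribute rejections (first violated rule wins)
QC_RULES: tuple[tuple[str, str, str], ...] = (
    ("depth", "depth", "min_depth"),
    ("alt_depth", "alt_depth", "min_alt_depth"),
    ("qual", "qual", "min_qual"),
    ("base_call_qual", "base_call_qual", "min_base_call_qual"),
    ("strand_bias_p", "strand_bias_p", "min_strand_bias_p"),
    ("baseq_bias_p", "baseq_bias_p", "min_baseq_bias_p"),
    ("tail_bias_p", "tail_bias_p", "min_tail_bias_p"),
    ("hwe_p", "hwe_p", "min_hwe_p"),
)


def qc_filter(
    variants: Sequence[VariantRecord], thresholds: Optional[QcThresholds] = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Apply every QC rule; return passing variants and per-rule rejection counts.

    The counts dict has one entry per rule plus ``"pass"`` and
    ``"missing_field"``; counts sum to the input size.
    """
    thresholds = thresholds or QcThresholds()
    counts = {rule: 0 for rule, _, _ in QC_RULES}
    counts["missing_field"] = 0
    counts["pass"] = 0
    passing: list[VariantRecord] = []
    for var in variants:
        failed = None
        for rule, attr, tattr in QC_RULES:
            value = getattr(var, attr, None)
            if value is None:
                failed = "missing_field"
                break
            if value < getattr(thresholds, tattr):
                failed = rule
                break
        if failed is None:
            counts["pass"] += 1
            passing.append(var)
        else:
            counts[failed] += 1
    return passing, counts


def rare_variant_filter(
    variants: Sequence[VariantRecord],
    region: GenomicInterval,
    thresholds: Optional[QcThresholds] = None,
) -> list[VariantRecord]:
    """Keep in-region variants that are novel or rare in population databases.

    The database allele frequency is folded to a minor allele frequency
    min(af, 1-af) before comparison with ``max_pop_af``; absent frequency
    means novel and is kept.
    """
    thresholds = thresholds or QcThresholds()
    out = []
    for var in variants:
        if var.chrom != region.chrom or not region.start <= var.pos <= region.end:
            continue
        if var.pop_af is None:
            out.append(var)
        elif min(var.pop_af, 1.0 - var.pop_af) <= thresholds.max_pop_af:
            out.append(var)
    return out


def vaf_confirm_aupd(
    variants: Sequence[VariantRecord],
    params: Optional[DetectionParams] = None,
) -> list[Segment]:
    """Confirm aUPD from variant allele frequencies used as BAF.

    The VAF series of one chromosome runs through the array pipeline
    unchanged (QC filter, mirroring, CBS, telomere classification) except
    that the copy-neutrality gate is disabled: exome VAF carries no reliable
    dosage signal, so segments are classified on allelic imbalance and
    telomere extension only.
    """
    params = params or DetectionParams()
    chroms = {v.chrom for v in variants}
    if len(chroms) != 1:
        raise InsufficientDataError("vaf_confirm_aupd expects a single chromosome")
    pseudo = [
        SNPRecord(
            snp_id=f"{v.chrom}:{v.pos}:{v.alt}",
            chrom=v.chrom,
            pos=v.pos,
            baf=v.vaf,
            lrr=0.0,
        )
        for v in sorted(variants, key=lambda v: v.pos)
    ]
    if len(pseudo) < 2 * params.cbs_min_width:
        raise InsufficientDataError(
            f"need at least {2 * params.cbs_min_width} variants"
        )
    retained = snp_qc_filter(pseudo, params)
    if not retained:
        return []
    # lrr is identically 0 on pseudo-records, so the neutrality gate is moot
    return call_aupd(retained, params, chrom_max_pos=pseudo[-1].pos)
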