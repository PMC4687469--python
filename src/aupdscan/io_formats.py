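"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 1-based inclusive (matching the published case
table); BED export converts to 0-based half-open. Floats are serialised with
6 decimal places so that write-then-read round-trips are byte-stable.

The packaged case table (``data/table1.tsv``) transcribes the published
summary of cases with chromosome 14 abnormalities; ``ND``, ``NA``, the
em-dash and empty cells all map to absent values.
"""
from __future__ import annotations

import csv
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .errors import DataValueError, FormatError
from .types import (
    CaseGroup,
    CaseRecord,
    GenomicInterval,
    MethylationPeaks,
    Segment,
    SNPRecord,
    VariantRecord,
)

PathLike = Union[str, Path]

_FLOAT_FMT = "{:.6f}"
_ABSENT = {"", "ND", "NA", "—", "-", "nd", "na"}

# coordinate strings appear with inconsistent whitespace and optional
# thousands separators, e.g. "chr14: 94,245,652-105,417,313"
_REGION_RE = re.compile(
    r"^chr\s*(?P<chrom>\w+)\s*:\s*(?P<start>[\d,]+)\s*-\s*(?P<end>[\d,]+)$"
)

SNP_COLUMNS = ("snp_id", "chrom", "pos", "baf", "lrr")
PEAK_COLUMNS = ("sample_id", "group", "m_height", "u_height")


def _absent(cell: str) -> bool:
    return cell.strip() in _ABSENT


def _parse_float(cell: str) -> Optional[float]:
    if _absent(cell):
        return None
    # the source table uses U+2212 for negative values
    return float(cell.strip().replace("−", "-"))


def parse_region(text: str, precise: bool = True) -> GenomicInterval:
    """Parse a coordinate string like ``chr14: 94245652-105417313``."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise FormatError(f"unparseable coordinate string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return GenomicInterval(m.group("chrom"), start, end, precise=precise)


# ---------------------------------------------------------------------------
# SNP profiles
# ---------------------------------------------------------------------------

def read_snp_profile(path: PathLike) -> dict[str, list[SNPRecord]]:
    """Read a tab-delimited SNP profile into records grouped by chromosome.

    Returns a dict mapping chromosome to records sorted by position.
    Raises :class:`FormatError` for missing columns and
    :class:`DataValueError` (with the line number) for out-of-range values.
    """
    by_chrom: dict[str, list[SNPRecord]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in SNP_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = SNPRecord(
                    snp_id=row["snp_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    baf=float(row["baf"]),
                    lrr=float(row["lrr"]),
                )
            except (TypeError, ValueError, DataValueError) as exc:
                raise DataValueError(f"{path} line {lineno}: {exc}") from exc
            by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.pos)
        seen = {r.pos for r in recs}
        if len(seen) != len(recs):
            raise DataValueError(f"{path}: duplicate positions on chrom {chrom}")
    return by_chrom


def write_snp_profile(records: Iterable[SNPRecord], path: PathLike) -> None:
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.pos}\t"
                f"{_FLOAT_FMT.format(r.baf)}\t{_FLOAT_FMT.format(r.lrr)}\n"
            )


# ---------------------------------------------------------------------------
# Case table
# ---------------------------------------------------------------------------

def _classify_case(region: str, has_interval: bool) -> CaseGroup:
    if has_interval:
        return CaseGroup.AUPD14Q
    if "+14" in region or "idic(14" in region:
        return CaseGroup.TRISOMY14
    return CaseGroup.OTHER


def read_case_table(path: Optional[PathLike] = None) -> list[CaseRecord]:
    """Read the case table; with no argument, the packaged fixture.

    One record per row. Coordinate strings become
    :class:`~aupdscan.types.GenomicInterval`; rows footnoted as
    megabase-resolution get ``precise=False``. Karyotype / microsatellite-only
    rows carry no interval.
    """
    if path is None:
        ref = resources.files("aupdscan.data").joinpath("table1.tsv")
        with resources.as_file(ref) as p:
            return read_case_table(p)

    cases: list[CaseRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"case_id", "region_or_karyotype", "disorder"}
        if not required <= set(reader.fieldnames or []):
            raise FormatError(f"{path}: case table must have columns {sorted(required)}")
        for row in reader:
            region = row["region_or_karyotype"].strip()
            footnote = row.get("size_footnote", "").strip()
            interval: Optional[GenomicInterval] = None
            karyotype: Optional[str] = None
            if region.lower().startswith("chr"):
                interval = parse_region(region, precise=(footnote != "b"))
            elif not _absent(region):
                karyotype = region
            drivers_cell = row.get("driver_mutations", "")
            drivers = (
                []
                if _absent(drivers_cell) or drivers_cell.strip().lower() == "none detected"
                else [d.strip() for d in drivers_cell.split(";") if d.strip()]
            )
            diagnosis = row["disorder"].strip()
            cases.append(
                CaseRecord(
                    case_id=row["case_id"].strip(),
                    diagnosis=diagnosis,
                    aupd_interval=interval,
                    karyotype=karyotype,
                    size_mb_printed=_parse_float(row.get("size_mb", "")),
                    mean_baf=_parse_float(row.get("mean_baf", "")),
                    methylation_value=_parse_float(row.get("methylation", "")),
                    drivers=drivers,
                    exome=row.get("exome", "").strip().lower() == "yes",
                    cohort="population" if diagnosis == "PC" else "clinical",
                    group=_classify_case(region, interval is not None),
                )
            )
    for c in cases:
        if c.aupd_interval is not None and c.aupd_interval.chrom != "14":
            raise FormatError(f"{c.case_id}: aUPD interval not on chromosome 14")
    return cases


# ---------------------------------------------------------------------------
# Methylation peaks
# ---------------------------------------------------------------------------

def read_methylation_peaks(path: PathLike) -> list[MethylationPeaks]:
    peaks: list[MethylationPeaks] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in PEAK_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                peaks.append(
                    MethylationPeaks(
                        sample_id=row["sample_id"],
                        group=row["group"],
                        m_height=float(row["m_height"]),
                        u_height=float(row["u_height"]),
                        batch=row.get("batch", "") or "",
                    )
                )
            except (TypeError, ValueError, DataValueError) as exc:
                raise DataValueError(f"{path} line {lineno}: {exc}") from exc
    return peaks


def write_methylation_peaks(peaks: Iterable[MethylationPeaks], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(PEAK_COLUMNS + ("batch",)) + "\n")
        for p in peaks:
            fh.write(
                f"{p.sample_id}\t{p.group}\t{_FLOAT_FMT.format(p.m_height)}\t"
                f"{_FLOAT_FMT.format(p.u_height)}\t{p.batch}\n"
            )


# ---------------------------------------------------------------------------
# VCF variants
# ---------------------------------------------------------------------------

#: default INFO keys carrying the bias / HWE p-values and the population
#: allele frequency; override any of them via ``info_keys``.
DEFAULT_INFO_KEYS = {
    "strand_bias_p": "SBP",
    "baseq_bias_p": "BQBP",
    "tail_bias_p": "TBP",
    "hwe_p": "HWEP",
    "base_call_qual": "BQ",
    "pop_af": "POP_AF",
}


def read_vcf_variants(
    path: PathLike, info_keys: Optional[dict[str, str]] = None
) -> list[VariantRecord]:
    """Read a VCF 4.x file into one record per ALT allele.

    Depth and allelic depth come from the first sample's FORMAT DP/AD (falling
    back to INFO DP/AD for sites-only files); the four bias/HWE p-values and
    the population allele frequency come from INFO fields whose keys default
    to :data:`DEFAULT_INFO_KEYS`. Multi-allelic sites are decomposed.
    """
    from cyvcf2 import VCF

    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)

    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"

        if var.format("DP") is not None:
            depth = int(var.format("DP")[0][0])
        elif var.INFO.get("DP") is not None:
            depth = int(var.INFO.get("DP"))
        else:
            raise FormatError(f"{where}: missing required tag DP")

        ad = var.format("AD")
        if ad is not None:
            alt_depths = [int(x) for x in ad[0][1:]]
        elif var.INFO.get("AD") is not None:
            info_ad = var.INFO.get("AD")
            if isinstance(info_ad, (tuple, list)):
                alt_depths = [int(x) for x in info_ad[1:]]
            else:
                alt_depths = [int(info_ad)]
        else:
            raise FormatError(f"{where}: missing required tag AD")
        if len(alt_depths) < len(var.ALT):
            raise FormatError(f"{where}: AD has fewer values than ALT alleles")

        def info_p(field: str) -> float:
            val = var.INFO.get(keys[field])
            if val is None:
                raise FormatError(f"{where}: missing required tag {keys[field]}")
            return float(val)

        pop_af_raw = var.INFO.get(keys["pop_af"])
        pop_afs: list[Optional[float]]
        if pop_af_raw is None:
            pop_afs = [None] * len(var.ALT)
        elif isinstance(pop_af_raw, (tuple, list)):
            pop_afs = [float(x) for x in pop_af_raw]
        else:
            pop_afs = [float(pop_af_raw)] * len(var.ALT)

        for alt, alt_depth, pop_af in zip(var.ALT, alt_depths, pop_afs):
            out.append(
                VariantRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref=var.REF,
                    alt=alt,
                    depth=depth,
                    alt_depth=alt_depth,
                    qual=float(var.QUAL if var.QUAL is not None else 0.0),
                    base_call_qual=info_p("base_call_qual"),
                    strand_bias_p=info_p("strand_bias_p"),
                    baseq_bias_p=info_p("baseq_bias_p"),
                    tail_bias_p=info_p("tail_bias_p"),
                    hwe_p=info_p("hwe_p"),
                    pop_af=pop_af,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Segments / BED
# ---------------------------------------------------------------------------

def write_segments_bed(segments: Iterable[Segment], path: PathLike) -> None:
    """Write segments as BED (0-based half-open); score = mean mirrored BAF."""
    with open(path, "w", newline="") as fh:
        for s in segments:
            name = "aUPD" if s.is_aupd else "neutral"
            fh.write(
                f"{s.chrom}\t{s.start_pos - 1}\t{s.end_pos}\t{name}\t"
                f"{_FLOAT_FMT.format(s.mean_mbaf)}\n"
            )


def read_segments_bed(path: PathLike) -> list[tuple[str, int, int, str, float]]:
    """Read a BED file back into 1-based inclusive tuples (for round-trips)."""
    rows = []
    with open(path, newline="") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            rows.append(
                (fields[0], int(fields[1]) + 1, int(fields[2]), fields[3], float(fields[4]))
            )
    return rows


def write_segments_report(segments: Iterable[Segment], path: PathLike) -> None:
    cols = (
        "chrom start end n_snps mean_mbaf mean_lrr telomeric is_aupd clone_fraction"
    ).split()
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start_pos}\t{s.end_pos}\t{s.n_snps}\t"
                f"{_FLOAT_FMT.format(s.mean_mbaf)}\t{_FLOAT_FMT.format(s.mean_lrr)}\t"
                f"{int(s.telomeric)}\t{int(s.is_aupd)}\t"
                f"{_FLOAT_FMT.format(s.clone_fraction)}\n"
            )
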