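"""Synthetic SNP profiles, MS-PCR peaks and JAK2 burdens with known truth.

The generator emulates exactly the mixture structure the detection chain
assumes: a mosaic terminal event carried by a cell fraction f displaces
heterozygous-SNP BAF to 0.5 +/- f/2 (aUPD, copy-neutral) or to the allele
dosage bands (1 + f*dup)/(2 + f) with an LRR shift of log2((2+f)/2)
(trisomy). MS-PCR peak heights follow the allele doses at the imprinted
locus — paternal aUPD gives methylated:unmethylated = (1+f):(1-f) — and the
V617F burden composes homozygous and heterozygous compartments as
v = f_hom + f_het/2.

Noise defaults (BAF sd 0.03, LRR sd 0.15, peak CV 0.05) are typical array /
fragment-analysis spreads; see the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataValueError
from .io_formats import write_methylation_peaks, write_snp_profile
from .types import GenomicInterval, MethylationPeaks, SNPRecord

AUPD_KINDS = {"aupd_paternal", "aupd_maternal"}
TRISOMY_KINDS = {"trisomy_paternal", "trisomy_maternal"}


@dataclass(frozen=True)
class Event:
    interval: GenomicInterval
    kind: str  # aupd_paternal | aupd_maternal | trisomy_paternal | trisomy_maternal
    clone_fraction: float

    def __post_init__(self) -> None:
        if self.kind not in AUPD_KINDS | TRISOMY_KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")
        if not 0.0 <= self.clone_fraction <= 1.0:
            raise DataValueError(f"clone fraction {self.clone_fraction} outside [0, 1]")


@dataclass
class SimSpec:
    """Parameters of one simulated genome."""

    n_snps: int = 2000
    het_rate: float = 0.3
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"14": 107_349_540})
    events: list[Event] = field(default_factory=list)
    baf_noise_sd: float = 0.03
    lrr_noise_sd: float = 0.15
    hom_baf_sd: float = 0.01
    peak_scale: float = 1000.0
    peak_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Event]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.interval.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            if chrom not in self.chrom_lengths:
                raise ConfigError(f"event on chrom {chrom} absent from chrom_lengths")
            evs = sorted(evs, key=lambda e: e.interval.start)
            for a, b in zip(evs, evs[1:]):
                if a.interval.end >= b.interval.start:
                    raise ConfigError(f"overlapping events on chrom {chrom}")


def _event_at(events: Sequence[Event], pos: int) -> Optional[Event]:
    for ev in events:
        if ev.interval.start <= pos <= ev.interval.end:
            return ev
    return None


def simulate_snp_profile(spec: SimSpec) -> dict[str, list[SNPRecord]]:
    """Draw one SNP-array profile under the mixture model.

    Germline genotype per SNP: heterozygous with probability ``het_rate``,
    otherwise AA/BB equiprobably. For het SNPs inside an aUPD event at clone
    fraction f, the duplicated haplotype's sign is drawn per SNP (mirroring
    makes it irrelevant downstream) and BAF is 0.5 + s*f/2 plus noise; LRR
    stays centred at 0. Trisomy shifts LRR by log2((2+f)/2) and places het
    BAF at the dosage bands. All BAFs are truncated to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    profile: dict[str, list[SNPRecord]] = {}
    for chrom in sorted(spec.chrom_lengths):
        length = spec.chrom_lengths[chrom]
        events = [e for e in spec.events if e.interval.chrom == chrom]
        pos = np.sort(rng.choice(length, size=spec.n_snps, replace=False)) + 1
        het = rng.random(spec.n_snps) < spec.het_rate
        hom_b = rng.random(spec.n_snps) < 0.5  # BB vs AA for hom SNPs
        sign = np.where(rng.random(spec.n_snps) < 0.5, 1.0, -1.0)
        baf_noise = rng.normal(0.0, spec.baf_noise_sd, spec.n_snps)
        hom_noise = np.abs(rng.normal(0.0, spec.hom_baf_sd, spec.n_snps))
        lrr = rng.normal(0.0, spec.lrr_noise_sd, spec.n_snps)

        records: list[SNPRecord] = []
        for k in range(spec.n_snps):
            p = int(pos[k])
            ev = _event_at(events, p)
            if het[k]:
                if ev is None or ev.clone_fraction == 0.0:
                    baf = 0.5 + baf_noise[k]
                elif ev.kind in AUPD_KINDS:
                    baf = 0.5 + sign[k] * ev.clone_fraction / 2.0 + baf_noise[k]
                else:  # trisomy: B-allele dose (1 + f*dup_b) of (2 + f) copies
                    f = ev.clone_fraction
                    dup_b = sign[k] > 0
                    baf = (1.0 + (f if dup_b else 0.0)) / (2.0 + f) + baf_noise[k]
            else:
                baf = hom_noise[k] if not hom_b[k] else 1.0 - hom_noise[k]
            baf = min(max(baf, 0.0), 1.0)
            this_lrr = lrr[k]
            if ev is not None and ev.kind in TRISOMY_KINDS:
                this_lrr += np.log2((2.0 + ev.clone_fraction) / 2.0)
            records.append(
                SNPRecord(
                    snp_id=f"snp_{chrom}_{k}",
                    chrom=chrom,
                    pos=p,
                    baf=float(baf),
                    lrr=float(this_lrr),
                )
            )
        profile[chrom] = records
    return profile


def methylation_doses(f: float, kind: str) -> tuple[float, float]:
    """Noiseless (methylated, unmethylated) allele doses for an event at fraction f.

    Balanced diploid contributes one methylated (paternal) and one
    unmethylated (maternal) allele. Paternal aUPD in a fraction f of cells
    gives doses (1+f, 1-f); maternal aUPD the reverse; a paternal extra copy
    (trisomy) gives (1+f, 1); maternal trisomy (1, 1+f).
    """
    if not 0.0 <= f <= 1.0:
        raise DataValueError(f"clone fraction {f} outside [0, 1]")
    if kind == "aupd_paternal":
        return 1.0 + f, 1.0 - f
    if kind == "aupd_maternal":
        return 1.0 - f, 1.0 + f
    if kind == "trisomy_paternal":
        return 1.0 + f, 1.0
    if kind == "trisomy_maternal":
        return 1.0, 1.0 + f
    raise ConfigError(f"unknown event kind {kind!r}")


def simulate_methylation_peaks(
    f: float,
    kind: str = "aupd_paternal",
    scale: float = 1000.0,
    cv: float = 0.05,
    seed: int = 0,
    sample_id: str = "sim",
    group: str = "aupd14q",
) -> MethylationPeaks:
    """MS-PCR peak heights: dose * scale * (1 + Normal(0, cv)), floored at 0."""
    rng = np.random.default_rng(seed)
    m_dose, u_dose = methylation_doses(f, kind)
    m = m_dose * scale * max(0.0, 1.0 + rng.normal(0.0, cv)) if cv > 0 else m_dose * scale
    u = u_dose * scale * max(0.0, 1.0 + rng.normal(0.0, cv)) if cv > 0 else u_dose * scale
    return MethylationPeaks(sample_id=sample_id, group=group, m_height=m, u_height=u)


def simulate_jak2_case(
    f14: float,
    f9_hom: float,
    f_het: float,
    error_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """V617F burden plus chromosome 9p/14q mirrored BAFs for one case.

    Allele conservation: v = f9_hom + f_het/2. Mirrored BAFs follow the
    mixture identity 0.5 + f/2. Gaussian measurement error ``error_sd`` is
    added to each quantity, truncated to its valid range.
    """
    for name, val in (("f14", f14), ("f9_hom", f9_hom), ("f_het", f_het)):
        if not 0.0 <= val <= 1.0:
            raise DataValueError(f"{name} = {val} outside [0, 1]")
    if f9_hom + f_het > 1.0:
        raise DataValueError(f"f9_hom + f_het = {f9_hom + f_het} exceeds 1")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, error_sd, 3) if error_sd > 0 else np.zeros(3)
    v = min(max(f9_hom + f_het / 2.0 + noise[0], 0.0), 1.0)
    baf14 = min(max(0.5 + f14 / 2.0 + noise[1], 0.5), 1.0)
    baf9 = min(max(0.5 + f9_hom / 2.0 + noise[2], 0.5), 1.0)
    return {"v617f_burden": v, "baf14": baf14, "baf9": baf9}


def simulate_cohort(
    n_cases: int,
    template: SimSpec,
    seed: int = 0,
    out_dir: Optional[Path] = None,
) -> list[dict]:
    """Simulate ``n_cases`` genomes from a template spec with per-case seeds.

    Each case reuses the template's events and noise but an independent
    sub-seed drawn from ``seed``. With ``out_dir``, profiles and peak tables
    are written in the package's TSV dialects plus a truth table. Returns
    per-case dicts with the spec, profile, peaks, and truth values.
    """
    if n_cases < 1:
        raise ConfigError("n_cases must be >= 1")
    root = np.random.SeedSequence(seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_cases)]
    cohort: list[dict] = []
    for idx, sub in enumerate(sub_seeds):
        case_id = f"SIM{idx:03d}"
        spec = SimSpec(
            n_snps=template.n_snps,
            het_rate=template.het_rate,
            chrom_lengths=dict(template.chrom_lengths),
            events=list(template.events),
            baf_noise_sd=template.baf_noise_sd,
            lrr_noise_sd=template.lrr_noise_sd,
            hom_baf_sd=template.hom_baf_sd,
            peak_scale=template.peak_scale,
            peak_noise_cv=template.peak_noise_cv,
            seed=sub,
        )
        profile = simulate_snp_profile(spec)
        f = spec.events[0].clone_fraction if spec.events else 0.0
        kind = spec.events[0].kind if spec.events else "aupd_paternal"
        peaks = simulate_methylation_peaks(
            f,
            kind=kind,
            scale=spec.peak_scale,
            cv=spec.peak_noise_cv,
            seed=sub + 1,
            sample_id=case_id,
            group="aupd14q" if spec.events else "control",
        )
        cohort.append(
            {
                "case_id": case_id,
                "seed": sub,
                "spec": spec,
                "profile": profile,
                "peaks": peaks,
                "truth_f": f,
                "truth_kind": kind if spec.events else None,
            }
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for case in cohort:
            all_records = [
                r for recs in case["profile"].values() for r in recs
            ]
            write_snp_profile(all_records, out_dir / f"{case['case_id']}.snp.tsv")
        write_methylation_peaks(
            [c["peaks"] for c in cohort], out_dir / "peaks.tsv"
        )
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("case_id\tseed\tclone_fraction\tkind\n")
            for c in cohort:
                fh.write(
                    f"{c['case_id']}\t{c['seed']}\t{c['truth_f']:.6f}\t"
                    f"{c['truth_kind'] or ''}\n"
                )
    return cohort
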