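"""Core domain types.

Coordinates are 1-based inclusive throughout the package; the BED writer is
the only place where conversion to 0-based half-open happens.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .errors import DataValueError


@dataclass(frozen=True)
class SNPRecord:
    """One array probe: B-allele frequency and log R ratio at a genomic position."""

    snp_id: str
    chrom: str
    pos: int
    baf: float
    lrr: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataValueError(f"{self.snp_id}: position {self.pos} must be >= 1")
        if not 0.0 <= self.baf <= 1.0:
            raise DataValueError(f"{self.snp_id}: BAF {self.baf} outside [0, 1]")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval.

    ``precise`` is False for intervals whose boundaries are only known to the
    nearest megabase; such intervals are excluded from minimal-region
    intersection by default.
    """

    chrom: str
    start: int
    end: int
    precise: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DataValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start > end"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"chr{self.chrom}:{self.start}-{self.end}"


class CaseGroup(str, Enum):
    AUPD14Q = "aupd14q"
    TRISOMY14 = "trisomy14"
    CONTROL = "control"
    SCREEN = "screen"
    OTHER = "other"


@dataclass
class CaseRecord:
    """One row of the packaged case table.

    Absent numeric fields are ``None`` (mapped from ND / NA / em-dash in the
    source), never zero-filled.
    """

    case_id: str
    diagnosis: str
    aupd_interval: Optional[GenomicInterval] = None
    karyotype: Optional[str] = None
    size_mb_printed: Optional[float] = None
    mean_baf: Optional[float] = None
    methylation_value: Optional[float] = None
    drivers: list[str] = field(default_factory=list)
    exome: bool = False
    cohort: str = "clinical"
    group: CaseGroup = CaseGroup.OTHER


@dataclass(frozen=True)
class MethylationPeaks:
    """Methylated / unmethylated MS-PCR peak heights for one sample."""

    sample_id: str
    group: str
    m_height: float
    u_height: float
    batch: str = ""

    def __post_init__(self) -> None:
        if self.m_height < 0 or self.u_height < 0:
            raise DataValueError(f"{self.sample_id}: negative peak height")


@dataclass(frozen=True)
class VariantRecord:
    """One ALT allele of a sequenced variant with QC annotations.

    ``pop_af`` of ``None`` means the variant is absent from population
    databases, i.e. novel.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_depth: int
    qual: float
    base_call_qual: float
    strand_bias_p: float
    baseq_bias_p: float
    tail_bias_p: float
    hwe_p: float
    pop_af: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.depth:
            raise DataValueError(
                f"{self.chrom}:{self.pos} alt depth {self.alt_depth} outside "
                f"[0, {self.depth}]"
            )

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise DataValueError(f"{self.chrom}:{self.pos} has zero depth")
        return self.alt_depth / self.depth


@dataclass
class Segment:
    """A contiguous run of retained SNPs with its mirrored-BAF summary."""

    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    mean_mbaf: float
    mean_lrr: float
    telomeric: bool = False
    is_aupd: bool = False

    @property
    def clone_fraction(self) -> float:
        return 2.0 * (self.mean_mbaf - 0.5)


class OrderCall(str, Enum):
    AUPD14_FIRST = "AUPD14_FIRST"
    JAK2_FIRST = "JAK2_FIRST"
    UNCERTAIN = "UNCERTAIN"


@dataclass
class ClonalEstimate:
    """Cell-fraction decomposition for a case with aUPD14q and JAK2 V617F."""

    case_id: str
    f14: float
    f9_hom: float
    f_het: float
    order_call: OrderCall

    @property
    def jak2_total(self) -> float:
        return self.f9_hom + self.f_het
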