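"""Interval arithmetic over per-case aUPD calls.

The minimal affected region (MAR) is the intersection of the per-case aUPD
intervals — [max(starts), min(ends)] for intervals on one chromosome.
Intervals whose boundaries are only resolved to the nearest megabase are
excluded by default ("conservative" MAR) but still counted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .errors import DataValueError, InsufficientDataError
from .types import CaseRecord, GenomicInterval


def _round_half_up(value: float, digits: int = 1) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def interval_size_mb(interval: GenomicInterval) -> float:
    """Interval length in megabases, (end - start + 1)/1e6, half-up to 1 dp."""
    return _round_half_up(interval.length_bp / 1e6)


def prevalence(numerator: int, denominator: int) -> float:
    """Percentage at 1 decimal place, rounded half-up."""
    if denominator <= 0:
        raise DataValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise DataValueError("numerator must lie in [0, denominator]")
    return _round_half_up(100.0 * numerator / denominator)


@dataclass
class RegionSummary:
    mar: Optional[GenomicInterval]
    mar_size_mb: Optional[float]
    n_cases_used: int
    n_cases_excluded_imprecise: int
    contributing_case_ids: list[str] = field(default_factory=list)
    empty_intersection: bool = False


def count_aupd_cases(cases: Sequence[CaseRecord]) -> int:
    """Number of cases with a chromosome-14 aUPD interval.

    Trisomy, karyotype-only and microsatellite-only rows do not count.
    """
    return sum(1 for c in cases if c.aupd_interval is not None)


def minimal_affected_region(
    cases: Sequence[CaseRecord], require_precise: bool = True
) -> RegionSummary:
    """Intersect per-case aUPD intervals into the minimal affected region.

    With ``require_precise`` (default), megabase-resolution intervals are
    excluded from the intersection and counted separately. An empty
    intersection is reported explicitly, not raised.
    """
    with_interval = [c for c in cases if c.aupd_interval is not None]
    if not with_interval:
        raise InsufficientDataError("no case carries an aUPD interval")
    chroms = {c.aupd_interval.chrom for c in with_interval}
    if len(chroms) != 1:
        raise DataValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    if require_precise:
        used = [c for c in with_interval if c.aupd_interval.precise]
        excluded = len(with_interval) - len(used)
    else:
        used = with_interval
        excluded = 0
    if not used:
        raise InsufficientDataError("no usable (precise) intervals")

    start = max(c.aupd_interval.start for c in used)
    end = min(c.aupd_interval.end for c in used)
    ids = [c.case_id for c in used]
    if start > end:
        return RegionSummary(
            mar=None,
            mar_size_mb=None,
            n_cases_used=len(used),
            n_cases_excluded_imprecise=excluded,
            contributing_case_ids=ids,
            empty_intersection=True,
        )
    mar = GenomicInterval(chrom, start, end, precise=True)
    for c in used:  # containment audit
        assert c.aupd_interval.contains(mar)
    return RegionSummary(
        mar=mar,
        mar_size_mb=interval_size_mb(mar),
        n_cases_used=len(used),
        n_cases_excluded_imprecise=excluded,
        contributing_case_ids=ids,
    )
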