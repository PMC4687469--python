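"""Terminal copy-neutral aUPD calling from a SNP-array profile.

The chain is: QC filter (drop homozygous-range SNPs and SNPs whose flanking
neighbours differ too much) -> mirror BAF about 0.5 -> circular binary
segmentation (CBS) of the mirrored series -> classify each segment as aUPD if
its mean mirrored BAF exceeds the threshold, its mean log R ratio is
copy-neutral, and it extends to the last probe of the chromosome.

In a mosaic sample where a fraction f of cells carry the event, heterozygous
SNPs sit at BAF 0.5 +/- f/2, so the segmented mirrored BAF is
0.5 + f/2 and the clone fraction is recovered as f = 2*(mBAF - 0.5).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataValueError
from .types import Segment, SNPRecord


@dataclass
class DetectionParams:
    """Thresholds and CBS settings for aUPD calling.

    ``mbaf_threshold`` (0.56, strict inequality) is the allelic-imbalance
    cutoff; at noiseless mixture level it corresponds to a clone fraction of
    0.12. ``lrr_neutral_tol`` operationalises "log R ratio ~ 0";
    ``telomere_tol_bp`` operationalises "extends to the telomere" as reaching
    within that distance of the last probe on the chromosome.
    """

    baf_hom_low: float = 0.1
    baf_hom_high: float = 0.9
    neighbor_diff_max: float = 0.6
    mbaf_threshold: float = 0.56
    lrr_neutral_tol: float = 0.15
    telomere_tol_bp: int = 1_000_000
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_min_width: int = 5
    cbs_seed: int = 1729

    def __post_init__(self) -> None:
        if not 0.5 < self.mbaf_threshold < 1.0:
            raise DataValueError("mbaf_threshold must lie in (0.5, 1)")
        for name in ("lrr_neutral_tol", "telomere_tol_bp", "cbs_alpha"):
            if getattr(self, name) <= 0:
                raise DataValueError(f"{name} must be positive")


def mirror_baf(baf):
    """Fold BAF about 0.5: returns 0.5 + |baf - 0.5|, in [0.5, 1]."""
    arr = np.asarray(baf, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise DataValueError("BAF outside [0, 1]")
    out = 0.5 + np.abs(arr - 0.5)
    return float(out) if np.isscalar(baf) else out


def estimate_clone_fraction(mean_mbaf: float) -> float:
    """Invert the mixture identity mBAF = f*1 + (1-f)*0.5."""
    if not 0.5 <= mean_mbaf <= 1.0:
        raise DataValueError(f"mean mirrored BAF {mean_mbaf} outside [0.5, 1]")
    return 2.0 * (mean_mbaf - 0.5)


def snp_qc_filter(
    records: Sequence[SNPRecord], params: Optional[DetectionParams] = None
) -> list[SNPRecord]:
    """Drop non-informative SNPs from one chromosome's position-sorted records.

    Two rules, both evaluated on the original sorted series: (i) SNPs with
    BAF above ``baf_hom_high`` or below ``baf_hom_low`` (homozygous range);
    (ii) interior SNPs whose flanking neighbours' BAFs differ by more than
    ``neighbor_diff_max``. The first and last SNP are exempt from (ii).
    """
    params = params or DetectionParams()
    positions = [r.pos for r in records]
    if positions != sorted(positions):
        raise DataValueError("records must be sorted by position")
    baf = np.array([r.baf for r in records])
    n = len(records)
    drop = (baf > params.baf_hom_high) | (baf < params.baf_hom_low)
    if n >= 3:
        neighbor = np.abs(baf[2:] - baf[:-2]) > params.neighbor_diff_max
        drop[1:-1] |= neighbor
    return [r for r, d in zip(records, drop) if not d]


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

class _ArcStat:
    """Max-|T| arc statistic with index arrays precomputed for one length.

    An arc (i, j), 0 <= i < j <= n, is the block ``values[i:j]``; its
    complement wraps around, so linear blocks enumerate every circular
    two-way partition. T compares arc mean with complement mean, scaled by
    the whole-series standard deviation. Arc and complement must each hold
    at least ``min_width`` points. Ties go to the smallest (i, then j).
    """

    def __init__(self, n: int, min_width: int) -> None:
        if n < 2 * min_width:
            raise DataValueError(f"need at least {2 * min_width} values")
        self.n = n
        span = np.arange(n + 1)
        width = span[None, :] - span[:, None]
        mask = (width >= min_width) & (width <= n - min_width)
        self.i_idx, self.j_idx = np.nonzero(mask)  # row-major: ordered by (i, j)
        m = (self.j_idx - self.i_idx).astype(float)
        self._inv_m = 1.0 / m
        self._inv_c = 1.0 / (n - m)
        self._inv_se = 1.0 / np.sqrt(self._inv_m + self._inv_c)

    def __call__(self, x: np.ndarray) -> tuple[float, int, int]:
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            return 0.0, 0, int(self.j_idx[0])
        prefix = np.concatenate(([0.0], np.cumsum(x)))
        arc_sum = prefix[self.j_idx] - prefix[self.i_idx]
        t = np.abs(
            arc_sum * self._inv_m - (prefix[self.n] - arc_sum) * self._inv_c
        ) * (self._inv_se / sd)
        best = int(np.argmax(t))  # first occurrence = smallest (i, j)
        return float(t[best]), int(self.i_idx[best]), int(self.j_idx[best])


def cbs_max_stat(values: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max |T| over all circular arcs of the series; returns (|T|, i, j)."""
    x = np.asarray(values, dtype=float)
    return _ArcStat(len(x), min_width)(x)


def _perm_significant(
    x: np.ndarray,
    observed: float,
    stat_fn: _ArcStat,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test for the max-|T| statistic with early stopping.

    Declares non-significance as soon as the exceedance count can no longer
    yield p <= alpha; otherwise runs all ``n_perm`` shuffles.
    """
    max_exceed = int(np.floor(alpha * n_perm))
    exceed = 0
    work = x.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if stat_fn(work)[0] >= observed:
            exceed += 1
            if exceed > max_exceed:
                return False
    return True


def cbs_segment(
    values: Sequence[float], params: Optional[DetectionParams] = None
) -> list[int]:
    """Recursive CBS change-point detection on an ordered series.

    Returns the sorted interior change-point indices; segment k runs over
    ``values[cp[k]:cp[k+1]]`` with implicit boundaries 0 and n. A series
    shorter than twice the minimum width is returned unsplit.
    """
    params = params or DetectionParams()
    x = np.asarray(values, dtype=float)
    rng = np.random.default_rng(params.cbs_seed)
    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * params.cbs_min_width:
            return
        stat_fn = _ArcStat(n, params.cbs_min_width)
        stat, i, j = stat_fn(seg)
        if stat == 0.0:
            return
        if not _perm_significant(
            seg, stat, stat_fn, params.cbs_alpha, params.cbs_n_perm, rng
        ):
            return
        cuts = [c for c in (i, j) if 0 < c < n]
        for c in cuts:
            breakpoints.append(lo + c)
        for a, b in zip([lo] + [lo + c for c in cuts], [lo + c for c in cuts] + [hi]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(set(breakpoints))


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _band_location(mbaf: np.ndarray, ceiling: float) -> float:
    """Estimate the mirrored-BAF band centre, correcting exclusion truncation.

    The homozygous-SNP exclusion removes every probe with BAF beyond its
    bounds, so when a clone's band 0.5 + f/2 approaches the mirrored ceiling
    (0.9 at default bounds) the retained values are draws from a normal
    truncated above, and their mean understates the band. When the sample
    mean is within 3 sample-sd of the ceiling, the band centre is
    re-estimated by truncated-normal maximum likelihood; otherwise the plain
    mean is returned.
    """
    from scipy import optimize, stats as sps

    mean = float(np.mean(mbaf))
    sd = float(np.std(mbaf, ddof=1)) if len(mbaf) > 1 else 0.0
    if sd == 0.0 or mean < ceiling - 3.0 * sd:
        return mean

    x = np.asarray(mbaf, dtype=float)

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        z = (x - mu) / sigma
        log_norm = sps.norm.logcdf((ceiling - mu) / sigma)
        return float(-np.sum(sps.norm.logpdf(z) - log_sigma - log_norm))

    res = optimize.minimize(
        nll, x0=np.array([mean, np.log(max(sd, 1e-4))]), method="Nelder-Mead"
    )
    mu = float(res.x[0])
    # fall back to the plain mean if the fit wandered off
    if not np.isfinite(mu) or not 0.5 <= mu <= 1.1:
        return mean
    return min(mu, 1.0)


@dataclass
class AupdCall:
    """A merged terminal aUPD region (possibly spanning several segments)."""

    chrom: str
    start_pos: int
    end_pos: int
    n_snps: int
    mean_mbaf: float
    mean_lrr: float
    clone_fraction: float


def call_aupd(
    records: Sequence[SNPRecord],
    params: Optional[DetectionParams] = None,
    chrom_max_pos: Optional[int] = None,
) -> list[Segment]:
    """Segment one chromosome's QC-filtered records and classify aUPD.

    ``chrom_max_pos`` is the last probe position on the chromosome before QC
    (defaults to the last retained probe). A segment is aUPD when its mean
    mirrored BAF strictly exceeds the threshold, its mean LRR is within the
    copy-neutral tolerance, and it is telomeric: it contains the last
    retained SNP and ends within ``telomere_tol_bp`` of ``chrom_max_pos``.
    """
    params = params or DetectionParams()
    if not records:
        return []
    chroms = {r.chrom for r in records}
    if len(chroms) != 1:
        raise DataValueError("call_aupd operates on a single chromosome")
    chrom = chroms.pop()
    if chrom_max_pos is None:
        chrom_max_pos = records[-1].pos

    mbaf = mirror_baf([r.baf for r in records])
    lrr = np.array([r.lrr for r in records])
    pos = np.array([r.pos for r in records])
    n = len(records)

    cps = cbs_segment(mbaf, params) if n >= 2 * params.cbs_min_width else []
    bounds = [0] + cps + [n]
    segments: list[Segment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = Segment(
            chrom=chrom,
            start_pos=int(pos[a]),
            end_pos=int(pos[b - 1]),
            n_snps=b - a,
            mean_mbaf=float(np.mean(mbaf[a:b])),
            mean_lrr=float(np.mean(lrr[a:b])),
        )
        # the terminal gap must be consistent with the segment's own probe
        # spacing: at low retained density (e.g. inside a near-complete aUPD
        # region, where QC removes most probes) the last retained probe can
        # legitimately sit several median spacings from the chromosome end
        spacing = (seg.end_pos - seg.start_pos) / max(seg.n_snps - 1, 1)
        gap_tol = max(params.telomere_tol_bp, 10.0 * spacing)
        seg.telomeric = (b == n) and (seg.end_pos >= chrom_max_pos - gap_tol)
        seg.is_aupd = (
            seg.mean_mbaf > params.mbaf_threshold
            and abs(seg.mean_lrr) <= params.lrr_neutral_tol
            and seg.telomeric
        )
        segments.append(seg)
    return segments


def merge_terminal_call(
    records: Sequence[SNPRecord],
    segments: Sequence[Segment],
    params: Optional[DetectionParams] = None,
) -> Optional[AupdCall]:
    """Build one aUPD call from the segments of a chromosome.

    The published definition is a region of allelic imbalance with neutral
    copy number extending to the telomere; if CBS subdivides that region,
    the call is the union of the terminal aUPD segment and every adjacent
    proximal segment that also meets the imbalance and copy-neutrality
    criteria. The clone fraction is 2*(band - 0.5) with the band centre
    estimated over the merged region (truncation-corrected near the
    homozygote exclusion bound). Returns None when no terminal segment
    qualifies.
    """
    params = params or DetectionParams()
    if not segments or not segments[-1].is_aupd:
        return None
    first = len(segments) - 1
    while first > 0:
        prev = segments[first - 1]
        if (
            prev.mean_mbaf > params.mbaf_threshold
            and abs(prev.mean_lrr) <= params.lrr_neutral_tol
        ):
            first -= 1
        else:
            break
    merged = segments[first:]
    start, end = merged[0].start_pos, merged[-1].end_pos
    in_call = [r for r in records if start <= r.pos <= end]
    mbaf = mirror_baf([r.baf for r in in_call])
    ceiling = 0.5 + min(params.baf_hom_high - 0.5, 0.5 - params.baf_hom_low)
    band = _band_location(np.asarray(mbaf), ceiling)
    return AupdCall(
        chrom=merged[0].chrom,
        start_pos=start,
        end_pos=end,
        n_snps=len(in_call),
        mean_mbaf=float(np.mean(mbaf)),
        mean_lrr=float(np.mean([r.lrr for r in in_call])),
        clone_fraction=min(max(2.0 * (band - 0.5), 0.0), 1.0),
    )


def detect_profile(
    profile: dict[str, list[SNPRecord]], params: Optional[DetectionParams] = None
) -> list[Segment]:
    """Run QC + mirroring + CBS + calling on every chromosome of a profile."""
    params = params or DetectionParams()
    out: list[Segment] = []
    for chrom in sorted(profile):
        records = profile[chrom]
        if not records:
            continue
        retained = snp_qc_filter(records, params)
        if not retained:
            continue
        out.extend(call_aupd(retained, params, chrom_max_pos=records[-1].pos))
    return out


def detect_calls(
    profile: dict[str, list[SNPRecord]], params: Optional[DetectionParams] = None
) -> list[AupdCall]:
    """Full pipeline to merged terminal aUPD calls, one at most per chromosome."""
    params = params or DetectionParams()
    calls: list[AupdCall] = []
    for chrom in sorted(profile):
        records = profile[chrom]
        if not records:
            continue
        retained = snp_qc_filter(records, params)
        if not retained:
            continue
        segments = call_aupd(retained, params, chrom_max_pos=records[-1].pos)
        call = merge_terminal_call(retained, segments, params)
        if call is not None:
            calls.append(call)
    return calls
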