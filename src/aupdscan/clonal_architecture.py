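"""Cell-fraction decomposition and order-of-acquisition for aUPD14q / JAK2.

Model: aUPD9p duplicates the mutant JAK2 allele, so homozygous-mutant cells
are exactly the aUPD9p clone, f9_hom = 2*(BAF9 - 0.5). Heterozygous-mutant
cells contribute half a mutant allele each, giving the conservation identity

    v617f_burden = f9_hom + f_het / 2

which is inverted for f_het. The aUPD14q cell fraction comes from the same
mixture identity on chromosome 14, f14 = 2*(BAF14 - 0.5).

Order of acquisition uses the twofold rule: the event present in at least
twice as many cells as the other is called the earlier one; anything in
between is uncertain.
"""
from __future__ import annotations

from typing import Optional, Sequence

from .errors import DataValueError, ModelInconsistencyError
from .types import ClonalEstimate, OrderCall


def decompose_jak2(
    v: float, baf9: float, tol: float = 0.05
) -> tuple[float, float]:
    """Split a JAK2 V617F allele burden into homozygous/heterozygous cell fractions.

    Returns ``(f9_hom, f_het)``. Small negative ``f_het`` or a total slightly
    above 1 (within ``tol``, from measurement noise) are clamped; larger
    violations raise :class:`ModelInconsistencyError`.
    """
    if not 0.0 <= v <= 1.0:
        raise DataValueError(f"allele burden {v} outside [0, 1]")
    if not 0.5 <= baf9 <= 1.0:
        raise DataValueError(f"mirrored BAF9 {baf9} outside [0.5, 1]")
    f9_hom = 2.0 * (baf9 - 0.5)
    f_het = 2.0 * (v - f9_hom)
    if f_het < -tol:
        raise ModelInconsistencyError(
            f"burden {v} < homozygous fraction {f9_hom}: identity "
            "v = f9_hom + f_het/2 violated (f_het < 0)"
        )
    f_het = max(f_het, 0.0)
    if f9_hom + f_het > 1.0 + tol:
        raise ModelInconsistencyError(
            f"f9_hom + f_het = {f9_hom + f_het:.3f} > 1: identity "
            "v = f9_hom + f_het/2 implies an infeasible cell fraction"
        )
    f_het = min(f_het, 1.0 - f9_hom)
    return f9_hom, f_het


def order_of_acquisition(
    f14: float, jak2_total: float, ratio: float = 2.0
) -> OrderCall:
    """Twofold rule: the clone at >= ratio times the other's size came first."""
    if not (0.0 <= f14 <= 1.0 and 0.0 <= jak2_total <= 1.0):
        raise DataValueError("cell fractions must lie in [0, 1]")
    if ratio <= 1.0:
        raise DataValueError("ratio must exceed 1")
    if f14 == 0.0 and jak2_total == 0.0:
        raise DataValueError("no clone to order: both fractions are zero")
    if f14 >= ratio * jak2_total:
        return OrderCall.AUPD14_FIRST
    if jak2_total >= ratio * f14:
        return OrderCall.JAK2_FIRST
    return OrderCall.UNCERTAIN


def clonal_report(
    cases: Sequence[dict],
    tol: float = 0.05,
    ratio: float = 2.0,
) -> tuple[list[ClonalEstimate], list[tuple[str, str]]]:
    """Decompose and order every case; collect per-case errors.

    Each case dict needs ``case_id``, ``v`` (V617F burden), ``baf9`` and
    ``baf14`` (mirrored BAFs). Returns (estimates, [(case_id, error), ...]);
    a failing case is reported and skipped, the rest are processed.
    """
    estimates: list[ClonalEstimate] = []
    failures: list[tuple[str, str]] = []
    for case in cases:
        cid = case["case_id"]
        try:
            f9_hom, f_het = decompose_jak2(case["v"], case["baf9"], tol=tol)
            f14 = 2.0 * (case["baf14"] - 0.5)
            if not 0.0 <= f14 <= 1.0:
                raise DataValueError(f"baf14 {case['baf14']} outside [0.5, 1]")
            call = order_of_acquisition(f14, f9_hom + f_het, ratio=ratio)
            estimates.append(
                ClonalEstimate(
                    case_id=cid, f14=f14, f9_hom=f9_hom, f_het=f_het, order_call=call
                )
            )
        except (DataValueError, ModelInconsistencyError) as exc:
            failures.append((cid, str(exc)))
    return estimates, failures
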