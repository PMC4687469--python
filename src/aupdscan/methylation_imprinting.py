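"""Parental methylation imbalance at an imprinted locus from MS-PCR peaks.

The locus (e.g. *MEG3* at 14q32) is methylated on the paternal and
unmethylated on the maternal chromosome, so in a balanced diploid sample the
methylated peak carries ~half the signal. The raw ratio M/(M+U) is therefore
~0.5 in controls; after subtracting the control mean ("normalised to zero")
the methylation value runs from -0.5 (complete paternal loss / maternal
gain) to +0.5 (complete paternal gain / maternal loss). For a paternal aUPD
clone at cell fraction f the noiseless value is f/2, matching the BAF-based
clone-fraction estimate 2*(mBAF-0.5) case by case.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from . import stats_core
from .errors import AssayError, ConfigError, InsufficientDataError
from .types import CaseRecord, MethylationPeaks


class ParentalCall(str, Enum):
    PATERNAL_GAIN = "paternal_gain"
    MATERNAL_GAIN = "maternal_gain"
    BALANCED = "balanced"


@dataclass
class MethylationValue:
    sample_id: str
    group: str
    raw_ratio: float
    value: float
    parental_call: ParentalCall = ParentalCall.BALANCED
    out_of_range: bool = False  # |value| > 0.5, possible with biased controls


def methylation_raw_ratio(peaks: MethylationPeaks) -> float:
    """Methylated peak height over the sum of both peaks."""
    total = peaks.m_height + peaks.u_height
    if total <= 0:
        raise AssayError(f"{peaks.sample_id}: both MS-PCR peaks are zero")
    return peaks.m_height / total


def classify_parental_origin(value: float, threshold: float = 0.12) -> ParentalCall:
    """Call parental origin from a normalised methylation value.

    Default threshold 0.12 is ~3 control standard deviations.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    if value > threshold:
        return ParentalCall.PATERNAL_GAIN
    if value < -threshold:
        return ParentalCall.MATERNAL_GAIN
    return ParentalCall.BALANCED


def normalise_to_controls(
    peaks: Sequence[MethylationPeaks],
    control_group: str = "control",
    call_threshold: float = 0.12,
    by_batch: bool = False,
) -> list[MethylationValue]:
    """Convert peak heights to normalised methylation values.

    The control offset is the mean raw ratio of samples in ``control_group``
    (globally, or per batch with ``by_batch``); every sample's value is its
    raw ratio minus the offset, so control values average exactly zero.
    Values outside [-0.5, 0.5] are retained but flagged.
    """
    def offset_for(subset: Iterable[MethylationPeaks]) -> float:
        ratios = [methylation_raw_ratio(p) for p in subset if p.group == control_group]
        if not ratios:
            raise ConfigError(f"no samples in control group {control_group!r}")
        return float(np.mean(ratios))

    out: list[MethylationValue] = []
    if by_batch:
        batches = sorted({p.batch for p in peaks})
        offsets = {
            b: offset_for([p for p in peaks if p.batch == b]) for b in batches
        }
    else:
        global_offset = offset_for(peaks)
        offsets = None

    for p in peaks:
        ratio = methylation_raw_ratio(p)
        offset = offsets[p.batch] if offsets is not None else global_offset
        value = ratio - offset
        out.append(
            MethylationValue(
                sample_id=p.sample_id,
                group=p.group,
                raw_ratio=ratio,
                value=value,
                parental_call=classify_parental_origin(value, call_threshold),
                out_of_range=abs(value) > 0.5 + 1e-12,
            )
        )
    return out


def group_comparison(
    case_values: Sequence[float], control_values: Sequence[float]
) -> dict:
    """Descriptive statistics per group plus a two-sided Mann-Whitney p."""
    if len(case_values) == 0 or len(control_values) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    test = stats_core.mann_whitney_u(case_values, control_values)
    return {
        "case_mean": float(np.mean(case_values)),
        "case_sd": float(np.std(case_values, ddof=1)) if len(case_values) > 1 else 0.0,
        "case_n": len(case_values),
        "control_mean": float(np.mean(control_values)),
        "control_sd": float(np.std(control_values, ddof=1))
        if len(control_values) > 1
        else 0.0,
        "control_n": len(control_values),
        "u": test.u,
        "p_two_sided": test.p_two_sided,
        "method": test.method,
    }


def correlate_with_baf(cases: Sequence[CaseRecord]) -> stats_core.CorrelationResult:
    """Spearman correlation of methylation value with mean aUPD BAF.

    Uses every case where both fields are present.
    """
    pairs = [
        (c.mean_baf, c.methylation_value)
        for c in cases
        if c.mean_baf is not None and c.methylation_value is not None
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} complete (BAF, methylation) pairs; need >= 3"
        )
    baf = [p[0] for p in pairs]
    meth = [p[1] for p in pairs]
    return stats_core.spearman_rho(baf, meth)
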