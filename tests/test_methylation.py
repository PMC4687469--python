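"""Peak-ratio arithmetic, control normalisation, parental calls, correlations."""
import numpy as np
import pytest

from aupdscan.errors import AssayError, ConfigError, InsufficientDataError
from aupdscan.methylation_imprinting import (
    ParentalCall,
    classify_parental_origin,
    correlate_with_baf,
    group_comparison,
    methylation_raw_ratio,
    normalise_to_controls,
)
from aupdscan.synthetic_cohort import simulate_methylation_peaks
from aupdscan.types import CaseRecord, MethylationPeaks


def _peaks(m, u, sid="s", group="aupd14q", batch=""):
    return MethylationPeaks(sid, group, m, u, batch)


class TestRawRatio:
    @pytest.mark.parametrize(
        "m, u, expected", [(100, 100, 0.5), (100, 0, 1.0), (73, 27, 0.73)]
    )
    def test_values(self, m, u, expected):
        assert methylation_raw_ratio(_peaks(m, u)) == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        for _ in range(10):
            m, u = rng.uniform(1, 500, 2)
            c = rng.uniform(0.01, 100)
            assert methylation_raw_ratio(_peaks(m, u)) == pytest.approx(
                methylation_raw_ratio(_peaks(m * c, u * c))
            )

    def test_failed_assay(self):
        with pytest.raises(AssayError):
            methylation_raw_ratio(_peaks(0.0, 0.0))


class TestNormalisation:
    def test_complete_maternal_loss_scores_half(self):
        peaks = [
            _peaks(100, 100, "c1", "control"),
            _peaks(50, 50, "c2", "control"),
            _peaks(80, 0, "case", "aupd14q"),
        ]
        values = {v.sample_id: v for v in normalise_to_controls(peaks)}
        assert values["case"].value == pytest.approx(0.5)
        assert values["case"].parental_call is ParentalCall.PATERNAL_GAIN

    def test_control_mean_exactly_zero(self, rng):
        for _ in range(5):
            n = int(rng.integers(2, 10))
            peaks = [
                _peaks(rng.uniform(10, 100), rng.uniform(10, 100), f"c{i}", "control")
                for i in range(n)
            ]
            values = normalise_to_controls(peaks)
            assert np.mean([v.value for v in values]) == pytest.approx(0.0, abs=1e-12)

    def test_sample_at_control_mean_scores_zero(self):
        peaks = [
            _peaks(52, 48, "c1", "control"),
            _peaks(48, 52, "c2", "control"),
            _peaks(50, 50, "case", "screen"),
        ]
        (case,) = [v for v in normalise_to_controls(peaks) if v.sample_id == "case"]
        assert case.value == pytest.approx(0.0)
        assert case.parental_call is ParentalCall.BALANCED

    def test_batchwise_normalisation(self):
        peaks = [
            _peaks(60, 40, "c1", "control", batch="b1"),  # biased batch
            _peaks(60, 40, "s1", "aupd14q", batch="b1"),
            _peaks(50, 50, "c2", "control", batch="b2"),
            _peaks(60, 40, "s2", "aupd14q", batch="b2"),
        ]
        by_id = {
            v.sample_id: v for v in normalise_to_controls(peaks, by_batch=True)
        }
        assert by_id["s1"].value == pytest.approx(0.0)
        assert by_id["s2"].value == pytest.approx(0.1)

    def test_biased_controls_flag_out_of_range(self):
        peaks = [
            _peaks(20, 80, "c1", "control"),  # offset 0.2
            _peaks(100, 0, "case", "aupd14q"),  # value 0.8
        ]
        (case,) = [v for v in normalise_to_controls(peaks) if v.sample_id == "case"]
        assert case.value == pytest.approx(0.8)
        assert case.out_of_range

    def test_no_controls_rejected(self):
        with pytest.raises(ConfigError):
            normalise_to_controls([_peaks(1, 1, "s", "aupd14q")])


class TestParentalCall:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.45, ParentalCall.PATERNAL_GAIN),
            (-0.14, ParentalCall.MATERNAL_GAIN),
            (0.0, ParentalCall.BALANCED),
            (0.12, ParentalCall.BALANCED),  # threshold is strict
        ],
    )
    def test_calls(self, value, expected):
        assert classify_parental_origin(value, threshold=0.12) is expected


class TestGroupComparison:
    def test_identical_groups(self):
        result = group_comparison([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert result["p_two_sided"] == pytest.approx(1.0)

    def test_shifted_groups_significant(self, rng):
        cases = list(rng.normal(0.25, 0.15, 20))
        controls = list(rng.normal(0.0, 0.04, 24))
        result = group_comparison(cases, controls)
        assert result["p_two_sided"] < 1e-4
        assert result["case_n"] == 20 and result["control_n"] == 24


class TestBafCorrelation:
    def test_noiseless_mixture_link_is_monotone(self):
        cases = [
            CaseRecord(f"s{i}", "ET", mean_baf=0.5 + f / 2, methylation_value=f / 2)
            for i, f in enumerate(np.linspace(0.1, 0.9, 12))
        ]
        result = correlate_with_baf(cases)
        assert result.rho == pytest.approx(1.0)
        assert result.n == 12

    def test_incomplete_pairs_excluded(self):
        cases = [
            CaseRecord("a", "ET", mean_baf=0.7, methylation_value=0.2),
            CaseRecord("b", "ET", mean_baf=0.8, methylation_value=0.3),
            CaseRecord("c", "ET", mean_baf=None, methylation_value=0.1),
            CaseRecord("d", "ET", mean_baf=0.9, methylation_value=0.4),
        ]
        assert correlate_with_baf(cases).n == 3

    def test_too_few_pairs_rejected(self):
        cases = [CaseRecord("a", "ET", mean_baf=0.7, methylation_value=0.2)]
        with pytest.raises(InsufficientDataError):
            correlate_with_baf(cases)

    def test_permutation_null_rarely_reaches_observed(self, rng):
        """Permuting methylation against BAF kills the correlation."""
        f = np.linspace(0.1, 0.9, 19)
        high = 0
        for _ in range(200):
            perm = rng.permutation(f)
            cases = [
                CaseRecord(
                    f"s{i}", "ET", mean_baf=0.5 + fi / 2, methylation_value=pi / 2
                )
                for i, (fi, pi) in enumerate(zip(f, perm))
            ]
            if abs(correlate_with_baf(cases).rho) >= 0.5:
                high += 1
        assert high <= 10  # >= 95% of permutations below 0.5


class TestTrisomyNoParentalBias:
    def test_random_parental_origin_centres_on_zero(self, rng):
        """Trisomy with random parental origin shows no methylation bias."""
        values = []
        for i in range(200):
            kind = "trisomy_paternal" if rng.random() < 0.5 else "trisomy_maternal"
            peaks = simulate_methylation_peaks(
                0.8, kind=kind, cv=0.05, seed=int(rng.integers(2**31))
            )
            values.append(methylation_raw_ratio(peaks) - 0.5)
        spread = np.std(values) / np.sqrt(len(values))
        assert abs(np.mean(values)) < 3 * spread + 0.01
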