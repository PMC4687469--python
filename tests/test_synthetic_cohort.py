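"""The generator's mixture structure, noiseless identities and determinism."""
import numpy as np
import pytest

from aupdscan.errors import ConfigError, DataValueError
from aupdscan.synthetic_cohort import (
    Event,
    SimSpec,
    methylation_doses,
    simulate_cohort,
    simulate_jak2_case,
    simulate_methylation_peaks,
    simulate_snp_profile,
)
from aupdscan.aupd_detection import mirror_baf
from aupdscan.methylation_imprinting import methylation_raw_ratio
from aupdscan.types import GenomicInterval

CHR14_LEN = 107_349_540


def _event(f, kind="aupd_paternal", start=64_000_000, end=CHR14_LEN):
    return Event(GenomicInterval("14", start, end), kind, f)


def _het_bafs(profile, lo=0, hi=CHR14_LEN):
    """BAFs of heterozygous SNPs (identified by BAF away from 0/1)."""
    return np.array(
        [r.baf for r in profile["14"] if lo <= r.pos <= hi and 0.05 < r.baf < 0.95]
    )


class TestSnpProfile:
    def test_null_genome_het_baf_centred(self):
        spec = SimSpec(n_snps=2000, seed=7)
        baf = _het_bafs(simulate_snp_profile(spec))
        assert len(baf) >= 400
        assert abs(baf.mean() - 0.5) < 3 * 0.03 / np.sqrt(len(baf))

    def test_complete_aupd_pushes_hets_to_homozygosity(self):
        spec = SimSpec(n_snps=1000, events=[_event(1.0)], seed=7)
        profile = simulate_snp_profile(spec)
        inside = np.array(
            [r.baf for r in profile["14"] if r.pos >= 64_000_000]
        )
        assert np.all((inside < 0.2) | (inside > 0.8))

    def test_noiseless_mirrored_baf_is_half_plus_half_f(self):
        """f=0.82 noiseless: every het mirrored BAF is exactly 0.91."""
        spec = SimSpec(
            n_snps=500, events=[_event(0.82)], baf_noise_sd=0.0, hom_baf_sd=0.0,
            seed=3,
        )
        profile = simulate_snp_profile(spec)
        het_inside = [
            r.baf
            for r in profile["14"]
            if r.pos >= 64_000_000 and r.baf not in (0.0, 1.0)
        ]
        assert het_inside
        assert np.allclose(mirror_baf(het_inside), 0.91)

    def test_trisomy_shifts_lrr_and_baf_bands(self):
        f = 1.0
        spec = SimSpec(
            n_snps=1000, events=[_event(f, kind="trisomy_paternal")],
            baf_noise_sd=0.0, hom_baf_sd=0.0, lrr_noise_sd=0.0, seed=11,
        )
        profile = simulate_snp_profile(spec)
        inside = [r for r in profile["14"] if r.pos >= 64_000_000]
        lrr = {round(r.lrr, 6) for r in inside}
        assert lrr == {round(np.log2(1.5), 6)}
        het_bands = {round(r.baf, 6) for r in inside if r.baf not in (0.0, 1.0)}
        assert het_bands <= {round(1 / 3, 6), round(2 / 3, 6)}

    def test_overlapping_events_rejected(self):
        with pytest.raises(ConfigError):
            SimSpec(
                events=[
                    _event(0.5, start=10, end=100),
                    _event(0.5, start=50, end=200),
                ]
            )

    def test_same_seed_identical_different_seed_distinct(self):
        spec = SimSpec(n_snps=300, seed=5)
        a = simulate_snp_profile(spec)
        b = simulate_snp_profile(SimSpec(n_snps=300, seed=5))
        c = simulate_snp_profile(SimSpec(n_snps=300, seed=6))
        assert a == b
        assert a != c


class TestMethylationPeaks:
    @pytest.mark.parametrize(
        "f, kind, expected_ratio",
        [
            (0.0, "aupd_paternal", 0.5),
            (1.0, "aupd_paternal", 1.0),
            (0.46, "aupd_paternal", 0.73),
            (1.0, "aupd_maternal", 0.0),
            (1.0, "trisomy_paternal", 2 / 3),
        ],
    )
    def test_noiseless_dose_ratios(self, f, kind, expected_ratio):
        peaks = simulate_methylation_peaks(f, kind=kind, cv=0.0)
        assert methylation_raw_ratio(peaks) == pytest.approx(expected_ratio)

    def test_doses_reject_bad_fraction(self):
        with pytest.raises(DataValueError):
            methylation_doses(1.5, "aupd_paternal")


class TestJak2Case:
    @pytest.mark.parametrize(
        "f14, f9_hom, f_het, burden, baf9",
        [
            (0.0, 0.0, 1.0, 0.5, 0.5),
            (0.0, 1.0, 0.0, 1.0, 1.0),
            (0.3, 0.4, 0.2, 0.5, 0.7),
        ],
    )
    def test_noiseless_composition(self, f14, f9_hom, f_het, burden, baf9):
        out = simulate_jak2_case(f14, f9_hom, f_het, error_sd=0.0)
        assert out["v617f_burden"] == pytest.approx(burden)
        assert out["baf9"] == pytest.approx(baf9)
        assert out["baf14"] == pytest.approx(0.5 + f14 / 2)

    def test_allele_conservation_on_grid(self):
        for f_hom in np.arange(0.0, 1.01, 0.1):
            for f_het in np.arange(0.0, 1.01 - f_hom, 0.1):
                out = simulate_jak2_case(0.2, f_hom, f_het, error_sd=0.0)
                assert out["v617f_burden"] == pytest.approx(f_hom + f_het / 2)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(DataValueError):
            simulate_jak2_case(0.2, 0.7, 0.5)


class TestCohort:
    def test_outputs_byte_identical_across_runs(self, tmp_path):
        template = SimSpec(n_snps=200, events=[_event(0.5)])
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            simulate_cohort(3, template, seed=99, out_dir=out)
            dirs.append(out)
        for f in sorted(p.name for p in dirs[0].iterdir()):
            assert (dirs[0] / f).read_bytes() == (dirs[1] / f).read_bytes()

    def test_known_fractions_recovered_by_detection(self):
        from aupdscan.aupd_detection import detect_calls

        template = SimSpec(n_snps=2000, events=[_event(0.6)])
        cohort = simulate_cohort(2, template, seed=17)
        for case in cohort:
            (call,) = detect_calls(case["profile"])
            assert abs(call.clone_fraction - case["truth_f"]) <= 0.05

    def test_null_cohort_yields_no_calls(self):
        from aupdscan.aupd_detection import detect_calls

        template = SimSpec(n_snps=1500)
        cohort = simulate_cohort(3, template, seed=23)
        assert all(not detect_calls(c["profile"]) for c in cohort)
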