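import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanodisc_sas.biodist import (
    BiodistTable,
    DecayContext,
    activity_to_counts,
    biexponential_fit,
    counts_to_activity,
    decay_apply,
    decay_correct,
    intact_fraction,
    organ_ratio,
    percent_id_per_gram,
)
from nanodisc_sas.synthdata import Chromatogram, simulate_biodistribution, DEFAULT_ORGANS


class TestDecay:
    def test_zero_elapsed_is_identity(self):
        assert decay_correct(5.0, 0.0) == 5.0

    def test_one_half_life_doubles(self):
        ctx = DecayContext(half_life=12.7)
        assert decay_correct(1.0, 12.7, ctx) == pytest.approx(2.0, rel=1e-14)

    def test_two_half_lives_quadruple(self):
        ctx = DecayContext(half_life=12.7)
        assert decay_correct(1.0, 25.4, ctx) == pytest.approx(4.0, rel=1e-14)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        activity=st.floats(min_value=1e-6, max_value=1e6),
        elapsed=st.floats(min_value=0.0, max_value=100.0),
    )
    def test_correct_inverts_apply(self, activity, elapsed):
        ctx = DecayContext(half_life=12.7)
        assert decay_correct(decay_apply(activity, elapsed, ctx), elapsed, ctx) == pytest.approx(
            activity, rel=1e-12
        )


class TestCounting:
    def test_published_efficiency_case(self):
        # 943 counts/s at 9.43% efficiency = 10 kBq
        assert counts_to_activity(943.0, 0.0943) == pytest.approx(10_000.0, rel=1e-12)

    def test_unit_efficiency_is_identity(self):
        assert counts_to_activity(100.0, 1.0) == 100.0

    def test_round_trip(self):
        assert activity_to_counts(counts_to_activity(321.0, 0.0943), 0.0943) == pytest.approx(
            321.0
        )

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            counts_to_activity(100.0, 0.0)


class TestPercentID:
    def test_full_dose_in_one_gram(self):
        assert percent_id_per_gram(10.0, 1.0, 10.0) == pytest.approx(100.0)

    def test_blood_level_scale(self):
        # 0.96 MBq in 1 g after a 10 MBq injection → 9.6 %ID/g
        assert percent_id_per_gram(0.96, 1.0, 10.0) == pytest.approx(9.6)

    def test_linear_in_inverse_mass(self):
        assert percent_id_per_gram(1.0, 2.0, 10.0) == pytest.approx(
            percent_id_per_gram(1.0, 1.0, 10.0) / 2.0
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(rescale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_activity_unit_change(self, rescale):
        base = percent_id_per_gram(0.96, 1.3, 10.0)
        assert percent_id_per_gram(0.96 * rescale, 1.3, 10.0 * rescale) == pytest.approx(
            base, rel=1e-12
        )

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            percent_id_per_gram(1.0, 0.0, 10.0)


class TestBiexponentialFit:
    times = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0])

    def test_noiseless_recovery(self):
        A, k1, B, k2 = 9.0, 0.35, 3.5, 0.02
        y = A * np.exp(-k1 * self.times) + B * np.exp(-k2 * self.times)
        fit = biexponential_fit(self.times, y, seed=0)
        assert not fit.monophasic
        assert (fit.A, fit.k1, fit.B, fit.k2) == pytest.approx((A, k1, B, k2), rel=1e-4)

    def test_single_exponential_flagged_monophasic(self):
        y = 5.0 * np.exp(-0.3 * self.times)
        fit = biexponential_fit(self.times, y, seed=0)
        assert fit.monophasic

    def test_noisy_recovery_within_3_sd(self):
        A, k1, B, k2 = 9.0, 0.35, 3.5, 0.02
        truth = np.array([A, k1, B, k2])
        rng_master = np.random.default_rng(123)
        hits = 0
        for _ in range(20):
            rng = np.random.default_rng(rng_master.integers(2**31))
            y = (A * np.exp(-k1 * self.times) + B * np.exp(-k2 * self.times)) * (
                1 + 0.03 * rng.standard_normal(self.times.size)
            )
            fit = biexponential_fit(self.times, y, seed=1)
            est = np.array([fit.A, fit.k1, fit.B, fit.k2])
            sds = np.array([fit.sd["A"], fit.sd["k1"], fit.sd["B"], fit.sd["k2"]])
            if np.all(np.abs(est - truth) <= 3 * sds):
                hits += 1
        assert hits >= 18

    def test_fast_phase_ordering_on_default_blood(self):
        df = simulate_biodistribution(
            {"blood": DEFAULT_ORGANS["blood"]}, times=self.times, noise_fraction=0.02, seed=5
        )
        fit = biexponential_fit(df.time_h.to_numpy(), df.pid_g.to_numpy(), seed=0)
        t_fast, t_slow = fit.half_times
        assert t_fast < t_slow

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            biexponential_fit([1, 2, 3], [1.0, 0.5, 0.25], seed=0)


class TestIntactFraction:
    def flat_chromatogram(self, values):
        v = np.linspace(4.0, 12.0, len(values))
        return Chromatogram(v, np.asarray(values, float), [])

    def test_all_counts_in_window(self):
        counts = np.zeros(200)
        counts[80:100] = 50.0
        chrom = self.flat_chromatogram(counts)
        window = (chrom.elution_volume[75], chrom.elution_volume[105])
        assert intact_fraction(chrom, window) == pytest.approx(1.0)

    def test_window_over_empty_region_gives_zero(self):
        counts = np.zeros(200)
        counts[150:160] = 50.0
        chrom = self.flat_chromatogram(counts)
        assert intact_fraction(chrom, (4.5, 5.5)) == pytest.approx(0.0, abs=1e-12)

    def test_window_outside_range_rejected(self):
        chrom = self.flat_chromatogram(np.ones(50))
        with pytest.raises(ValueError):
            intact_fraction(chrom, (1.0, 3.0))

    def test_baseline_subtraction(self):
        counts = np.full(200, 10.0)
        counts[80:100] += 90.0
        chrom = self.flat_chromatogram(counts)
        window = (chrom.elution_volume[78], chrom.elution_volume[102])
        assert intact_fraction(chrom, window) == pytest.approx(1.0, abs=0.01)


class TestOrganRatio:
    def table(self):
        return BiodistTable(
            pd.DataFrame(
                {
                    "organ": ["tumor", "muscle", "tumor", "muscle"],
                    "time_h": [24.0, 24.0, 48.0, 48.0],
                    "pid_g": [4.0, 0.3, 3.8, 0.25],
                    "sd": [0.4, 0.05, 0.4, 0.05],
                    "n": [10, 10, 10, 10],
                }
            )
        )

    def test_identical_organs_give_unity(self):
        assert organ_ratio(self.table(), "tumor", "tumor", 24.0) == 1.0

    def test_tumor_to_muscle_arithmetic(self):
        assert organ_ratio(self.table(), "tumor", "muscle", 24.0) == pytest.approx(
            4.0 / 0.3, rel=1e-12
        )

    def test_missing_organ_rejected(self):
        with pytest.raises(KeyError):
            organ_ratio(self.table(), "kidney", "muscle", 24.0)

    def test_table_validation(self):
        with pytest.raises(ValueError):
            BiodistTable(pd.DataFrame({"organ": ["a"], "time_h": [1.0], "pid_g": [-1.0]}))
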