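import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockcomp import (DomainError, average_profile, chi_square_periodogram,
                       classify_genotype, dd_regime, fold_qp, gen_activity,
                       morning_activity)
from clockcomp.chronotype import _qp_statistic
from clockcomp.synthetic import DEFAULT_GENOTYPES
from conftest import make_series


def brute_force_qp(counts, n_cycles, bins_per_cycle):
    """Direct evaluation of the folded-matrix statistic with plain loops."""
    used = n_cycles * bins_per_cycle
    x = [float(v) for v in counts[:used]]
    grand = sum(x) / used
    col_means = []
    for h in range(bins_per_cycle):
        col = [x[c * bins_per_cycle + h] for c in range(n_cycles)]
        col_means.append(sum(col) / n_cycles)
    between = sum((m - grand) ** 2 for m in col_means)
    total = sum((v - grand) ** 2 for v in x)
    return used * n_cycles * between / total


class TestFoldQp:
    def test_matches_brute_force_on_two_cycle_fixture(self):
        # 2 cycles x 4 bins with rows (1,0,0,0) and (1,0,0,0)
        counts = [1, 0, 0, 0, 1, 0, 0, 0]
        series = make_series(counts, bin_width=60)
        qp, df = fold_qp(series, period=4.0)
        assert df == 3
        assert qp == pytest.approx(brute_force_qp(counts, 2, 4), abs=1e-12)
        assert qp == pytest.approx(8.0)

    def test_matches_brute_force_on_random_fixture(self, rng):
        counts = rng.poisson(3.0, size=5 * 6)
        series = make_series(counts, bin_width=60)
        qp, df = fold_qp(series, period=6.0)
        assert df == 5
        assert qp == pytest.approx(brute_force_qp(counts, 5, 6), rel=1e-12)

    def test_zero_variance_series_scores_zero(self):
        qp, df = fold_qp(make_series([4] * 48, bin_width=60), period=6.0)
        assert qp == 0.0

    def test_true_period_beats_incommensurate_period(self, square_wave_series):
        qp_true, _ = fold_qp(square_wave_series, period=24.0)
        qp_other, _ = fold_qp(square_wave_series, period=31.0)
        assert qp_true > qp_other

    def test_needs_two_complete_cycles(self):
        with pytest.raises(DomainError):
            fold_qp(make_series([1] * 30, bin_width=60), period=20.0)

    @pytest.mark.parametrize("scale", [2, 7])
    def test_scaling_counts_leaves_qp_unchanged(self, rng, scale):
        counts = rng.poisson(2.0, size=96)
        a, _ = _qp_statistic(counts, 60, 8.0)
        b, _ = _qp_statistic(counts * scale, 60, 8.0)
        assert b == pytest.approx(a, rel=1e-12)


class TestPeriodogram:
    def test_constant_series_is_arrhythmic(self):
        r = chi_square_periodogram(make_series([3] * 2500, bin_width=10))
        assert not r.rhythmic

    def test_empty_grid_rejected(self, square_wave_series):
        with pytest.raises(DomainError):
            chi_square_periodogram(square_wave_series, grid=[])

    def test_noiseless_square_wave_peak_within_one_grid_step(self):
        day = [5] * 36 + [0] * 108  # 24-h square wave at 10-min bins
        series = make_series(day * 10, bin_width=10)
        r = chi_square_periodogram(series)
        assert r.rhythmic
        assert abs(r.peak_period - 24.0) <= 0.1 + 1e-9

    @pytest.mark.parametrize("genotype,tau", [("per_s", 19.0),
                                              ("per_l", 27.6)])
    def test_synthetic_mutant_peak_recovers_tau(self, genotype, tau):
        series = gen_activity(DEFAULT_GENOTYPES[genotype], dd_regime(14.0),
                              seed=7)
        r = chi_square_periodogram(series)
        assert r.rhythmic
        assert abs(r.peak_period - tau) <= 0.1 + 1e-9

    def test_mean_tau_over_many_flies_within_tolerance(self):
        # scaled-down version of the 60-fly recovery invariant
        peaks = []
        for i in range(15):
            s = gen_activity(DEFAULT_GENOTYPES["wildtype"], dd_regime(14.0),
                             seed=300 + i)
            peaks.append(chi_square_periodogram(s).peak_period)
        assert abs(np.mean(peaks) - 24.3) <= 0.2


class TestClassification:
    @pytest.mark.parametrize("tau,expected", [
        (19.0, "short"),
        (24.3, "wildtype_like"),
        (27.6, "long"),
        (22.0, "wildtype_like"),   # boundaries belong to the middle class
        (26.0, "wildtype_like"),
    ])
    def test_rhythmic_classes_follow_boundaries(self, square_wave_series,
                                                tau, expected):
        r = chi_square_periodogram(square_wave_series)
        r.peak_period = tau
        r.rhythmic = True
        call = classify_genotype(r)
        assert call.genotype_class == expected
        assert call.tau == tau

    def test_non_rhythmic_is_arrhythmic_without_tau(self, square_wave_series):
        r = chi_square_periodogram(square_wave_series)
        r.rhythmic = False
        call = classify_genotype(r)
        assert call.genotype_class == "arrhythmic"
        assert call.tau is None

    @settings(deadline=None, max_examples=60)
    @given(tau=st.floats(14.0, 35.0), rhythmic=st.booleans())
    def test_partition_is_exhaustive_and_exclusive(self, tau, rhythmic):
        from clockcomp import PeriodogramResult

        grid = np.array([tau])
        r = PeriodogramResult(fly_id="f", periods=grid, qp=np.array([1.0]),
                              threshold=np.array([0.5]), df=np.array([3]),
                              peak_period=tau, peak_qp=1.0, rhythmic=rhythmic)
        call = classify_genotype(r)
        matches = [
            not rhythmic and call.genotype_class == "arrhythmic",
            rhythmic and tau < 22.0 and call.genotype_class == "short",
            rhythmic and 22.0 <= tau <= 26.0
            and call.genotype_class == "wildtype_like",
            rhythmic and tau > 26.0 and call.genotype_class == "long",
        ]
        assert sum(matches) == 1


class TestProfiles:
    def test_single_fly_single_cycle_is_identity(self, rng):
        counts = rng.poisson(2.0, size=24)
        s = make_series(counts, bin_width=60, mode="LD")
        profile = average_profile([s])
        np.testing.assert_allclose(profile.mean, counts)

    def test_two_constant_flies_average_pointwise(self):
        a = make_series([2] * 48, bin_width=60, mode="LD")
        b = make_series([6] * 48, bin_width=60, mode="LD")
        profile = average_profile([a, b])
        np.testing.assert_allclose(profile.mean, 4.0)

    def test_mixed_cycle_lengths_rejected(self):
        a = make_series([1] * 24, bin_width=60, mode="LD", T=24.0)
        b = make_series([1] * 19, bin_width=60, mode="LD", T=19.0)
        with pytest.raises(DomainError):
            average_profile([a, b])

    def test_wildtype_profile_is_bimodal_at_transitions(self):
        from clockcomp import ld_regime
        series = [gen_activity(DEFAULT_GENOTYPES["wildtype"],
                               ld_regime(5.0, bin_width=10), bin_width=10,
                               seed=500 + i)
                  for i in range(12)]
        profile = average_profile(series)
        zt = profile.zt
        near_on = profile.mean[(zt < 2) | (zt >= 22)].max()
        near_off = profile.mean[(zt >= 10) & (zt < 14)].max()
        siesta = profile.mean[(zt >= 4) & (zt < 8)].mean()
        assert near_on > 2 * siesta
        assert near_off > 2 * siesta


class TestMorningActivity:
    def test_constant_one_count_per_ten_minutes_gives_18(self):
        s = make_series([1] * 144, bin_width=10, mode="LD")
        assert morning_activity(s) == pytest.approx(18.0)

    def test_all_activity_inside_window_equals_total(self):
        counts = [4] * 18 + [0] * 126  # everything in ZT0-3 at 10-min bins
        s = make_series(counts, bin_width=10, mode="LD")
        assert morning_activity(s) == pytest.approx(sum(counts))

    def test_window_must_fit_cycle(self):
        s = make_series([1] * 114, bin_width=10, mode="LD", T=19.0)
        with pytest.raises(DomainError):
            morning_activity(s, window=(0.0, 20.0))

    def test_genotype_ordering_matches_morning_bout_sizes(self):
        from clockcomp import ld_regime
        levels = {}
        for g in ("per_l", "wildtype", "per_s"):
            series = [gen_activity(DEFAULT_GENOTYPES[g],
                                   ld_regime(4.0, bin_width=10), bin_width=10,
                                   seed=900 + i)
                      for i in range(10)]
            levels[g] = morning_activity(average_profile(series))
        assert levels["per_l"] > levels["wildtype"] > levels["per_s"]
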