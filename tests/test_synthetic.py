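import numpy as np
import pytest

from clockcomp import (AdditiveAttractiveness, DomainError, DriftConfig,
                       ValidationError, census_frequencies,
                       chi_square_periodogram, dd_regime, gen_activity,
                       gen_competition, gen_counts, gen_mating_trials,
                       gen_survival_assay, mc_confidence_interval,
                       neutral_envelopes, survival_rates)
from clockcomp.synthetic import (DEFAULT_GENOTYPES, EGG_TO_PUPA, GenotypeParams,
                                 SelectionParams,
                                 simulate_selected_frequencies)


class TestActivityGenerator:
    def test_zero_amplitude_gives_flat_poisson(self):
        params = GenotypeParams(label="flat", tau=24.0, morning_amp=0.0,
                                evening_amp=0.0, baseline=2.0,
                                dark_suppression=1.0)
        series = gen_activity(params, dd_regime(4.0, bin_width=10),
                              bin_width=10, seed=0)
        mean = series.counts.mean()
        assert mean == pytest.approx(20.0, rel=0.1)
        halves = np.array_split(series.counts.astype(float), 2)
        assert abs(halves[0].mean() - halves[1].mean()) < 2.0

    def test_seeded_generation_bit_reproducible(self):
        p = DEFAULT_GENOTYPES["wildtype"]
        a = gen_activity(p, dd_regime(3.0), seed=5)
        b = gen_activity(p, dd_regime(3.0), seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_short_mutant_period_recovered(self):
        series = gen_activity(DEFAULT_GENOTYPES["per_s"], dd_regime(14.0),
                              seed=21)
        r = chi_square_periodogram(series)
        assert abs(r.peak_period - 19.0) <= 0.1 + 1e-9

    def test_arrhythmic_genotype_has_no_prominent_peak(self):
        # an uncorrected 211-point scan crosses the per-period 5% line by
        # chance on pure noise, so the discriminating property is peak
        # prominence: flat generators sit near the line, rhythmic ones far
        # above it
        flat = chi_square_periodogram(
            gen_activity(DEFAULT_GENOTYPES["per_0"], dd_regime(14.0), seed=22))
        rhythmic = chi_square_periodogram(
            gen_activity(DEFAULT_GENOTYPES["per_s"], dd_regime(14.0), seed=22))
        i_flat = int(np.argmax(flat.qp - flat.threshold))
        i_rhy = int(np.argmax(rhythmic.qp - rhythmic.threshold))
        assert flat.peak_qp / flat.threshold[i_flat] < 1.3
        assert rhythmic.peak_qp / rhythmic.threshold[i_rhy] > 2.0


class TestCompetitionGenerator:
    def test_neutral_mean_stays_inside_sample_envelope(self):
        cfg = DriftConfig(n_censuses=5, replicates=10_000, seed=31)
        env = neutral_envelopes(cfg)
        rng = np.random.default_rng(32)
        _, samp = simulate_selected_frequencies(cfg, SelectionParams(), 1_000,
                                                rng)
        mean = samp.mean(axis=2)
        inside = ((mean >= env.samp_lo) & (mean <= env.samp_hi)).mean(axis=0)
        assert np.all(inside[1:] >= 0.90)  # ~95% by construction

    def test_halved_mutant_viability_drops_below_envelope(self):
        cfg = DriftConfig(n_censuses=5, replicates=10_000, seed=33)
        env = neutral_envelopes(cfg)
        sel = SelectionParams(viability_male_mut=0.5,
                              viability_female_mm=0.5)
        _, samp = simulate_selected_frequencies(cfg, sel, 200,
                                                np.random.default_rng(34))
        mean5 = samp.mean(axis=2)[:, 5]
        assert (mean5 < env.samp_lo[5]).mean() >= 0.99

    def test_declining_frequency_under_strong_selection(self):
        cfg = DriftConfig(n_censuses=5, replicates=1_000)
        sel = SelectionParams(viability_male_mut=0.5,
                              viability_female_mm=0.5)
        records = gen_competition(cfg, sel, seed=35)
        traj = census_frequencies(records, mutant_classes=("short",))
        assert traj.mean[0] == pytest.approx(0.5)
        assert traj.mean[-1] < 0.2
        assert traj.mean[-1] < traj.mean[1]

    def test_census_records_have_expected_shape(self):
        cfg = DriftConfig(n_censuses=2, replicates=1_000)
        records = gen_competition(cfg, seed=36)
        assert len(records) == cfg.n_vials * (cfg.n_censuses + 1)
        later = [r for r in records if r.census > 0]
        assert all(len(r.calls) == 32 for r in later)

    def test_all_zero_viabilities_rejected(self):
        with pytest.raises(DomainError):
            SelectionParams(viability_male_wt=0.0, viability_male_mut=0.0)


class TestMatingTrialGenerator:
    def test_no_effects_choose_evenly(self):
        model = AdditiveAttractiveness(A=1.0, a_m=0.0, a_x=0.0)
        assert model.p_alpha == pytest.approx(0.5)
        assert model.p_beta == pytest.approx(0.5)
        rng = np.random.default_rng(41)
        arm_a, arm_b = gen_mating_trials(model, n_per_arm=4000,
                                         mating_success=1.0, seed=rng)
        assert arm_a.chose_mutant / arm_a.matings == pytest.approx(0.5,
                                                                   abs=0.03)
        assert arm_b.chose_mutant / arm_b.matings == pytest.approx(0.5,
                                                                   abs=0.03)

    def test_worked_example_arm_probabilities(self):
        model = AdditiveAttractiveness(A=1.0, a_m=0.5, a_x=0.2)
        assert model.p_alpha == pytest.approx(1.5 / 2.7)
        assert model.p_beta == pytest.approx(1.7 / 2.7)

    def test_estimator_round_trip_recovers_pm(self):
        model = AdditiveAttractiveness(A=1.0, a_m=0.5, a_x=0.2)  # p_m = 0.6
        arm_a, arm_b = gen_mating_trials(model, n_per_arm=20_000,
                                         mating_success=1.0, seed=42)
        est = mc_confidence_interval(arm_a, arm_b, n_replicates=10_000,
                                     seed=43)
        assert est.p_m == pytest.approx(0.6, abs=0.02)

    def test_matings_bounded_by_trials(self):
        model = AdditiveAttractiveness()
        arm_a, arm_b = gen_mating_trials(model, n_per_arm=100,
                                         mating_success=0.3, seed=44)
        for arm in (arm_a, arm_b):
            assert 0 <= arm.chose_mutant <= arm.matings <= arm.trials


class TestSurvivalGenerator:
    def test_perfect_rates_fill_every_vial(self):
        assays = gen_survival_assay({"g": (1.0, 1.0)}, seed=51)
        assert assays["g"].pupae == [100] * 10
        assert assays["g"].adults == [100] * 10

    def test_zero_rate_yields_no_pupae(self):
        assays = gen_survival_assay({"g": (0.0, 1.0)}, seed=52)
        assert assays["g"].pupae == [0] * 10

    def test_default_rates_recovered_within_binomial_error(self):
        assays = gen_survival_assay(seed=53)
        for genotype, rate in EGG_TO_PUPA.items():
            est = survival_rates(assays[genotype]).s_e
            se = np.sqrt(rate * (1 - rate) / 1000)
            assert abs(est - rate) <= 3 * se


class TestCountGenerator:
    def test_poisson_limit_at_infinite_dispersion(self):
        values = np.array(gen_counts(50.0, n=100_000, dispersion=np.inf,
                                     seed=61))
        ratio = values.var() / values.mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_default_dispersion_is_overdispersed(self):
        values = np.array(gen_counts(100.0, n=100_000, seed=62))
        ratio = values.var() / values.mean()
        assert ratio == pytest.approx(4.0, abs=0.3)

    def test_sample_mean_recovers_input_mean(self):
        mean = 949.0
        values = np.array(gen_counts(mean, n=10_000, seed=63))
        se = values.std() / np.sqrt(len(values))
        assert abs(values.mean() - mean) <= 3 * se

    def test_zero_draws_rejected(self):
        with pytest.raises(DomainError):
            gen_counts(10.0, n=0)

    def test_seeded_counts_reproducible(self):
        assert gen_counts(30.0, n=10, seed=64) == gen_counts(30.0, n=10,
                                                             seed=64)
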