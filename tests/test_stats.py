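"""Discriminability, hypothesis tests, and coding classifications."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from raphetag.rates import epoch_firing_rates, spike_density
from raphetag.session import TaskConfig
from raphetag.simulate import (
    NeuronProfile,
    generate_lick_train,
    generate_spike_train,
    generate_task_schedule,
)
from raphetag.stats import (
    anticipatory_lick_test,
    auroc_trace_for_condition,
    block_tone_lick_test,
    choice_preference_test,
    classify_value_salience,
    cohens_u3,
    count_proportion,
    expected_vs_unexpected,
    feature_correlation,
    firing_rate_drift,
    mann_whitney_auroc,
    peak_latency,
    proportion_bins_test,
    rate_comparison,
    response_duration,
    reward_size_monotonicity,
    sliding_auroc,
    task_modulation_anova,
    within_block_dynamics,
)


def auroc_pair_count_oracle(a, b):
    """Exhaustive concordant-pair count: (#{a > b} + 0.5 #{a = b}) / (n1 n2)."""
    wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    return wins / (len(a) * len(b))


class TestAuroc:
    def test_identical_samples_exactly_half(self, rng):
        x = rng.normal(5, 2, 30)
        assert mann_whitney_auroc(x, x.copy()) == 0.5

    def test_complete_separation_is_one(self):
        assert mann_whitney_auroc(np.arange(10, 20), np.arange(10)) == 1.0

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_pair_count_oracle(self, seed):
        r = np.random.default_rng(seed)
        n1, n2 = r.integers(2, 15, size=2)
        # integer-valued rates force ties
        a = r.integers(0, 6, n1).astype(float)
        b = r.integers(0, 6, n2).astype(float)
        assert mann_whitney_auroc(a, b) == pytest.approx(
            auroc_pair_count_oracle(a, b), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_antisymmetry(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(0, 5, 8).astype(float)
        b = r.integers(0, 5, 12).astype(float)
        assert mann_whitney_auroc(a, b) + mann_whitney_auroc(b, a) \
            == pytest.approx(1.0)

    def test_sliding_trace_flags_injected_response(self):
        """A unit excited for ~300 ms after punishment onset produces a
        significant auROC excursion of about that duration."""
        r = np.random.default_rng(8)
        cfg = TaskConfig(n_trials_total=120)
        blocks, trials = generate_task_schedule(cfg, r)
        profile = NeuronProfile(
            unit_id="u", baseline_rate=5.0,
            us_response={"punishment_air": (15.0, 0.0, 300.0)})
        span = trials["us_onset_s"].max() + 5
        spikes = generate_spike_train(profile, blocks, trials, span, r)
        trace = auroc_trace_for_condition(spikes, trials, "punishment_air",
                                          window=(0.0, 2.5))
        us_bins = (trace.bin_centers_s >= 2.0) & (trace.bin_centers_s < 2.5)
        dur = response_duration(trace.p_values[us_bins], trace.alpha,
                                trace.bonferroni_m)
        assert dur == pytest.approx(300.0, abs=100.0)
        # pre-outcome bins stay near 0.5
        cs_pre = trace.auroc[trace.bin_centers_s < 1.0]
        assert np.all(np.abs(cs_pre - 0.5) < 0.2)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            sliding_auroc(np.zeros((3, 5)), np.zeros(5), np.ones(10))


class TestResponseDuration:
    def test_no_significant_bins_zero(self):
        assert response_duration(np.ones(25), 0.05) == 0.0

    def test_counts_corrected_bins(self):
        p = np.array([1e-6, 1e-6, 0.04, 1.0])
        # Bonferroni m=4: only the 1e-6 bins survive
        assert response_duration(p, 0.05) == 200.0


class TestRateComparison:
    def test_identical_samples_flat(self):
        x = np.full(10, 3.0)
        res = rate_comparison(x, x)
        assert res.p_value == 1.0 and res.direction == "none"

    def test_power_for_two_hz_gain(self):
        """Pre-trial rates 6 vs 4 spikes/s (2-s windows, 30 trials each):
        detected at alpha = 0.05 with direction + in >= 90% of seeds."""
        hits = 0
        n_seeds = 300
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            a = r.poisson(6.0 * 2.0, 30) / 2.0
            b = r.poisson(4.0 * 2.0, 30) / 2.0
            res = rate_comparison(a, b)
            hits += (res.p_value < 0.05) and res.direction == "+"
        assert hits / n_seeds >= 0.90

    def test_null_false_positive_rate(self):
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            r = np.random.default_rng(10_000 + seed)
            a = r.poisson(8, 30) / 2.0
            b = r.poisson(8, 30) / 2.0
            hits += rate_comparison(a, b).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(hits / n_seeds - 0.05) < 3 * se


class TestCohensU3:
    def test_identical_distributions_half(self, rng):
        a = rng.normal(size=5001)
        b = a.copy()
        assert cohens_u3(a, b) == pytest.approx(0.5, abs=0.01)

    def test_fully_shifted_is_one(self):
        assert cohens_u3(np.arange(10, 20), np.arange(10)) == 1.0

    def test_unit_shift_normal_matches_phi(self, rng):
        a = rng.normal(1.0, 1.0, 200_000)
        b = rng.normal(0.0, 1.0, 200_000)
        assert cohens_u3(a, b) == pytest.approx(sps.norm.cdf(1.0), abs=0.01)


class TestFeatureCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = feature_correlation(x, 2 * x + 1)
        assert res.direction == "+" and res.p_value < 1e-9

    def test_t_statistic_formula(self, rng):
        """With sample r exactly 0.60 and n = 29, t = 0.6 sqrt(27)/0.8 =
        3.8971 (printed values round the unrounded r to 3.89)."""
        x = rng.normal(size=29)
        e = rng.normal(size=29)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)  # orthogonalize
        e /= e.std()
        y = 0.6 * x + np.sqrt(1 - 0.36) * e
        res = feature_correlation(x, y)
        assert res.statistic == pytest.approx(0.6 * np.sqrt(27) / 0.8, abs=1e-6)
        assert res.p_value < 0.01

    def test_null_type_one_error(self):
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            hits += feature_correlation(r.normal(size=29),
                                        r.normal(size=29)).p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(hits / n_seeds - 0.05) < 3 * se

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            feature_correlation(np.ones(5), np.arange(5.0))


class TestDrift:
    def test_exact_linear_recovery(self):
        y = 5.0 - 0.01 * np.arange(50)
        slope, res = firing_rate_drift(y)
        assert slope == pytest.approx(-0.01, abs=1e-9)
        assert res.direction == "-"

    def test_constant_input(self):
        slope, res = firing_rate_drift(np.full(20, 3.0))
        assert slope == 0.0 and res.p_value == 1.0

    def test_generative_drift_recovered(self):
        """-0.5 spikes/s per hour across a 533-trial session: negative and
        significant in >= 90% of seeds."""
        n_trials = 533
        trial_times = np.arange(n_trials) * 12.5  # ~1.85 h session
        base = 5.0
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            lam = base - 0.5 * trial_times / 3600.0
            rates = r.poisson(lam * 2.0) / 2.0
            slope, res = firing_rate_drift(rates)
            hits += (res.direction == "-") and (res.p_value < 0.05)
        assert hits / n_seeds >= 0.90

    def test_shuffled_rates_at_nominal_alpha(self):
        hits = 0
        n_seeds = 400
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            rates = r.poisson(10.0, 100) / 2.0
            _, res = firing_rate_drift(r.permutation(rates))
            hits += res.p_value < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(hits / n_seeds - 0.05) < 3 * se


class TestValueSalience:
    def groups(self, rng, r, n_mean, p, n=30, sd=1.0):
        return {"reward": rng.normal(r, sd, n),
                "neutral": rng.normal(n_mean, sd, n),
                "punishment": rng.normal(p, sd, n)}

    def test_graded_means_value(self, rng):
        assert classify_value_salience(self.groups(rng, 6, 4, 2)).label == "value"

    def test_symmetric_elevation_salience(self, rng):
        assert classify_value_salience(self.groups(rng, 6, 2, 6)).label == "salience"

    def test_symmetric_suppression_salience(self, rng):
        assert classify_value_salience(self.groups(rng, 2, 6, 2)).label == "salience"

    def test_equal_means_unclassified(self, rng):
        assert classify_value_salience(
            self.groups(rng, 4, 4, 4)).label == "unclassified"

    def test_missing_block_type_raises(self, rng):
        with pytest.raises(ValueError, match="neutral"):
            classify_value_salience({"reward": np.ones(5),
                                     "punishment": np.ones(5)})


class TestRewardSizeMonotonicity:
    def sizes(self, rng, z, s, b, n=30):
        return {"zero": rng.normal(z, 1, n), "small": rng.normal(s, 1, n),
                "big": rng.normal(b, 1, n)}

    def test_increasing(self, rng):
        assert reward_size_monotonicity(self.sizes(rng, 4, 5, 6)) == "increasing"

    def test_decreasing(self, rng):
        assert reward_size_monotonicity(self.sizes(rng, 6, 5, 4)) == "decreasing"

    def test_non_monotonic(self, rng):
        assert reward_size_monotonicity(self.sizes(rng, 4, 6, 4)) == "non_monotonic"

    def test_missing_condition_raises(self, rng):
        with pytest.raises(ValueError):
            reward_size_monotonicity({"zero": np.ones(5), "big": np.ones(5)})


class TestTaskModulationAnova:
    def epoch_table(self, seed, cs_amp=0.0, n_trials=40):
        r = np.random.default_rng(seed)
        cfg = TaskConfig(n_trials_total=n_trials)
        blocks, trials = generate_task_schedule(cfg, r)
        profile = NeuronProfile(unit_id="u", baseline_rate=5.0,
                                cs_response=({"reward_big": (cs_amp, 0.0, 1000.0)}
                                             if cs_amp else {}))
        span = trials["us_onset_s"].max() + 5
        spikes = generate_spike_train(profile, blocks, trials, span, r)
        return epoch_firing_rates(spikes, trials)

    def test_flat_unit_rarely_modulated(self):
        hits = sum(task_modulation_anova(self.epoch_table(seed))[0]
                   for seed in range(120))
        # min of three effects at alpha = 0.01 -> familywise ~3%
        assert hits / 120 <= 0.075

    def test_cs_excited_unit_detected(self):
        modulated, table = task_modulation_anova(self.epoch_table(0, cs_amp=5.0))
        assert modulated

    def test_single_outcome_type_raises(self):
        er = self.epoch_table(1)
        with pytest.raises(ValueError):
            task_modulation_anova(er[er["trial_type"] == "reward_big"])


class TestWithinBlockDynamics:
    def table(self, rates):
        n = len(rates)
        return pd.DataFrame({"trial": np.arange(n),
                             "block_id": np.arange(n) // 10,
                             "pretrial_rate": rates})

    def test_constant_rates_flat_zero_profile(self):
        prof = within_block_dynamics(self.table(np.full(40, 4.0)), 10)
        np.testing.assert_allclose(prof["z_rate"], 0.0)

    def test_exponential_approach_monotone(self, rng):
        pos = np.arange(10)
        ramp = 2.0 * (1 - np.exp(-pos / 3.0))
        rates = np.concatenate([ramp + rng.normal(0, 0.05, 10)
                                for _ in range(20)])
        prof = within_block_dynamics(self.table(rates), 10)
        assert np.all(np.diff(prof["mean_rate"]) > -0.1)
        assert prof["mean_rate"].iloc[-1] > prof["mean_rate"].iloc[0] + 1.0

    def test_single_block_z_scores_its_rates(self):
        rates = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        prof = within_block_dynamics(self.table(rates), 10)
        np.testing.assert_allclose(
            prof["z_rate"], (rates - rates.mean()) / rates.std())


class TestExpectedVsUnexpected:
    def test_identical_responses_near_zero(self, rng):
        a = rng.poisson(10, 60) / 2.0
        diff, res = expected_vs_unexpected(a, a.copy())
        assert diff == 0.0 and res.p_value > 0.9

    def test_dopaminergic_like_large_positive(self, rng):
        expected = rng.poisson(6, 60) / 2.0
        unexpected = rng.poisson(20, 60) / 2.0
        diff, res = expected_vs_unexpected(expected, unexpected)
        assert diff > 0 and res.p_value < 1e-6 and res.direction == "+"


class TestPeakLatency:
    def test_rectangular_response_peak_in_span(self):
        r = np.random.default_rng(3)
        cfg = TaskConfig(n_trials_total=100)
        blocks, trials = generate_task_schedule(cfg, r)
        profile = NeuronProfile(unit_id="u", baseline_rate=4.0,
                                cs_response={"reward_big": (15.0, 300.0, 250.0)})
        span = trials["us_onset_s"].max() + 5
        spikes = generate_spike_train(profile, blocks, trials, span, r)
        sel = trials[trials["trial_type"] == "reward_big"]
        dens = spike_density(spikes, sel["cs_onset_s"].to_numpy(), (0.0, 1.0))
        peak = peak_latency(dens.mean(), dens.time_s, (0.0, 1.0))
        assert 300.0 <= peak <= 650.0

    def test_flat_density_earliest_sample(self):
        t = np.arange(0, 1.0, 0.001)
        assert peak_latency(np.ones_like(t), t, (0.2, 0.8)) == pytest.approx(200.0)

    def test_latency_ordering_between_presets(self):
        """Generative CS latencies 330 vs 390 ms: the population peak
        ordering is recovered."""
        peaks = {}
        for lat in (330.0, 390.0):
            r = np.random.default_rng(17)
            cfg = TaskConfig(n_trials_total=80)
            blocks, trials = generate_task_schedule(cfg, r)
            profile = NeuronProfile(unit_id="u", baseline_rate=4.0,
                                    cs_response={"reward_big": (12.0, lat, 200.0)})
            span = trials["us_onset_s"].max() + 5
            spikes = generate_spike_train(profile, blocks, trials, span, r)
            sel = trials[trials["trial_type"] == "reward_big"]
            dens = spike_density(spikes, sel["cs_onset_s"].to_numpy(), (0.0, 1.0))
            peaks[lat] = peak_latency(dens.mean(), dens.time_s, (0.0, 1.0))
        assert peaks[330.0] < peaks[390.0]

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            peak_latency(np.ones(10), np.arange(10) / 10.0, (2.0, 3.0))


class TestLickTests:
    def session_licks(self, seed, anticipatory):
        r = np.random.default_rng(seed)
        cfg = TaskConfig(n_trials_total=60)
        blocks, trials = generate_task_schedule(cfg, r)
        span = trials["us_onset_s"].max() + 5
        licks = generate_lick_train(
            blocks, trials, span, r, baseline_rate=1.0,
            anticipatory_rate={"reward_big": anticipatory})
        return licks, trials

    def test_anticipatory_licking_detected(self):
        licks, trials = self.session_licks(0, 8.0)
        res = anticipatory_lick_test(licks, trials)
        assert res["anova"].p_value < 0.001
        pair = res["pairwise"][("reward_big", "punishment_air")]
        assert pair.p_value < 0.001 and pair.direction == "+"

    def test_uniform_licking_not_significant(self):
        fp = 0
        n_seeds = 200
        for seed in range(n_seeds):
            licks, trials = self.session_licks(seed, 0.0)
            res = anticipatory_lick_test(licks, trials)
            fp += res["anova"].p_value < 0.001
        assert fp / n_seeds <= 0.05  # alpha = 0.001, wide margin

    def test_no_licks_degenerate(self):
        _, trials = self.session_licks(1, 0.0)
        res = anticipatory_lick_test(np.zeros(0), trials)
        assert res["anova"].p_value == 1.0

    def test_tone_lick_paired_test(self, rng):
        a = rng.normal(5.0, 1.0, 12)
        b = a - 2.0
        res = block_tone_lick_test(a, b)
        assert res.p_value < 0.01 and res.direction == "+"
        flipped = block_tone_lick_test(b, a)
        assert flipped.direction == "-"
        same = block_tone_lick_test(a, a.copy())
        assert same.p_value == 1.0


class TestChoicePreference:
    def choices(self, rng, p, n=300):
        picks = np.where(rng.random(n) < p, "water", "water_plus_airpuff")
        return pd.DataFrame({"trial": np.arange(n), "chosen_port": picks})

    def test_all_water_proportion_one(self, rng):
        res = choice_preference_test(self.choices(rng, 1.0))
        assert res["proportion_water"] == 1.0

    def test_strong_preference_significant(self, rng):
        res = choice_preference_test(self.choices(rng, 0.9))
        assert res["test"].p_value < 1e-10 and res["test"].direction == "+"

    def test_chance_preference_type_one(self):
        fp = 0
        n_seeds = 400
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            fp += choice_preference_test(
                self.choices(r, 0.5))["test"].p_value < 0.05
        assert fp / n_seeds < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_seeds)


class TestCountProportion:
    @pytest.mark.parametrize("k,n,expected", [
        (6, 260, 2.3),
        (254, 314, 80.9),
        (0, 10, 0.0),
    ])
    def test_reported_percentages(self, k, n, expected):
        assert count_proportion(k, n)["percent"] == expected

    def test_ci_brackets_estimate(self):
        res = count_proportion(6, 260)
        assert res["ci_low_percent"] < 2.3 < res["ci_high_percent"]

    def test_zero_n_raises(self):
        with pytest.raises(ValueError):
            count_proportion(0, 0)


class TestProportionBinsTest:
    def test_identical_proportions_or_near_one(self):
        res = proportion_bins_test(10, 100, 10, 100)
        assert res["odds_ratio"] == pytest.approx(1.0, abs=0.05)
        assert res["p_value"] == 1.0

    def test_p_value_matches_hypergeometric_enumeration(self):
        """Fisher p equals the exhaustive sum of hypergeometric
        probabilities no larger than the observed table's."""
        a, ta, b, tb = 10, 100, 20, 100
        res = proportion_bins_test(a, ta, b, tb)
        K = a + b  # total significant bins
        N = ta + tb
        pmf = sps.hypergeom.pmf(np.arange(K + 1), N, K, ta)
        p_oracle = pmf[pmf <= pmf[a] * (1 + 1e-12)].sum()
        assert res["p_value"] == pytest.approx(p_oracle, rel=1e-9)

    def test_conditional_mle_odds_ratio_against_likelihood_oracle(self):
        """The reported odds ratio maximizes the Fisher noncentral
        hypergeometric likelihood of the observed table."""
        from scipy.optimize import minimize_scalar
        a, ta, b, tb = 10, 100, 20, 100
        res = proportion_bins_test(a, ta, b, tb)
        nll = lambda logpsi: -sps.nchypergeom_fisher.logpmf(
            a, ta + tb, a + b, ta, np.exp(logpsi))
        opt = minimize_scalar(nll, bounds=(-5, 5), method="bounded")
        assert res["odds_ratio"] == pytest.approx(np.exp(opt.x), rel=1e-3)

    def test_zero_margin_reported_missing(self):
        res = proportion_bins_test(0, 100, 0, 100)
        assert np.isnan(res["odds_ratio"])
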