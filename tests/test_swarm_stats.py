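"""Thresholding, fraction-above, SEM, t tests, Monte Carlo subsampling
and dose response, checked against closed forms and brute-force
enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dropswarm as dw
from dropswarm import swarm_stats as ss


class TestComputeThreshold:
    def test_hand_computed_example(self):
        model = ss.compute_threshold([10, 12, 14], k=3)
        assert model.mu0 == 12
        assert model.sigma0 == pytest.approx(2.0)
        assert model.threshold == pytest.approx(18.0)

    def test_degenerate_population_threshold_at_common_value(self):
        model = ss.compute_threshold([7.0, 7.0, 7.0])
        assert model.threshold == 7.0

    def test_k_zero_is_the_mean(self):
        model = ss.compute_threshold([1.0, 2.0, 3.0], k=0)
        assert model.threshold == pytest.approx(2.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ss.compute_threshold([1.0])


class TestFractionAbove:
    def test_trivial_cases(self):
        model = ss.ThresholdModel(mu0=2.5, sigma0=0.0)
        assert ss.fraction_above([1, 2], model) == 0.0
        assert ss.fraction_above([1, 2, 3, 4], model) == 0.5
        with pytest.raises(ValueError):
            ss.fraction_above([], model)

    def test_three_sigma_tail_of_the_negative_control_itself(self):
        rng = np.random.default_rng(123)
        neg = rng.normal(100.0, 5.0, 10 ** 5)
        model = ss.compute_threshold(neg, k=3)
        frac = ss.fraction_above(neg, model)
        p = 0.00135  # one-sided normal 3-sigma tail
        se = math.sqrt(p * (1 - p) / neg.size)
        assert abs(frac - p) <= 3 * se

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_invariant_under_increasing_affine_transform(self, scale, offset, seed):
        x = np.random.default_rng(seed).normal(10.0, 3.0, 40)
        model = ss.ThresholdModel(mu0=11.0, sigma0=0.0)
        transformed = ss.ThresholdModel(mu0=scale * 11.0 + offset, sigma0=0.0)
        assert ss.fraction_above(x, model) == ss.fraction_above(
            scale * x + offset, transformed
        )


class TestSemCurve:
    def test_closed_form_and_quadrupling(self):
        x = np.random.default_rng(0).normal(50, 10, 200)
        s = x.std(ddof=1)
        curve = ss.sem_curve(x, [1, 3, 4, 12, 80])
        np.testing.assert_allclose(curve["sem"], s / np.sqrt(curve.n))
        by_n = curve.set_index("n")["sem"]
        assert by_n[12] == pytest.approx(by_n[3] / 2)
        assert by_n[3] / by_n[80] == pytest.approx(math.sqrt(80 / 3))

    def test_relative_sem_drop_is_five_fold_from_3_to_80(self):
        """Going from 3 to 80 particles divides the relative SEM by ~5."""
        rel3 = 0.25
        x = np.random.default_rng(1).normal(1.0, rel3 * math.sqrt(3), 5000)
        curve = ss.sem_curve(x, [3, 80]).set_index("n")
        assert curve.relative_sem[3] == pytest.approx(rel3, rel=0.05)
        assert curve.relative_sem[80] < 0.05
        assert curve.relative_sem[3] / curve.relative_sem[80] == pytest.approx(
            math.sqrt(80 / 3)
        )

    def test_constant_population_has_zero_sem(self):
        curve = ss.sem_curve([4.0] * 10, [1, 5])
        np.testing.assert_array_equal(curve["sem"], 0.0)


class TestOneTailedTTest:
    def test_identical_samples_give_half(self):
        x = [1.0, 2.0, 3.0]
        assert ss.one_tailed_t_test(x, x) == pytest.approx(0.5)

    def test_well_separated_samples(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        assert ss.one_tailed_t_test(a, b) < 1e-10

    def test_swap_maps_p_to_one_minus_p(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1.5, 40)
        assert ss.one_tailed_t_test(a, b) + ss.one_tailed_t_test(b, a) == pytest.approx(1.0)

    def test_degenerate_equal_samples_return_half(self):
        assert ss.one_tailed_t_test([2.0, 2.0], [2.0, 2.0]) == 0.5


class TestClassifySample:
    def test_all_below_is_negative(self):
        model = ss.ThresholdModel(mu0=10.0, sigma0=1.0)
        assert ss.classify_sample([1, 2, 3], model) == "negative"

    def test_single_exceedance_is_positive_by_default(self):
        model = ss.ThresholdModel(mu0=10.0, sigma0=1.0)
        assert ss.classify_sample([1, 2, 14], model) == "positive"

    def test_fraction_cutoff_rule(self):
        model = ss.ThresholdModel(mu0=0.0, sigma0=0.0)
        rule = ss.ClassificationRule(min_fraction=0.5)
        x = [-1, -1, -1, 1, 1]  # fraction above = 0.4
        assert ss.classify_sample(x, model, rule) == "negative"


class TestMonteCarloSubsample:
    def _result(self, neg, pos, n_values, reps=2000, seed=0, rule=None):
        model = ss.compute_threshold(neg)
        cfg = ss.MonteCarloConfig(n_values=tuple(n_values), reps=reps, seed=seed)
        return ss.monte_carlo_subsample(
            neg, pos, model, cfg, rule or ss.ClassificationRule()
        )

    def test_full_population_subset_has_zero_spread(self):
        rng = np.random.default_rng(2)
        neg, pos = rng.normal(100, 5, 20), rng.normal(150, 10, 20)
        res = self._result(neg, pos, [20], reps=100)
        assert res.sd_mean_intensity[0] < 1e-12  # exhausts the population each draw
        assert res.sd_fraction_above[0] == 0.0
        assert res.sd_p_value[0] < 1e-12

    def test_disjoint_populations_never_false_negative(self):
        rng = np.random.default_rng(3)
        neg, pos = rng.normal(100, 5, 60), rng.normal(200, 5, 60)
        res = self._result(neg, pos, [1, 5, 20], reps=500)
        np.testing.assert_array_equal(res.false_negative_rate, 0.0)

    def test_false_negative_rate_matches_hypergeometric_enumeration(self):
        """Brute force over all subsets of an N = 12 population."""
        rng = np.random.default_rng(4)
        neg = rng.normal(100.0, 5.0, 40)
        model = ss.compute_threshold(neg)
        k_above = 4
        pos = np.concatenate(
            [
                np.linspace(90, 110, 12 - k_above),  # below threshold
                np.full(k_above, model.threshold + 50),
            ]
        )
        n_values = [1, 2, 3, 6, 9, 12]
        reps = 5000
        res = ss.monte_carlo_subsample(
            neg, pos, model,
            ss.MonteCarloConfig(n_values=tuple(n_values), reps=reps, seed=9),
        ).set_index("n")
        above = pos > model.threshold
        for n in n_values:
            exact = np.mean(
                [
                    not any(above[list(idx)])
                    for idx in itertools.combinations(range(12), n)
                ]
            )
            se = math.sqrt(max(exact * (1 - exact), 1e-12) / reps)
            assert abs(res.false_negative_rate[n] - exact) <= max(3 * se, 1e-9)
        fn = res.false_negative_rate.to_numpy()
        assert np.all(np.diff(fn) <= 1e-9)  # non-increasing in n

    def test_subset_mean_spread_matches_enumeration(self):
        """Without-replacement SD of the subset mean on a fixed population."""
        rng = np.random.default_rng(8)
        neg = rng.normal(0, 1, 30)
        pos = rng.normal(3, 2, 10)
        n = 4
        res = self._result(neg, pos, [n], reps=5000, seed=13)
        means = [
            pos[list(idx)].mean() for idx in itertools.combinations(range(10), n)
        ]
        exact_sd = np.std(means)
        assert res.sd_mean_intensity[0] == pytest.approx(exact_sd, rel=0.1)

    def test_oversized_subset_rejected(self):
        rng = np.random.default_rng(10)
        neg, pos = rng.normal(0, 1, 30), rng.normal(1, 1, 5)
        with pytest.raises(ValueError, match="exceeds population"):
            self._result(neg, pos, [6], reps=10)

    def test_deterministic_and_order_independent(self):
        rng = np.random.default_rng(11)
        neg, pos = rng.normal(100, 5, 40), rng.normal(120, 10, 40)
        a = self._result(neg, pos, [2, 5, 10], reps=200, seed=21)
        b = self._result(neg, pos, [10, 2, 5], reps=200, seed=21)
        merged = a.merge(b, on="n", suffixes=("_a", "_b"))
        np.testing.assert_allclose(
            merged.mean_fraction_above_a, merged.mean_fraction_above_b
        )
        np.testing.assert_allclose(
            merged.mean_mean_intensity_a, merged.mean_mean_intensity_b
        )


class TestCompareMethods:
    def test_identical_repeats_give_half_for_both(self):
        rng = np.random.default_rng(14)
        repeats = [rng.normal(100, 5, 60) for _ in range(3)]
        p_fraction, p_mean = ss.compare_methods(repeats, repeats)
        assert p_fraction == pytest.approx(0.5)
        assert p_mean == pytest.approx(0.5)

    def test_three_repeats_return_finite_p_values(self):
        rng = np.random.default_rng(15)
        neg = [rng.normal(100, 5, 80) for _ in range(3)]
        pos = [rng.normal(130, 8, 80) for _ in range(3)]
        p_fraction, p_mean = ss.compare_methods(neg, pos)
        assert 0 <= p_fraction <= 1 and 0 <= p_mean <= 1

    def test_shared_background_drift_favors_fraction_method(self):
        """Per-repeat background shifts cancel in the fraction statistic."""
        wins = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            neg, pos = [], []
            for _ in range(3):
                drift = rng.normal(0.0, 15.0)  # shared within a repeat
                neg.append(rng.normal(100 + drift, 5.0, 80))
                pos.append(rng.normal(130 + drift, 8.0, 80))
            p_fraction, p_mean = ss.compare_methods(neg, pos)
            wins += p_fraction < p_mean
        assert wins / n_seeds >= 0.8


class TestFitDoseResponse:
    def _table(self, conc_to_values):
        rows = []
        for c, values in conc_to_values.items():
            for v in values:
                rows.append({"condition": c, "mean_intensity": v, "roi_mode": "combined"})
        return pd.DataFrame(rows)

    def test_exact_linear_means_recovered(self):
        table = self._table({c: [2.0 + 3.0 * c] * 4 for c in [0.0, 0.5, 1.0, 2.0]})
        fit = ss.fit_dose_response(
            table, threshold_model=ss.ThresholdModel(mu0=2.0, sigma0=0.1)
        )
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_lod_is_first_exceeding_dose_by_construction(self):
        doses = [0.0, 0.05, 0.1, 1.0]
        table = pd.concat(
            [
                pd.DataFrame(
                    {
                        "condition": c,
                        "mean_intensity": dw.sample_intensity_population(
                            c, 80, dose_params=(60.0, 1.0, 100.0), cv=0.05, seed=17
                        ),
                        "roi_mode": "combined",
                    }
                )
                for c in doses
            ],
            ignore_index=True,
        )
        fit = ss.fit_dose_response(table)
        assert fit.lod_estimate == 0.05

    def test_flat_response_reports_not_detected(self):
        table = self._table({c: [5.0, 5.1, 4.9] for c in [0.0, 1.0, 2.0]})
        fit = ss.fit_dose_response(table)
        assert fit.lod_estimate is None

    def test_too_few_concentrations_rejected(self):
        table = self._table({0.0: [1.0, 1.1], 1.0: [2.0, 2.1]})
        with pytest.raises(ValueError):
            ss.fit_dose_response(table)
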