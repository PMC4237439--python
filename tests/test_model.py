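import math

import numpy as np
import pytest

from conftest import crisp_two_domain_dataset, make_fitted_model
from tsimpact.errors import NotFittedError, ValidationError
from tsimpact.model import (
    HIGH,
    LOW,
    Rule,
    TSModel,
    build_rule_grid,
    coefficient_cis,
    fit_consequents,
    fit_ts,
    firing_strengths,
    predict,
    summarize_coefficients,
)
from tsimpact.partition import partitions_from_bounds
from tsimpact.synthetic import DOMAINS, GeneratorConfig, generate_areas, scores_matrix


class TestRuleGrid:
    def test_six_domains_give_64_rules(self):
        parts = partitions_from_bounds({name: (20.0, 40.0) for name in DOMAINS})
        rules = build_rule_grid(parts)
        assert len(rules) == 64

    def test_one_domain_gives_two_rules(self):
        rules = build_rule_grid(partitions_from_bounds({"x": (20.0, 40.0)}))
        assert [r.antecedent for r in rules] == [(LOW,), (HIGH,)]

    def test_all_patterns_distinct_and_ordered(self, toy_partitions):
        rules = build_rule_grid(toy_partitions)
        patterns = [r.antecedent for r in rules]
        assert len(set(patterns)) == len(patterns) == 4
        assert patterns[0] == (LOW, LOW) and patterns[-1] == (HIGH, HIGH)


class TestFiringStrengths:
    def test_hand_computed_product(self, toy_partitions):
        # choose x where the low memberships are exactly 0.5 and 0.8
        sigma = 5.0
        x1 = 20.0 + sigma * math.sqrt(2 * math.log(1 / 0.5))
        x2 = 20.0 + sigma * math.sqrt(2 * math.log(1 / 0.8))
        model = TSModel(("d1", "d2"), toy_partitions, build_rule_grid(toy_partitions))
        w, v = firing_strengths(model, np.array([x1, x2]))
        assert w[0] == pytest.approx(0.5 * 0.8, abs=1e-12)

    def test_partition_of_unity(self, toy_partitions, rng):
        model = TSModel(("d1", "d2"), toy_partitions, build_rule_grid(toy_partitions))
        X = rng.uniform(0, 100, size=(1000, 2))
        _, V = firing_strengths(model, X)
        assert np.allclose(V.sum(axis=1), 1.0, atol=1e-12)

    def test_exclusive_core_point(self, crisp_partitions):
        model = TSModel(("d1", "d2"), crisp_partitions, build_rule_grid(crisp_partitions))
        w, v = firing_strengths(model, np.array([5.0, 95.0]))  # low, high
        assert w[1] == pytest.approx(1.0)  # rule (low, high)
        assert v[1] == pytest.approx(1.0)
        assert w[2] == 0.0  # rule (high, low): both flanks underflow

    def test_all_zero_fallback_spreads_uniformly(self):
        parts = partitions_from_bounds({"d1": (20.0, 80.0)}, flank_width=1e-3)
        rules = [Rule(0, (LOW,), 1.0, np.zeros(1)), Rule(1, (HIGH,), 2.0, np.zeros(1))]
        model = TSModel(("d1",), parts, rules, fitted=True)
        with pytest.warns(RuntimeWarning):
            w, v = firing_strengths(model, np.array([50.0]))
        assert np.allclose(v, 0.5)


class TestConsequentFit:
    def test_one_rule_model_reduces_to_ols(self, rng):
        """With a single always-on rule the weighted fit is plain least squares."""
        parts = partitions_from_bounds({"d1": (99.0, 99.5), "d2": (99.0, 99.5)},
                                       flank_width=5.0)
        rules = [Rule(0, (LOW, LOW))]
        X = rng.uniform(0, 90, size=(100, 2))
        y = 3.0 + 0.5 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(0, 1, 100)
        for weighting in ("normalized", "membership"):
            model = TSModel(("d1", "d2"), parts, [Rule(0, (LOW, LOW))])
            fit_consequents(model, X, y, weighting=weighting)
            beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(100), X]), y, rcond=None)
            assert model.rules[0].intercept == pytest.approx(beta[0], abs=1e-8)
            assert np.allclose(model.rules[0].slopes, beta[1:], atol=1e-8)

    def test_noise_free_recovery_with_separated_cores(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng)
        model = TSModel(truth.domains, truth.partitions,
                        build_rule_grid(truth.partitions))
        fit_consequents(model, X, y)
        for fitted, true in zip(model.rules, truth.rules):
            assert np.allclose(fitted.slopes, true.slopes, atol=0.01)
            assert fitted.intercept == pytest.approx(true.intercept, abs=0.5)

    def test_duplicated_rows_leave_fit_unchanged(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng, n_per_region=20)
        m1 = TSModel(truth.domains, truth.partitions, build_rule_grid(truth.partitions))
        fit_consequents(m1, X, y)
        m2 = TSModel(truth.domains, truth.partitions, build_rule_grid(truth.partitions))
        fit_consequents(m2, np.vstack([X, X]), np.concatenate([y, y]))
        for r1, r2 in zip(m1.rules, m2.rules):
            assert np.allclose(r1.slopes, r2.slopes, atol=1e-9)

    def test_low_support_rule_frozen(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng, n_per_region=20)
        # remove one corner entirely: its rule has ~zero support
        keep = ~((X[:, 0] > 50) & (X[:, 1] > 50))
        model = TSModel(truth.domains, truth.partitions, build_rule_grid(truth.partitions))
        fit_consequents(model, X[keep], y[keep])
        assert np.allclose(model.rules[3].slopes, 0.0)

    def test_empty_training_raises(self, crisp_partitions):
        model = TSModel(("d1", "d2"), crisp_partitions, build_rule_grid(crisp_partitions))
        with pytest.raises(ValidationError):
            fit_consequents(model, np.empty((0, 2)), np.empty(0))


class TestPredict:
    def test_unfitted_raises(self, toy_partitions):
        model = TSModel(("d1", "d2"), toy_partitions, build_rule_grid(toy_partitions))
        with pytest.raises(NotFittedError):
            predict(model, np.array([10.0, 10.0]))

    def test_one_rule_model_is_linear(self, rng):
        parts = partitions_from_bounds({"d1": (99.0, 99.5)}, flank_width=5.0)
        model = TSModel(("d1",), parts, [Rule(0, (LOW,), 5.0, np.array([0.3]))], fitted=True)
        x = rng.uniform(0, 90, size=(20, 1))
        assert np.allclose(predict(model, x), 5.0 + 0.3 * x[:, 0])

    def test_exclusive_core_matches_local_model(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng)
        x = np.array([10.0, 10.0])
        assert predict(truth, x) == pytest.approx(truth.rules[0].linear_output(x), abs=1e-10)

    def test_convexity_of_fused_prediction(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng)
        pts = rng.uniform(0, 100, size=(1000, 2))
        Y = np.column_stack([r.linear_output(pts) for r in truth.rules])
        pred = predict(truth, pts)
        assert np.all(pred >= Y.min(axis=1) - 1e-9)
        assert np.all(pred <= Y.max(axis=1) + 1e-9)

    def test_matches_independent_direct_evaluation(self, rng):
        """Fused output equals a separately coded rule-by-rule evaluation."""
        cfg = GeneratorConfig()
        truth = cfg.truth_model()
        pts = rng.uniform(0, 100, size=(100, 6))
        for x in pts:
            num, den = 0.0, 0.0
            for rule in truth.rules:
                w = 1.0
                for j, lab in enumerate(rule.antecedent):
                    part = truth.partitions[j]
                    fset = part.high_set if lab == HIGH else part.low_set
                    lo, hi = fset.core
                    if x[j] < lo:
                        mu = math.exp(-((lo - x[j]) ** 2) / (2 * fset.flank_width**2))
                    elif x[j] > hi:
                        mu = math.exp(-((x[j] - hi) ** 2) / (2 * fset.flank_width**2))
                    else:
                        mu = 1.0
                    w *= mu
                yi = rule.intercept + float(np.dot(rule.slopes, x))
                num += w * yi
                den += w
            assert predict(truth, x) == pytest.approx(num / den, abs=1e-12)


class TestCoefficientCIs:
    def test_noise_free_cis_are_tight(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng)
        model = TSModel(truth.domains, truth.partitions, build_rule_grid(truth.partitions))
        fit_consequents(model, X, y)
        cis = coefficient_cis(model, X, y)
        for ci in cis:
            width = ci.upper - ci.lower
            assert np.all(width[np.isfinite(width)] < 1e-5)

    def test_bounds_bracket_estimates(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng, noise_sd=2.0)
        model = TSModel(truth.domains, truth.partitions, build_rule_grid(truth.partitions))
        fit_consequents(model, X, y)
        for ci in coefficient_cis(model, X, y):
            assert np.all(ci.lower <= ci.estimate + 1e-12)
            assert np.all(ci.estimate <= ci.upper + 1e-12)

    def test_bootstrap_and_analytic_agree(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng, noise_sd=2.0)
        model = TSModel(truth.domains, truth.partitions, build_rule_grid(truth.partitions))
        fit_consequents(model, X, y)
        analytic = coefficient_cis(model, X, y, method="analytic")
        boot = coefficient_cis(model, X, y, method="bootstrap", n_boot=200, seed=0)
        for ca, cb in zip(analytic, boot):
            # intervals for every coefficient overlap
            assert np.all(np.maximum(ca.lower, cb.lower) <= np.minimum(ca.upper, cb.upper))

    def test_zero_support_rule_unbounded_ci(self, rng):
        parts = partitions_from_bounds({"d1": (20.0, 80.0)}, flank_width=2.0)
        rules = [Rule(0, (LOW,)), Rule(1, (HIGH,))]
        model = TSModel(("d1",), parts, rules)
        x = rng.uniform(0, 15, size=(30, 1))
        y = 1.0 + 0.1 * x[:, 0]
        fit_consequents(model, x, y)
        with pytest.warns(RuntimeWarning):
            cis = coefficient_cis(model, x, y)
        assert np.all(np.isinf(cis[1].lower)) and np.all(np.isinf(cis[1].upper))


class TestSummaries:
    def test_single_rule_summary_collapses(self):
        parts = partitions_from_bounds({"d1": (99.0, 99.5)}, flank_width=5.0)
        model = TSModel(("d1",), parts, [Rule(0, (LOW,), 5.0, np.array([0.3]))], fitted=True)
        table = summarize_coefficients(model)
        assert table.loc["Minimum", "D1"] == table.loc["Maximum", "D1"] == table.loc["Mean", "D1"]

    def test_mean_is_arithmetic_mean(self, rng):
        X, y, truth = crisp_two_domain_dataset(rng)
        table = summarize_coefficients(truth)
        coefs = np.array([r.slopes for r in truth.rules])
        assert table.loc["Mean", "D1"] == pytest.approx(coefs[:, 0].mean(), abs=1e-12)

    def test_summary_brackets_generator_coefficients(self):
        cfg = GeneratorConfig()
        table = summarize_coefficients(cfg.truth_model())
        for j, name in enumerate(DOMAINS):
            col = name.capitalize()
            slopes = [r.slopes[j] for r in cfg.truth_rules]
            assert table.loc["Minimum", col] == pytest.approx(min(slopes))
            assert table.loc["Maximum", col] == pytest.approx(max(slopes))


def test_fit_ts_full_pipeline_smoke():
    areas = generate_areas(GeneratorConfig(n_areas=400, seed=9))
    X, y = scores_matrix(areas), areas["eur"].to_numpy()
    model = fit_ts(X, y, DOMAINS, seed=9)
    assert model.fitted and len(model.rules) == 64
    pred = predict(model, X)
    assert np.sqrt(np.mean((pred - y) ** 2)) < 10.0
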