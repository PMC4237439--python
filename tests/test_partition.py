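import numpy as np
import pytest

from tsimpact.errors import PartitionError, ValidationError
from tsimpact.partition import (
    FCMResult,
    FuzzySet,
    HIGH_LABEL,
    LOW_LABEL,
    fit_fcm,
    fit_partitions,
    membership,
    partitions_from_bounds,
    project_partitions,
)
from tsimpact.synthetic import CORE_BOUNDS, DOMAINS, GeneratorConfig, generate_areas, scores_matrix


def brute_force_fcm(X, n_clusters, m, seed, n_iter=200):
    """Independent naive alternating optimization, plain Python loops."""
    rng = np.random.default_rng(seed)
    n, d = X.shape
    U = rng.uniform(size=(n, n_clusters))
    U = U / U.sum(axis=1, keepdims=True)
    for _ in range(n_iter):
        V = np.zeros((n_clusters, d))
        for k in range(n_clusters):
            num = np.zeros(d)
            den = 0.0
            for i in range(n):
                num += (U[i, k] ** m) * X[i]
                den += U[i, k] ** m
            V[k] = num / den
        U_new = np.zeros_like(U)
        for i in range(n):
            dists = [np.sum((X[i] - V[k]) ** 2) for k in range(n_clusters)]
            if min(dists) < 1e-24:
                k0 = int(np.argmin(dists))
                U_new[i, k0] = 1.0
            else:
                for k in range(n_clusters):
                    U_new[i, k] = 1.0 / sum(
                        (dists[k] / dists[l]) ** (1.0 / (m - 1.0)) for l in range(n_clusters)
                    )
        U = U_new
    return V, U


class TestFCM:
    def test_matches_brute_force_oracle(self, rng):
        """Memberships agree with an independently coded naive optimizer."""
        X = np.vstack([rng.normal((10, 10), 2, (10, 2)), rng.normal((60, 70), 3, (10, 2))])
        res = fit_fcm(X, n_clusters=2, fuzzifier=2.0, tol=1e-12, max_iter=500, seed=7)
        V_ref, U_ref = brute_force_fcm(X, 2, 2.0, seed=7)
        # clusters may come out in either order
        if np.linalg.norm(res.prototypes[0] - V_ref[0]) > np.linalg.norm(
            res.prototypes[0] - V_ref[1]
        ):
            V_ref, U_ref = V_ref[::-1], U_ref[:, ::-1]
        assert np.allclose(res.membership_matrix, U_ref, atol=1e-6)
        assert np.allclose(res.prototypes, V_ref, atol=1e-6)

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.uniform(0, 100, size=(80, 3))
        res = fit_fcm(X, n_clusters=3, seed=1)
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8 * trace[0])

    def test_two_separated_blobs_1d(self, rng):
        x = np.concatenate([rng.normal(10, 0.5, 30), rng.normal(90, 0.5, 30)])
        res = fit_fcm(x, n_clusters=2, seed=0)
        protos = np.sort(res.prototypes[:, 0])
        assert abs(protos[0] - 10) < 1.0 and abs(protos[1] - 90) < 1.0

    def test_single_cluster_degenerates_to_mean(self, rng):
        X = rng.uniform(0, 100, size=(20, 2))
        res = fit_fcm(X, n_clusters=1, seed=0)
        assert np.allclose(res.membership_matrix, 1.0)
        assert np.allclose(res.prototypes[0], X.mean(axis=0))

    def test_point_coincident_with_prototype(self):
        x = np.array([[0.0], [0.0], [100.0], [100.0]])
        res = fit_fcm(x, n_clusters=2, tol=1e-12, seed=3)
        lo = int(np.argmin(res.prototypes[:, 0]))
        assert res.membership_matrix[0, lo] == pytest.approx(1.0)
        assert res.membership_matrix[2, 1 - lo] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, rng):
        X = rng.uniform(0, 100, size=(50, 4))
        res = fit_fcm(X, n_clusters=3, seed=5)
        assert np.allclose(res.membership_matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            fit_fcm(np.array([[np.nan]]), 1)
        with pytest.raises(ValidationError):
            fit_fcm(np.zeros((5, 2)), 2, fuzzifier=1.0)
        with pytest.raises(ValidationError):
            fit_fcm(np.zeros((1, 2)), 2)


class TestMembership:
    def test_core_membership_is_one(self):
        low = FuzzySet(LOW_LABEL, (0.0, 11.71), 5.0)
        high = FuzzySet(HIGH_LABEL, (36.56, 100.0), 5.0)
        assert membership(low, 5.0) == 1.0
        assert membership(high, 50.0) == 1.0
        assert membership(low, 11.71) == 1.0  # core edge
        assert membership(high, 36.56) == 1.0

    def test_continuity_at_core_edge(self):
        low = FuzzySet(LOW_LABEL, (0.0, 20.0), 5.0)
        eps = 1e-7
        assert abs(membership(low, 20.0 + eps) - 1.0) < 1e-6

    def test_flank_values_strictly_between_zero_and_one(self):
        low = FuzzySet(LOW_LABEL, (0.0, 20.0), 8.0)
        vals = low.membership(np.linspace(20.5, 60, 50))
        assert np.all((vals > 0) & (vals < 1))

    def test_out_of_scale_values_clamped(self):
        low = FuzzySet(LOW_LABEL, (0.0, 20.0), 5.0)
        assert membership(low, -10.0) == 1.0
        assert membership(low, 150.0) == membership(low, 100.0)

    def test_monotone_low_and_high(self, toy_partitions):
        grid = np.linspace(0, 100, 1000)
        for part in toy_partitions:
            lo = part.low_set.membership(grid)
            hi = part.high_set.membership(grid)
            assert np.all(np.diff(lo) <= 1e-12)
            assert np.all(np.diff(hi) >= -1e-12)


class TestProjection:
    def test_unordered_prototypes_raise(self):
        fcm = FCMResult(
            prototypes=np.array([[10.0, 50.0], [10.0, 20.0]]),
            membership_matrix=np.ones((2, 2)) / 2,
        )
        with pytest.raises(PartitionError):
            project_partitions(fcm, domains=["a", "b"])

    def test_core_form_and_overlap(self, rng):
        areas = generate_areas(GeneratorConfig(seed=3))
        X = scores_matrix(areas)
        parts, _ = fit_partitions(X, list(DOMAINS), seed=3)
        for p in parts:
            assert p.low_set.core[0] == 0.0 and p.high_set.core[1] == 100.0
            assert p.a < p.b
            mid = 0.5 * (p.a + p.b)
            lo, hi = p.low_set.membership(mid), p.high_set.membership(mid)
            assert 0.0 < lo < 1.0 and 0.0 < hi < 1.0

    def test_income_core_recovery_from_matched_data(self):
        """Learned income cut-offs land near the configured [0, 11.71]/[36.56, 100]."""
        areas = generate_areas(GeneratorConfig(seed=1))
        X = scores_matrix(areas)
        parts, _ = fit_partitions(X, list(DOMAINS), seed=1)
        income = next(p for p in parts if p.domain_name == "income")
        assert abs(income.a - CORE_BOUNDS["income"][0]) <= 3.0
        assert abs(income.b - CORE_BOUNDS["income"][1]) <= 3.0

    def test_all_domain_cores_roughly_recovered(self):
        areas = generate_areas(GeneratorConfig(seed=2))
        X = scores_matrix(areas)
        parts, _ = fit_partitions(X, list(DOMAINS), seed=2)
        for p in parts:
            a, b = CORE_BOUNDS[p.domain_name]
            assert abs(p.a - a) <= 5.0 and abs(p.b - b) <= 5.0

    def test_gap_fraction_flanks(self):
        areas = generate_areas(GeneratorConfig(seed=4, n_areas=400))
        X = scores_matrix(areas)
        parts, _ = fit_partitions(X, list(DOMAINS), seed=4, flank_mode="gap_fraction",
                                  flank_fraction=0.25)
        for p in parts:
            assert p.low_set.flank_width == pytest.approx(0.25 * (p.b - p.a))


class TestPartitionsFromBounds:
    def test_default_half_gap_flank(self):
        parts = partitions_from_bounds({"income": (11.71, 36.56)})
        assert parts[0].low_set.flank_width == pytest.approx((36.56 - 11.71) / 2)

    def test_invalid_core_order_raises(self):
        with pytest.raises(PartitionError):
            partitions_from_bounds({"x": (50.0, 40.0)})
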