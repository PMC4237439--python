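"""Fuzzy partitioning of deprivation domains.

Each domain score (0-100 scale) is split into two overlapping fuzzy sets,
"non-deprived" (low) and "highly deprived" (high).  A fuzzy set has a *core* --
a closed interval where membership is exactly 1 -- anchored to one end of the
scale (low cores start at 0, high cores end at 100), and a Gaussian flank that
decays smoothly outside the core.  The two cores never meet: scores between
the low core's upper edge ``a`` and the high core's lower edge ``b`` belong
partially to both sets, which is what lets neighbouring if-then rules share
influence over intermediate areas.

Partitions are either configured directly from core cut-off points
(:func:`partitions_from_bounds`) or learned from data: fuzzy c-means with two
clusters on the joint standardized score space, followed by projection of the
prototypes onto each domain axis (:func:`fit_partitions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

from .errors import PartitionError, ValidationError

SCALE = (0.0, 100.0)

LOW_LABEL = "non_deprived"
HIGH_LABEL = "highly_deprived"


@dataclass(frozen=True)
class FuzzySet:
    """One linguistic term for one domain.

    Parameters
    ----------
    label : str
        ``"non_deprived"`` or ``"highly_deprived"``.
    core : tuple of float
        Closed interval where membership equals 1.  Low sets have cores of the
        form ``[0, a]``, high sets ``[b, 100]``.
    flank_width : float
        Standard deviation of the Gaussian decay outside the core, in score
        units.  Must be positive.
    """

    label: str
    core: tuple[float, float]
    flank_width: float

    def __post_init__(self) -> None:
        lo, hi = self.core
        if not (SCALE[0] <= lo <= hi <= SCALE[1]):
            raise PartitionError(f"core {self.core} outside the 0-100 scale")
        if not (self.flank_width > 0 and math.isfinite(self.flank_width)):
            raise PartitionError(f"flank_width must be positive, got {self.flank_width}")
        if self.label not in (LOW_LABEL, HIGH_LABEL):
            raise PartitionError(f"unknown fuzzy-set label {self.label!r}")

    def membership(self, x) -> np.ndarray | float:
        """Membership degree in [0, 1]; 1 on the core, Gaussian decay outside.

        Scores outside [0, 100] are clamped to the scale before evaluation.
        """
        arr = np.clip(np.asarray(x, dtype=float), *SCALE)
        if np.any(~np.isfinite(np.asarray(x, dtype=float))):
            raise ValidationError("membership input contains non-finite values")
        lo, hi = self.core
        out = np.ones_like(arr)
        below = arr < lo
        above = arr > hi
        s2 = 2.0 * self.flank_width**2
        out = np.where(below, np.exp(-((lo - arr) ** 2) / s2), out)
        out = np.where(above, np.exp(-((arr - hi) ** 2) / s2), out)
        if np.isscalar(x) or np.ndim(x) == 0:
            return float(out)
        return out


def membership(fset: FuzzySet, x):
    """Functional alias for :meth:`FuzzySet.membership`."""
    return fset.membership(x)


@dataclass(frozen=True)
class DomainPartition:
    """The low/high fuzzy-set pair for one deprivation domain."""

    domain_name: str
    low_set: FuzzySet
    high_set: FuzzySet

    def __post_init__(self) -> None:
        if self.low_set.core[0] != SCALE[0]:
            raise PartitionError(f"{self.domain_name}: low core must start at 0")
        if self.high_set.core[1] != SCALE[1]:
            raise PartitionError(f"{self.domain_name}: high core must end at 100")
        if not self.low_set.core[1] < self.high_set.core[0]:
            raise PartitionError(
                f"{self.domain_name}: low core edge {self.low_set.core[1]} must lie "
                f"below high core edge {self.high_set.core[0]}"
            )

    @property
    def a(self) -> float:
        """Upper edge of the non-deprived core."""
        return self.low_set.core[1]

    @property
    def b(self) -> float:
        """Lower edge of the highly-deprived core."""
        return self.high_set.core[0]


def partitions_from_bounds(
    core_bounds: dict[str, tuple[float, float]],
    flank_width: float | dict[str, float] | None = None,
) -> list[DomainPartition]:
    """Build partitions directly from (a, b) core cut-off points.

    When ``flank_width`` is None each domain gets a flank standard deviation of
    half the core gap ``(b - a) / 2``, which reproduces the overlapping,
    non-complementary memberships seen in intermediate areas (both degrees
    strictly between 0 and 1 for scores between the cores).
    """
    parts = []
    for name, (a, b) in core_bounds.items():
        if isinstance(flank_width, dict):
            sigma = flank_width[name]
        elif flank_width is None:
            sigma = (b - a) / 2.0
        else:
            sigma = float(flank_width)
        parts.append(
            DomainPartition(
                domain_name=name,
                low_set=FuzzySet(LOW_LABEL, (0.0, float(a)), sigma),
                high_set=FuzzySet(HIGH_LABEL, (float(b), 100.0), sigma),
            )
        )
    return parts


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------


@dataclass
class FCMResult:
    """Outcome of a fuzzy c-means run.

    ``membership_matrix`` rows sum to one; ``objective_trace`` is the value of
    the fuzzy within-cluster scatter after each full (prototype, membership)
    update and is non-increasing.
    """

    prototypes: np.ndarray
    membership_matrix: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    fuzzifier: float = 2.0


def fit_fcm(
    data: np.ndarray,
    n_clusters: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    n_init: int = 1,
) -> FCMResult:
    """Standard alternating-optimization fuzzy c-means (Bezdek).

    Minimises ``sum_ik u_ik^m ||x_i - v_k||^2`` subject to rows of ``u``
    summing to one, by alternating the prototype update
    ``v_k = sum_i u_ik^m x_i / sum_i u_ik^m`` with the membership update
    ``u_ik = 1 / sum_l (||x_i - v_k|| / ||x_i - v_l||)^{2/(m-1)}``.

    A data point coincident with a prototype receives membership 1 in that
    cluster (split equally on exact ties) and 0 elsewhere.  Convergence is
    declared when the largest membership change falls below ``tol``.  With
    ``n_init > 1`` the run is repeated from seeded random starts and the
    solution with the lowest final objective is returned (the objective is
    non-convex and single random starts occasionally merge clusters).
    """
    if n_init > 1:
        runs = [
            fit_fcm(data, n_clusters, fuzzifier, tol, max_iter, seed=seed + 1000 * k)
            for k in range(n_init)
        ]
        return min(runs, key=lambda r: r.objective_trace[-1])
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValidationError("fit_fcm: data contains NaN or infinite values")
    n = X.shape[0]
    if n_clusters < 1:
        raise ValidationError("fit_fcm: n_clusters must be >= 1")
    if n_clusters > 1 and n < n_clusters:
        raise ValidationError(f"fit_fcm: need at least {n_clusters} points, got {n}")
    if not fuzzifier > 1:
        raise ValidationError("fit_fcm: fuzzifier must exceed 1")

    if n_clusters == 1:
        proto = X.mean(axis=0, keepdims=True)
        U = np.ones((n, 1))
        obj = float(((X - proto) ** 2).sum())
        return FCMResult(proto, U, [obj], n_iter=1, converged=True, fuzzifier=fuzzifier)

    rng = np.random.default_rng(seed)
    U = rng.uniform(size=(n, n_clusters))
    U /= U.sum(axis=1, keepdims=True)

    m = float(fuzzifier)
    exponent = 2.0 / (m - 1.0)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Um = U**m
        V = (Um.T @ X) / Um.sum(axis=0)[:, None]
        D2 = cdist(X, V, metric="sqeuclidean")
        U_new = _membership_from_distances(D2, exponent)
        trace.append(float((U_new**m * D2).sum()))
        delta = float(np.max(np.abs(U_new - U)))
        U = U_new
        if delta < tol:
            converged = True
            break
    return FCMResult(V, U, trace, n_iter=it, converged=converged, fuzzifier=m)


def _membership_from_distances(D2: np.ndarray, exponent: float) -> np.ndarray:
    """FCM membership update with the coincident-point singularity rule."""
    singular = D2 < 1e-24
    any_singular = singular.any(axis=1)
    with np.errstate(divide="ignore"):
        inv = D2 ** (-exponent / 2.0)
    U = np.where(any_singular[:, None], 0.0, inv)
    rows = np.where(any_singular)[0]
    for i in rows:
        hits = singular[i]
        U[i, hits] = 1.0 / hits.sum()
    U /= U.sum(axis=1, keepdims=True)
    return U


# ---------------------------------------------------------------------------
# Prototype projection -> per-domain partitions
# ---------------------------------------------------------------------------

CORE_MEMBERSHIP = 0.95  #: projected membership level defining the core edge


def _projected_low_membership(x, vl: float, vh: float, m: float):
    """1-D FCM membership of the low cluster along one domain axis."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(x - vl) / np.abs(x - vh)
        u = 1.0 / (1.0 + ratio ** (2.0 / (m - 1.0)))
    u = np.where(np.isclose(x, vl), 1.0, u)
    u = np.where(np.isclose(x, vh) & ~np.isclose(vl, vh), 0.0, u)
    return u


def _fit_flank_sigma(grid: np.ndarray, target: np.ndarray, edge: float) -> float:
    """Least-squares Gaussian flank width against a projected membership curve."""
    dist2 = (grid - edge) ** 2

    def loss(log_sigma: float) -> float:
        sigma = math.exp(log_sigma)
        pred = np.exp(-dist2 / (2.0 * sigma**2))
        return float(((pred - target) ** 2).sum())

    res = minimize_scalar(loss, bounds=(math.log(0.1), math.log(300.0)), method="bounded")
    return float(math.exp(res.x))


def _split_coordinates(coords: np.ndarray) -> tuple[float, float]:
    """Optimal two-group split of projected prototype coordinates (1-D k-means).

    Returns the means of the low and high groups.  With exactly two
    prototypes this is simply the smaller and larger coordinate.
    """
    xs = np.sort(coords)
    if xs.size < 2:
        raise PartitionError("need at least two projected prototypes per domain")
    best, best_cut = np.inf, 1
    for cut in range(1, xs.size):
        lo, hi = xs[:cut], xs[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best:
            best, best_cut = sse, cut
    return float(xs[:best_cut].mean()), float(xs[best_cut:].mean())


def project_partitions(
    fcm: FCMResult,
    data: np.ndarray | None = None,
    domains: list[str] | None = None,
    flank_mode: str = "projected",
    flank_fraction: float = 0.25,
) -> list[DomainPartition]:
    """Project the FCM prototypes onto each domain axis and extract fuzzy sets.

    For each domain the projected prototype coordinates are split into a low
    and a high group (optimal 1-D two-group split; with two clusters this is
    just coordinate order) whose means act as the cluster positions
    ``v_l < v_h`` along that axis.  The projected 1-D FCM membership curve
    between them then defines the cores: the low core edge ``a`` is the
    largest score whose projected low membership is at least 0.95
    (closed-form for the FCM update), and symmetrically for ``b``.  Gaussian
    flank widths are fitted by least squares to the decaying part of the
    projected curve.
    """
    V = np.asarray(fcm.prototypes, dtype=float)
    if V.shape[0] < 2:
        raise PartitionError("project_partitions requires an FCM fit with >= 2 clusters")
    d = V.shape[1]
    if domains is None:
        domains = [f"domain_{j}" for j in range(d)]
    if len(domains) != d:
        raise PartitionError("number of domain names does not match prototype dimension")

    m = fcm.fuzzifier
    # core edge from  (x - vl)/(vh - x) = r  with  u_low(x) = 0.95
    r = ((1.0 - CORE_MEMBERSHIP) / CORE_MEMBERSHIP) ** ((m - 1.0) / 2.0)

    parts: list[DomainPartition] = []
    for j, name in enumerate(domains):
        vl, vh = _split_coordinates(V[:, j])
        if not vh - vl > 1e-9:
            raise PartitionError(
                f"{name}: projected prototypes are not strictly ordered ({vl} vs {vh})"
            )
        a = (vl + r * vh) / (1.0 + r)
        b = (vh + r * vl) / (1.0 + r)
        a = float(np.clip(a, 0.0, 100.0))
        b = float(np.clip(b, 0.0, 100.0))
        if not a < b:
            raise PartitionError(f"{name}: degenerate cores derived from projection")

        if flank_mode == "projected":
            # fit flanks on the monotone stretch of the projected curve (the
            # 1-D FCM curve creeps back toward 0.5 far beyond the opposite
            # prototype, an artifact of the update, not of the partition)
            grid_low = np.linspace(a, max(vh, a + 1e-6), 200)
            t_low = _projected_low_membership(grid_low, vl, vh, m)
            sigma_low = _fit_flank_sigma(grid_low, t_low, a)
            grid_high = np.linspace(min(vl, b - 1e-6), b, 200)
            t_high = 1.0 - _projected_low_membership(grid_high, vl, vh, m)
            sigma_high = _fit_flank_sigma(grid_high, t_high, b)
        elif flank_mode == "gap_fraction":
            sigma_low = sigma_high = max((b - a) * flank_fraction, 1e-3)
        else:
            raise PartitionError(f"unknown flank_mode {flank_mode!r}")

        parts.append(
            DomainPartition(
                domain_name=name,
                low_set=FuzzySet(LOW_LABEL, (0.0, a), sigma_low),
                high_set=FuzzySet(HIGH_LABEL, (b, 100.0), sigma_high),
            )
        )
    return parts


def fit_partitions(
    scores: np.ndarray,
    domains: list[str],
    n_clusters: int = 2,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    n_init: int = 4,
    flank_mode: str = "projected",
    flank_fraction: float = 0.25,
) -> tuple[list[DomainPartition], FCMResult]:
    """Learn the per-domain fuzzy partitions from a score matrix.

    Scores are min-max standardized to [0, 1] per domain (so every domain
    contributes equally to the Euclidean distances) and clustered with fuzzy
    c-means on the joint space; prototypes are mapped back to the original
    0-100 scale before projection.  Two clusters (the default) suit cohorts
    organised along a single general-deprivation gradient; with more
    clusters the projection gets one prototype per data sub-region, so a
    domain whose deprivation runs against the overall gradient (e.g. access
    in rural areas) still projects a clean low/high split on its own axis.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(domains):
        raise ValidationError("fit_partitions: scores must be n x d with d = len(domains)")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    Z = (X - lo) / span
    fcm = fit_fcm(Z, n_clusters=n_clusters, fuzzifier=fuzzifier, tol=tol,
                  max_iter=max_iter, seed=seed, n_init=n_init)
    fcm_scaled = FCMResult(
        prototypes=fcm.prototypes * span + lo,
        membership_matrix=fcm.membership_matrix,
        objective_trace=fcm.objective_trace,
        n_iter=fcm.n_iter,
        converged=fcm.converged,
        fuzzifier=fcm.fuzzifier,
    )
    return (
        project_partitions(fcm_scaled, X, domains,
                           flank_mode=flank_mode, flank_fraction=flank_fraction),
        fcm_scaled,
    )
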