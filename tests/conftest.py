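import numpy as np
import pytest

from tsimpact.model import HIGH, LOW, Rule, TSModel, build_rule_grid, fit_consequents
from tsimpact.partition import partitions_from_bounds


@pytest.fixture
def toy_partitions():
    """Two-domain partition with cores [0,20]/[40,100] and narrow flanks."""
    return partitions_from_bounds({"d1": (20.0, 40.0), "d2": (20.0, 40.0)}, flank_width=5.0)


@pytest.fixture
def crisp_partitions():
    """Two-domain partition whose flanks are so narrow the regions are crisp."""
    return partitions_from_bounds({"d1": (30.0, 70.0), "d2": (30.0, 70.0)}, flank_width=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_fitted_model(partitions, coefficients, domains=None):
    """TSModel over the full rule grid with hand-set consequents.

    ``coefficients`` maps rule index -> (intercept, slopes...).
    """
    rules = build_rule_grid(partitions)
    domains = tuple(domains or (p.domain_name for p in partitions))
    for i, rule in enumerate(rules):
        c0, *slopes = coefficients[i]
        rule.intercept = float(c0)
        rule.slopes = np.asarray(slopes, dtype=float)
    return TSModel(domains, partitions, rules, fitted=True)


def crisp_two_domain_dataset(rng, n_per_region=60, noise_sd=0.0):
    """Noise-free-capable dataset with four well-separated corner clusters.

    Scores live deep inside the cores of :func:`crisp_partitions`; the
    outcome follows a known 4-rule TS model.  Returns (X, y, truth_model).
    """
    parts = partitions_from_bounds({"d1": (30.0, 70.0), "d2": (30.0, 70.0)}, flank_width=2.0)
    coefs = [
        (10.0, 0.10, 0.30),
        (12.0, 0.20, 0.05),
        (8.0, -0.10, 0.25),
        (20.0, 0.15, 0.15),
    ]
    truth = make_fitted_model(parts, coefs)
    blocks = []
    for lo1 in (True, False):
        for lo2 in (True, False):
            x1 = rng.uniform(2, 26, n_per_region) if lo1 else rng.uniform(74, 98, n_per_region)
            x2 = rng.uniform(2, 26, n_per_region) if lo2 else rng.uniform(74, 98, n_per_region)
            blocks.append(np.column_stack([x1, x2]))
    X = np.vstack(blocks)
    from tsimpact.model import predict

    y = predict(truth, X)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, len(y))
    return X, y, truth
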