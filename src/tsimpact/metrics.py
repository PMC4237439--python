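"""Per-area domain-impact metrics: MiD and CoD.

The TS model's prediction at an area is a convex combination of local linear
models, so the *local slope* of the outcome surface is itself a fused
quantity.  Two metrics expose it per area:

* **MiD** (micro-impact of domain): each rule's slope vector is first
  normalized to unit Euclidean length, then fused with the area's normalized
  firing strengths: ``MiD_j(x) = sum_i v_i(x) e_j^i``.  It is the expected
  direction and (relative) rate of change of the outcome per unit change in
  domain j at that specific area; a positive value means more deprivation in
  that domain goes with more education under-attainment.

* **CoD** (contribution of domain): ``CoD_j(x) = MiD_j(x) * x_j`` -- the
  micro-impact scaled by the domain's observed score, i.e. the absolute
  contribution of that domain to the area's expected outcome.  A domain can
  have a large MiD but a tiny CoD when its score is already very low, which
  is exactly the policy-relevant distinction the pair of metrics draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NotFittedError
from .model import Rule, TSModel, firing_strengths
from .selection import dominant_rule

logger = logging.getLogger(__name__)

NO_DOMAIN = "none"  #: sentinel when every MiD component is zero


def normalize_slopes(rule: Rule) -> np.ndarray:
    """Unit-Euclidean-norm slope vector of a rule (intercept excluded).

    An all-zero slope vector (a support-starved rule with frozen slopes) is
    returned as the zero vector rather than raising: such a rule contributes
    nothing to the MiD fusion.
    """
    slopes = np.asarray(rule.slopes, dtype=float)
    norm = float(np.linalg.norm(slopes))
    if norm == 0.0:
        logger.info("rule %d has an all-zero slope vector; contributing zeros to MiD",
                    rule.rule_id)
        return np.zeros_like(slopes)
    return slopes / norm


def _unit_slope_matrix(model: TSModel) -> np.ndarray:
    return np.vstack([normalize_slopes(rule) for rule in model.rules])


def mid(model: TSModel, x) -> np.ndarray:
    """Micro-impact of domain at x: the v-weighted fusion of unit slope vectors.

    Accepts a single score vector or an (n, d) matrix; the Euclidean norm of
    each returned row is at most 1 (convex combination of unit vectors).
    """
    if not model.fitted:
        raise NotFittedError("fit the model before computing MiD")
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    _, V = firing_strengths(model, X)
    E = _unit_slope_matrix(model)
    out = np.atleast_2d(V) @ E
    return out[0] if single else out


def cod(model: TSModel, x) -> np.ndarray:
    """Contribution of domain at x: ``MiD_j(x) * x_j`` (outcome units)."""
    X = np.asarray(x, dtype=float)
    return mid(model, X) * X


def strongest_domain(mid_vector: np.ndarray,
                     domains: tuple[str, ...]) -> tuple[str, int]:
    """Domain with the largest |MiD| and the sign of its effect.

    Ties resolve to the first domain in canonical order; an all-zero MiD
    yields the ``"none"`` sentinel with sign 0.
    """
    m = np.asarray(mid_vector, dtype=float)
    if np.all(m == 0.0):
        return NO_DOMAIN, 0
    j = int(np.argmax(np.abs(m)))
    return domains[j], int(np.sign(m[j]))


def cod_share(cod_vector: np.ndarray, predicted: float | None = None,
              denominator: str = "abs_sum") -> np.ndarray:
    """Signed per-domain share of the total contribution.

    ``abs_sum`` (default): ``CoD_j / sum_k |CoD_k|`` -- shares of the absolute
    contributions sum to one whenever any contribution is non-zero.
    ``predicted``: divide by the model's predicted outcome instead (requires
    ``predicted``).  An all-zero CoD vector yields all-zero shares.
    """
    c = np.asarray(cod_vector, dtype=float)
    if denominator == "abs_sum":
        total = float(np.abs(c).sum())
    elif denominator == "predicted":
        if predicted is None:
            raise ValueError("denominator='predicted' requires the predicted outcome")
        total = float(predicted)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if total == 0.0:
        return np.zeros_like(c)
    return c / total


@dataclass
class ImpactProfile:
    """Full per-area impact summary."""

    area_id: str
    mid: np.ndarray
    cod: np.ndarray
    dominant_rule_id: int
    strongest_domain: str
    strongest_sign: int
    cod_share: np.ndarray


def impact_profile(model: TSModel, x, area_id: str = "") -> ImpactProfile:
    """Compute the impact profile of a single area."""
    x = np.asarray(x, dtype=float)
    m = mid(model, x)
    c = m * x
    name, sign = strongest_domain(m, model.domains)
    return ImpactProfile(
        area_id=area_id,
        mid=m,
        cod=c,
        dominant_rule_id=dominant_rule(model, x),
        strongest_domain=name,
        strongest_sign=sign,
        cod_share=cod_share(c),
    )


def impact_table(model: TSModel, areas: pd.DataFrame) -> pd.DataFrame:
    """Tabular impact profiles for a whole area table.

    One row per area with columns ``mid_<domain>``, ``cod_<domain>``,
    ``dominant_rule``, ``strongest_domain`` (with ``strongest_sign``) and
    ``cod_share_<domain>`` -- the tabular stand-in for impact maps.
    """
    X = areas.loc[:, list(model.domains)].to_numpy(dtype=float)
    M = mid(model, X)
    C = M * X
    _, V = firing_strengths(model, X)
    dom_ids = np.array([model.rules[k].rule_id for k in np.argmax(V, axis=1)])
    out = {"area_id": areas["area_id"].to_numpy()}
    for j, name in enumerate(model.domains):
        out[f"mid_{name}"] = M[:, j]
    for j, name in enumerate(model.domains):
        out[f"cod_{name}"] = C[:, j]
    out["dominant_rule"] = dom_ids
    strongest = [strongest_domain(row, model.domains) for row in M]
    out["strongest_domain"] = [s[0] for s in strongest]
    out["strongest_sign"] = [s[1] for s in strongest]
    shares = np.vstack([cod_share(row) for row in C])
    for j, name in enumerate(model.domains):
        out[f"cod_share_{name}"] = shares[:, j]
    return pd.DataFrame(out)
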