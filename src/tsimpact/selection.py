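"""Rule-base pruning.

A full 2^d rule grid over six domains has 64 local linear models, most of
which describe sub-regions containing little or no data; keeping them risks
over-fitting and destroys interpretability.  This module ranks rules by an
activation-weighted contribution index -- the mean over a validation set of
``v_i(x) * |y_i(x)|``, i.e. how strongly a rule fires times how much its
local model asserts -- and then greedily removes rules in ascending
importance, re-fitting the survivors after each removal and keeping a
removal only if validation RMSE does not degrade beyond a stated tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .model import TSModel, firing_strengths, fit_consequents, predict


@dataclass(frozen=True)
class RuleImportance:
    rule_id: int
    importance: float
    rank: int  # 1 = most important


def rule_importance(model: TSModel, validation_scores: np.ndarray) -> list[RuleImportance]:
    """Activation-weighted contribution of every rule on a validation set.

    ``importance_i = mean_x  v_i(x) * |y_i(x)|``; a rule that never fires on
    the validation data scores zero, however large its coefficients.
    """
    X = np.asarray(validation_scores, dtype=float)
    if X.size == 0:
        raise ValidationError("rule_importance: validation set is empty")
    _, V = firing_strengths(model, X)
    Y = np.column_stack([rule.linear_output(X) for rule in model.rules])
    scores = (V * np.abs(Y)).mean(axis=0)
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(model.rules), dtype=int)
    ranks[order] = np.arange(1, len(model.rules) + 1)
    return [
        RuleImportance(rule.rule_id, float(scores[i]), int(ranks[i]))
        for i, rule in enumerate(model.rules)
    ]


@dataclass
class PruneStep:
    rule_id: int
    pattern: str
    importance: float
    removed: bool
    validation_rmse: float


@dataclass
class PruneReport:
    """Audit trail of the backward-elimination pass."""

    baseline_rmse: float
    rmse_tolerance: float
    steps: list[PruneStep] = field(default_factory=list)
    final_rmse: float = np.nan

    @property
    def n_removed(self) -> int:
        return sum(step.removed for step in self.steps)

    def to_text(self) -> str:
        lines = [
            f"baseline validation RMSE: {self.baseline_rmse:.6g}"
            f" (tolerance {self.rmse_tolerance:.2%})",
            f"{'rule':>6} {'pattern':>10} {'importance':>12} {'decision':>9} {'val RMSE':>10}",
        ]
        for s in self.steps:
            lines.append(
                f"{s.rule_id:>6} {s.pattern:>10} {s.importance:>12.5g} "
                f"{'removed' if s.removed else 'kept':>9} {s.validation_rmse:>10.6g}"
            )
        lines.append(f"final validation RMSE: {self.final_rmse:.6g}")
        return "\n".join(lines)


def _rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(obs)) ** 2)))


def prune(
    model: TSModel,
    train_scores: np.ndarray,
    train_outcome: np.ndarray,
    validation_scores: np.ndarray,
    validation_outcome: np.ndarray,
    rmse_tolerance: float = 0.01,
    min_rules: int = 1,
    refit: bool = True,
) -> tuple[TSModel, PruneReport]:
    """Greedy backward elimination of redundant rules.

    Rules are visited in ascending importance (computed once, on the full
    model).  A tentative removal is accepted only if the validation RMSE of
    the re-fitted reduced model stays within ``(1 + rmse_tolerance)`` times
    the full model's validation RMSE.  Elimination stops once ``min_rules``
    rules remain.  ``refit=False`` keeps the surviving coefficients frozen
    instead of re-estimating them after each removal.
    """
    if min_rules < 1:
        raise ConfigurationError("min_rules must be at least 1")
    Xt = np.asarray(train_scores, dtype=float)
    yt = np.asarray(train_outcome, dtype=float)
    Xv = np.asarray(validation_scores, dtype=float)
    yv = np.asarray(validation_outcome, dtype=float)

    baseline = _rmse(predict(model, Xv), yv)
    budget = baseline * (1.0 + rmse_tolerance)
    importances = {ri.rule_id: ri.importance for ri in rule_importance(model, Xv)}
    visit_order = sorted(model.rules, key=lambda r: (importances[r.rule_id], r.rule_id))

    current = model.copy()
    report = PruneReport(baseline_rmse=baseline, rmse_tolerance=rmse_tolerance)
    current_rmse = baseline
    for rule in visit_order:
        if len(current.rules) <= min_rules:
            break
        trial = current.copy(rules=[r for r in current.rules if r.rule_id != rule.rule_id])
        if refit:
            fit_consequents(trial, Xt, yt, **model.meta.get("fit_options", {}))
        trial_rmse = _rmse(predict(trial, Xv), yv)
        accept = trial_rmse <= budget
        if accept:
            current = trial
            current_rmse = trial_rmse
        report.steps.append(
            PruneStep(rule.rule_id, rule.pattern(), importances[rule.rule_id],
                      accept, trial_rmse if accept else current_rmse)
        )
    report.final_rmse = current_rmse
    return current, report


def dominant_rule(model: TSModel, x) -> int:
    """Rule with the maximal normalized firing strength at x (ties -> lowest id)."""
    _, v = firing_strengths(model, np.asarray(x, dtype=float))
    return int(model.rules[int(np.argmax(v))].rule_id)
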