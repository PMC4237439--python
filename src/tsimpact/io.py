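"""Plain-text serialization of partitions and models.

Formats are line-oriented and human-readable: partitions mirror the
published cut-off table (one line per domain and linguistic term), models
list one block per rule with the antecedent in "D"/"-" notation (D = highly
deprived) followed by the consequent coefficients.  Floats are written with
``repr`` so round-trips are exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ValidationError
from .model import HIGH, LOW, Rule, TSModel
from .partition import DomainPartition, FuzzySet, HIGH_LABEL, LOW_LABEL

_MODEL_HEADER = "# tsimpact ts-model v1"
_PARTITION_HEADER = "# tsimpact partitions v1"


def save_partitions(partitions: list[DomainPartition], path: str | Path) -> None:
    lines = [_PARTITION_HEADER]
    for p in partitions:
        lines.append(
            f"{p.domain_name} non_deprived core 0 {p.a!r} flank {p.low_set.flank_width!r}"
        )
        lines.append(
            f"{p.domain_name} highly_deprived core {p.b!r} 100 flank {p.high_set.flank_width!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_partitions(path: str | Path) -> list[DomainPartition]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")]
    sets: dict[str, dict[str, FuzzySet]] = {}
    order: list[str] = []
    for ln in lines:
        name, label, _core, lo, hi, _flank, sigma = ln.split()
        if name not in sets:
            sets[name] = {}
            order.append(name)
        sets[name][label] = FuzzySet(label, (float(lo), float(hi)), float(sigma))
    parts = []
    for name in order:
        pair = sets[name]
        if set(pair) != {LOW_LABEL, HIGH_LABEL}:
            raise ValidationError(f"partition file: domain {name} must have both fuzzy sets")
        parts.append(DomainPartition(name, pair[LOW_LABEL], pair[HIGH_LABEL]))
    return parts


def save_model(model: TSModel, path: str | Path) -> None:
    lines = [_MODEL_HEADER, "domains " + " ".join(model.domains)]
    for p in model.partitions:
        lines.append(
            f"partition {p.domain_name} {p.a!r} {p.b!r} "
            f"{p.low_set.flank_width!r} {p.high_set.flank_width!r}"
        )
    for rule in model.rules:
        coefs = " ".join(repr(float(c)) for c in [rule.intercept, *np.asarray(rule.slopes)])
        lines.append(f"rule {rule.rule_id} {rule.pattern()} {coefs}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> TSModel:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")]
    domains: tuple[str, ...] = ()
    parts: list[DomainPartition] = []
    rules: list[Rule] = []
    for ln in lines:
        kind, *rest = ln.split()
        if kind == "domains":
            domains = tuple(rest)
        elif kind == "partition":
            name, a, b, sl, sh = rest
            parts.append(
                DomainPartition(
                    name,
                    FuzzySet(LOW_LABEL, (0.0, float(a)), float(sl)),
                    FuzzySet(HIGH_LABEL, (float(b), 100.0), float(sh)),
                )
            )
        elif kind == "rule":
            rule_id, pattern, *coefs = rest
            antecedent = tuple(HIGH if ch == "D" else LOW for ch in pattern)
            values = [float(c) for c in coefs]
            rules.append(Rule(int(rule_id), antecedent, values[0], np.array(values[1:])))
        else:
            raise ValidationError(f"model file: unknown record kind {kind!r}")
    if not domains or not parts or not rules:
        raise ValidationError("model file: missing domains, partitions or rules")
    return TSModel(domains, parts, rules, fitted=all(r.is_fitted for r in rules))
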