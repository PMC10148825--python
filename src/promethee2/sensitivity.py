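"""Weight sensitivity of the outranking ranking.

A fixed weight vector (here 0.45/0.35/0.20 in the case study) is a judgement
call; these tools quantify how much the final ranking depends on it. Two
probes are provided: one-at-a-time weight perturbations around the base
vector, and criterion knockout (drop one criterion, renormalize the rest
proportionally). All scenarios run the full-precision pipeline — paper-mode
rounding is a table-reproduction device, not an analysis device.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import DecisionMatrix, normalize_weights
from .errors import ConfigurationError, DomainError
from .pipeline import run_promethee2

__all__ = [
    "Scenario",
    "SensitivityReport",
    "weight_sweep",
    "criterion_knockout",
    "rank_agreement",
]


@dataclass(frozen=True)
class Scenario:
    """One perturbed run: normalized weights, resulting order and ranks."""

    label: str
    criteria: tuple[str, ...]
    weights: tuple[float, ...]
    order: tuple[str, ...]
    ranks: dict[str, int] = field(compare=False)
    tau_vs_base: float = float("nan")


@dataclass(frozen=True)
class SensitivityReport:
    """Scenarios plus per-alternative rank stability and order reversals."""

    base: Scenario
    scenarios: tuple[Scenario, ...]
    stability: dict[str, tuple[int, int]]  # alternative -> (min rank, max rank)
    reversals: tuple[tuple[str, str], ...]  # pairs whose strict order flips

    def to_dict(self) -> dict:
        return {
            "base": _scenario_dict(self.base),
            "scenarios": [_scenario_dict(s) for s in self.scenarios],
            "stability": {a: list(r) for a, r in self.stability.items()},
            "reversals": [list(p) for p in self.reversals],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _scenario_dict(s: Scenario) -> dict:
    return {
        "label": s.label,
        "criteria": list(s.criteria),
        "weights": list(s.weights),
        "order": list(s.order),
        "ranks": dict(s.ranks),
        "tau_vs_base": None if np.isnan(s.tau_vs_base) else s.tau_vs_base,
    }


def _run_scenario(dm: DecisionMatrix, label: str) -> Scenario:
    res = run_promethee2(dm, mode="full-precision")
    ranks = {a: int(r) for a, r in res.flows.table["rank"].items()}
    return Scenario(
        label=label,
        criteria=dm.criterion_names,
        weights=tuple(float(c.weight) for c in res.decision_matrix.criteria),
        order=res.ranking,
        ranks=ranks,
    )


def _with_weights(dm: DecisionMatrix, weights: Sequence[float]) -> DecisionMatrix:
    crit = [replace(c, weight=float(w)) for c, w in zip(dm.criteria, weights)]
    return dm.with_criteria(normalize_weights(crit))


def _finish_report(dm: DecisionMatrix, base: Scenario,
                   scenarios: list[Scenario]) -> SensitivityReport:
    scenarios = [
        replace(s, tau_vs_base=rank_agreement(base.ranks, _restrict(base, s)))
        for s in scenarios
    ]
    alts = list(dm.alternatives)
    stability = {
        a: (
            min(s.ranks[a] for s in scenarios),
            max(s.ranks[a] for s in scenarios),
        )
        for a in alts
    }
    reversals: list[tuple[str, str]] = []
    for a, b in itertools.combinations(alts, 2):
        signs = {np.sign(s.ranks[a] - s.ranks[b]) for s in scenarios}
        if 1 in signs and -1 in signs:
            reversals.append((a, b))
    return SensitivityReport(
        base=base,
        scenarios=tuple(scenarios),
        stability=stability,
        reversals=tuple(reversals),
    )


def _restrict(base: Scenario, other: Scenario) -> dict[str, int]:
    # knockout scenarios keep the same alternative set, so this is a no-op
    # guard for future extension; tau is computed on the common set
    return {a: other.ranks[a] for a in base.ranks}


def weight_sweep(
    dm: DecisionMatrix,
    base_weights: Sequence[float] | None = None,
    grid: Mapping[str, Sequence[float]] | Sequence[Sequence[float]] | None = None,
) -> SensitivityReport:
    """One-at-a-time weight perturbations.

    For every criterion and every delta in its grid entry, the base weight is
    shifted by the delta, the vector renormalized, and the full-precision
    pipeline rerun. The unperturbed base is always scenario 0. A delta that
    drives a weight negative is a configuration error.
    """
    if grid is None or (hasattr(grid, "__len__") and len(grid) == 0):
        raise ConfigurationError("weight_sweep needs a non-empty delta grid")
    names = dm.criterion_names
    if base_weights is None:
        base_weights = [c.weight for c in dm.criteria]
    base_weights = [float(w) for w in base_weights]
    if len(base_weights) != dm.k:
        raise ConfigurationError(
            f"{len(base_weights)} base weights for {dm.k} criteria"
        )
    if isinstance(grid, Mapping):
        unknown = set(grid) - set(names)
        if unknown:
            raise ConfigurationError(f"grid names unknown criteria: {sorted(unknown)}")
        deltas = {n: list(grid.get(n, ())) for n in names}
    else:
        if len(grid) != dm.k:
            raise ConfigurationError(
                f"per-criterion grid has {len(grid)} entries for {dm.k} criteria"
            )
        deltas = {n: list(g) for n, g in zip(names, grid)}

    base_dm = _with_weights(dm, base_weights)
    base = _run_scenario(base_dm, "base")
    scenarios = [base]
    for j, name in enumerate(names):
        for d in deltas[name]:
            if d == 0:
                continue  # identical to the base scenario
            w = list(base_weights)
            w[j] += float(d)
            if w[j] < 0:
                raise ConfigurationError(
                    f"delta {d:+g} drives weight of {name!r} negative"
                )
            scenarios.append(
                _run_scenario(_with_weights(dm, w), f"{name}{d:+g}")
            )
    return _finish_report(dm, base, scenarios)


def criterion_knockout(dm: DecisionMatrix) -> SensitivityReport:
    """Drop each criterion in turn, renormalizing the remaining weights
    proportionally, and rerun the pipeline."""
    if dm.k < 2:
        raise DomainError("criterion knockout needs at least 2 criteria")
    base = _run_scenario(_with_weights(dm, [c.weight for c in dm.criteria]), "base")
    scenarios = [base]
    for j, name in enumerate(dm.criterion_names):
        kept = [c for i, c in enumerate(dm.criteria) if i != j]
        scores = np.delete(dm.scores, j, axis=1)
        sub = DecisionMatrix(
            alternatives=dm.alternatives,
            criteria=tuple(normalize_weights(kept)),
            scores=scores,
        )
        scenarios.append(_run_scenario(sub, f"drop:{name}"))
    return _finish_report(dm, base, scenarios)


def rank_agreement(order_a, order_b) -> float:
    """Kendall tau-b between two rankings of the same alternatives.

    Accepts either a strict order (sequence of alternative ids, best first)
    or a mapping alternative -> rank (which can express ties). Tau-b applies
    the standard tie correction; identical rankings give 1.0, exact
    reversals without ties give -1.0.
    """
    ra = _to_ranks(order_a)
    rb = _to_ranks(order_b)
    if set(ra) != set(rb):
        raise DomainError("rankings cover different alternative sets")
    alts = sorted(ra)
    x = [ra[a] for a in alts]
    y = [rb[a] for a in alts]
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _to_ranks(order) -> dict[str, int]:
    if isinstance(order, Mapping):
        return {str(a): int(r) for a, r in order.items()}
    seq = list(order)
    if len(set(seq)) != len(seq):
        raise DomainError("order sequence contains duplicate alternatives")
    return {str(a): i + 1 for i, a in enumerate(seq)}
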