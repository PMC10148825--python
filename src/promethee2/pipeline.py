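"""PROMETHEE-II outranking pipeline.

Given a crisp decision matrix with weighted, directed criteria, the method
proceeds in stages:

1.  min-max normalization per criterion — beneficial columns map through
    (C - min)/(max - min), cost columns through (max - C)/(max - min);
2.  pairwise deviations w_j(z, y) = t_j(z) - t_j(y) on each criterion;
3.  a preference function maps each deviation to a degree P_j(z, y) in [0, 1]
    (zero whenever w <= 0);
4.  weighted aggregation pi(z, y) = sum_j d_j * P_j(z, y) with weights d_j
    summing to one;
5.  outranking flows: phi+(z) averages pi(z, .) over the other n-1
    alternatives (dominance), phi-(z) averages pi(., z) (weakness);
6.  net flow phi = phi+ - phi- and a complete descending ranking.

Two modes are provided. ``full-precision`` (default for new analyses) keeps
float precision throughout. ``paper`` rounds half-up to 3 decimals after
normalization and after aggregation, reproducing how published worked
examples of the method are typically tabulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up_array
from .core import (
    Criterion,
    DecisionMatrix,
    PreferenceFunctionSpec,
    normalize_weights,
    validate_matrix,
)
from .errors import ConfigurationError, DomainError

__all__ = [
    "NormalizedMatrix",
    "PreferenceStructure",
    "FlowTable",
    "PrometheeResult",
    "normalize",
    "deviation",
    "preference_value",
    "pairwise_preferences",
    "aggregate_preferences",
    "positive_flow",
    "negative_flow",
    "net_flow",
    "competition_ranks",
    "rank_alternatives",
    "run_promethee2",
    "export_outranking_graph",
    "MODES",
]

MODES = ("paper", "full-precision")


@dataclass(frozen=True)
class NormalizedMatrix:
    """Min-max normalized scores; degenerate (constant) criteria flagged."""

    values: pd.DataFrame
    degenerate: frozenset[str] = frozenset()

    @property
    def alternatives(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def criterion_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass(frozen=True)
class PreferenceStructure:
    """Per-criterion preference tables P_j(z, y) and their weighted aggregate.

    All tables are m × m with a NaN diagonal — self-comparison is undefined
    and excluded from every flow sum.
    """

    per_criterion: dict[str, pd.DataFrame]
    aggregated: pd.DataFrame

    @property
    def alternatives(self) -> tuple[str, ...]:
        return tuple(self.aggregated.index)


@dataclass(frozen=True)
class FlowTable:
    """Outranking flows and ranks, one row per alternative."""

    table: pd.DataFrame  # columns: phi_plus, phi_minus, phi_net, rank

    @property
    def alternatives(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def rank_of(self, alternative: str) -> int:
        return int(self.table.loc[alternative, "rank"])

    @property
    def ordering(self) -> tuple[str, ...]:
        """Alternatives in display order: descending net flow, ties by input order."""
        phi = self.table["phi_net"].to_numpy()
        idx = np.argsort(-phi, kind="stable")
        return tuple(self.table.index[idx])


@dataclass(frozen=True)
class PrometheeResult:
    """Bundle of every pipeline stage for one run."""

    decision_matrix: DecisionMatrix
    normalized: NormalizedMatrix
    preferences: PreferenceStructure
    flows: FlowTable
    mode: str
    rounding: int | None = None
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def ranking(self) -> tuple[str, ...]:
        return self.flows.ordering


# ---------------------------------------------------------------------------
# Stage 2: normalization
# ---------------------------------------------------------------------------

def normalize(dm: DecisionMatrix, rounding: int | None = None) -> NormalizedMatrix:
    """Min-max normalize each criterion column to [0, 1].

    Beneficial criteria use (C - min)/(max - min); cost criteria use
    (max - C)/(max - min). A degenerate column (max = min) carries no
    discriminating information: it maps to all zeros and is flagged.
    When ``rounding`` is set, entries are rounded half-up to that many
    decimals (3 in paper mode).
    """
    report = validate_matrix(dm)
    if not report.ok:
        raise DomainError(
            "invalid decision matrix: " + "; ".join(report.failures)
        )
    out = np.empty((dm.m, dm.k), dtype=float)
    degenerate: set[str] = set()
    for j, crit in enumerate(dm.criteria):
        col = dm.scores[:, j]
        lo, hi = float(col.min()), float(col.max())
        if hi == lo:
            out[:, j] = 0.0
            degenerate.add(crit.name)
        elif crit.direction == "beneficial":
            out[:, j] = (col - lo) / (hi - lo)
        else:
            out[:, j] = (hi - col) / (hi - lo)
    if rounding is not None:
        out = round_half_up_array(out, rounding)
    values = pd.DataFrame(out, index=list(dm.alternatives),
                          columns=list(dm.criterion_names))
    return NormalizedMatrix(values=values, degenerate=frozenset(degenerate))


# ---------------------------------------------------------------------------
# Stage 3: pairwise deviations
# ---------------------------------------------------------------------------

def deviation(norm: NormalizedMatrix, criterion: str | int,
              z: str | int, y: str | int) -> float:
    """Evaluation difference w_j(z, y) = t_j(z) - t_j(y) on one criterion."""
    df = norm.values
    try:
        col = df.iloc[:, criterion] if isinstance(criterion, int) else df[criterion]
        tz = col.iloc[z] if isinstance(z, int) else col.loc[z]
        ty = col.iloc[y] if isinstance(y, int) else col.loc[y]
    except (KeyError, IndexError):
        raise DomainError(
            f"unknown criterion or alternative in deviation lookup: "
            f"criterion={criterion!r}, z={z!r}, y={y!r}"
        ) from None
    return float(tz - ty)


# ---------------------------------------------------------------------------
# Stage 4: preference functions
# ---------------------------------------------------------------------------

def preference_value(w: float, spec: PreferenceFunctionSpec) -> float:
    """Preference degree of a deviation under a generalized criterion.

    Every kind returns 0 for w <= 0. ``paper-linear`` is the identity on
    positive deviations (clamped at 1), which on min-max normalized scores
    coincides with a V-shape criterion with p equal to the full score range.
    """
    w = float(w)
    if w <= 0.0:
        return 0.0
    k = spec.kind
    if k == "paper-linear":
        return min(w, 1.0)
    if k == "usual":
        return 1.0
    if k == "u-shape":
        return 1.0 if w > spec.q else 0.0
    if k == "v-shape":
        return min(w / spec.p, 1.0)
    if k == "level":
        if w <= spec.q:
            return 0.0
        return 0.5 if w <= spec.p else 1.0
    if k == "v-shape-indifference":
        if w <= spec.q:
            return 0.0
        if w <= spec.p:
            return (w - spec.q) / (spec.p - spec.q)
        return 1.0
    if k == "gaussian":
        return 1.0 - math.exp(-(w * w) / (2.0 * spec.s * spec.s))
    raise ConfigurationError(f"unknown preference function kind {k!r}")


def pairwise_preferences(
    norm: NormalizedMatrix, criteria: Sequence[Criterion]
) -> dict[str, pd.DataFrame]:
    """P_j(z, y) for every criterion and ordered pair; NaN diagonal."""
    alts = list(norm.alternatives)
    m = len(alts)
    per: dict[str, pd.DataFrame] = {}
    for j, crit in enumerate(criteria):
        t = norm.values.iloc[:, j].to_numpy()
        P = np.full((m, m), np.nan)
        for a in range(m):
            for b in range(m):
                if a != b:
                    P[a, b] = preference_value(t[a] - t[b], crit.pf)
        per[crit.name] = pd.DataFrame(P, index=alts, columns=alts)
    return per


# ---------------------------------------------------------------------------
# Stage 5: weighted aggregation
# ---------------------------------------------------------------------------

def aggregate_preferences(
    per_criterion: Mapping[str, pd.DataFrame],
    weights: Mapping[str, float] | Sequence[float],
    rounding: int | None = None,
) -> pd.DataFrame:
    """pi(z, y) = sum_j d_j P_j(z, y); weights must sum to 1.

    ``rounding`` (paper mode: 3) rounds each aggregated value half-up.
    """
    names = list(per_criterion.keys())
    if isinstance(weights, Mapping):
        try:
            w = np.array([float(weights[n]) for n in names])
        except KeyError as e:
            raise ConfigurationError(f"missing weight for criterion {e.args[0]!r}")
    else:
        w = np.asarray(list(weights), dtype=float)
        if len(w) != len(names):
            raise ConfigurationError(
                f"{len(w)} weights supplied for {len(names)} preference tables"
            )
    if abs(float(w.sum()) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"weights must sum to 1 (got {w.sum():.6g}); apply normalize_weights first"
        )
    first = next(iter(per_criterion.values()))
    pi = np.zeros(first.shape, dtype=float)
    for wj, name in zip(w, names):
        tbl = per_criterion[name]
        if tbl.shape != first.shape:
            raise ConfigurationError(
                f"preference table for {name!r} has shape {tbl.shape}, "
                f"expected {first.shape}"
            )
        pi = pi + wj * tbl.to_numpy()
    if rounding is not None:
        pi = round_half_up_array(pi, rounding)
    return pd.DataFrame(pi, index=first.index, columns=first.columns)


# ---------------------------------------------------------------------------
# Stages 6-7: flows and ranking
# ---------------------------------------------------------------------------

def _as_square(pi) -> np.ndarray:
    a = np.asarray(pi, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DomainError("aggregated preference table must be square")
    if a.shape[0] < 2:
        raise DomainError("outranking flows need at least 2 alternatives")
    return a


def positive_flow(pi) -> np.ndarray:
    """phi+(z): row sums of pi over y != z, divided by n - 1."""
    a = _as_square(pi)
    return np.nansum(np.where(np.eye(len(a), dtype=bool), 0.0, a), axis=1) / (len(a) - 1)


def negative_flow(pi) -> np.ndarray:
    """phi-(z): column sums of pi over y != z, divided by n - 1."""
    a = _as_square(pi)
    return np.nansum(np.where(np.eye(len(a), dtype=bool), 0.0, a), axis=0) / (len(a) - 1)


def net_flow(phi_plus, phi_minus) -> np.ndarray:
    """phi = phi+ - phi-, elementwise."""
    p, q = np.asarray(phi_plus, float), np.asarray(phi_minus, float)
    if p.shape != q.shape:
        raise DomainError(
            f"flow vectors differ in length: {p.shape} vs {q.shape}"
        )
    return p - q


def competition_ranks(phi) -> np.ndarray:
    """Competition (\"1224\") ranks of net flows, descending.

    Tied alternatives share the smallest applicable rank; the next rank is
    skipped accordingly. Equality is exact: identical inputs produce
    identical flows bit-for-bit, so ties need no tolerance.
    """
    phi = np.asarray(phi, dtype=float)
    return np.array([1 + int(np.sum(phi > v)) for v in phi], dtype=int)


def rank_alternatives(phi_plus, phi_minus, alternatives: Sequence[str]) -> FlowTable:
    """Assemble the flow table: phi+, phi-, net flow and competition rank."""
    phi = net_flow(phi_plus, phi_minus)
    table = pd.DataFrame(
        {
            "phi_plus": np.asarray(phi_plus, float),
            "phi_minus": np.asarray(phi_minus, float),
            "phi_net": phi,
            "rank": competition_ranks(phi),
        },
        index=list(alternatives),
    )
    return FlowTable(table=table)


# ---------------------------------------------------------------------------
# The composed pipeline
# ---------------------------------------------------------------------------

def run_promethee2(dm: DecisionMatrix, mode: str = "full-precision") -> PrometheeResult:
    """Run all stages on a decision matrix.

    ``mode='paper'`` rounds half-up to 3 decimals after normalization and
    after aggregation (worked-example reproduction); ``'full-precision'``
    (alias ``'full'``) applies no intermediate rounding.
    """
    if mode == "full":
        mode = "full-precision"
    if mode not in MODES:
        raise ConfigurationError(
            f"unknown mode {mode!r}; expected 'paper' or 'full-precision'"
        )
    rounding = 3 if mode == "paper" else None

    criteria = normalize_weights(dm.criteria)
    dm = dm.with_criteria(criteria)

    norm = normalize(dm, rounding=rounding)
    per = pairwise_preferences(norm, dm.criteria)
    pi = aggregate_preferences(
        per, {c.name: c.weight for c in dm.criteria}, rounding=rounding
    )
    flows = rank_alternatives(
        positive_flow(pi.to_numpy()),
        negative_flow(pi.to_numpy()),
        dm.alternatives,
    )
    prefs = PreferenceStructure(per_criterion=per, aggregated=pi)
    return PrometheeResult(
        decision_matrix=dm,
        normalized=norm,
        preferences=prefs,
        flows=flows,
        mode=mode,
        rounding=rounding,
    )


# ---------------------------------------------------------------------------
# Valued outranking graph
# ---------------------------------------------------------------------------

def export_outranking_graph(
    pi: pd.DataFrame, threshold: float = 0.0
) -> list[tuple[str, str, float]]:
    """Weighted directed edge list of the valued outranking graph.

    One edge per ordered pair (z, y), z != y, with pi(z, y) >= threshold and
    weight pi(z, y). The default threshold 0 emits both arcs of every pair
    (the full valued graph); raising it prunes weak outrankings.
    """
    if threshold < 0:
        raise DomainError(f"threshold must be nonnegative, got {threshold}")
    edges: list[tuple[str, str, float]] = []
    alts = list(pi.index)
    vals = pi.to_numpy()
    for a, z in enumerate(alts):
        for b, y in enumerate(alts):
            if a == b:
                continue
            w = float(vals[a, b])
            if not np.isnan(w) and w >= threshold:
                edges.append((z, y, w))
    return edges
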