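"""Linguistic elicitation: verbal judgements → crisp scores → decision matrix.

Experts rate each (alternative, criterion) cell on an ordered verbal scale
("High" … "Null"). Each label carries a fixed crisp score in [0, 1]; a panel
of such ratings is aggregated — by modal label, or by mean/median of the
crisp conversions — into one crisp decision matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Criterion, DecisionMatrix
from .errors import DomainError, ElicitationError

__all__ = [
    "LinguisticScale",
    "FIVE_POINT_SCALE",
    "ExpertPanel",
    "to_crisp",
    "from_crisp",
    "aggregate_panel",
    "AGGREGATION_METHODS",
]

AGGREGATION_METHODS = ("mode", "mean-of-crisp", "median-of-crisp")


def _canon(label: str) -> str:
    return " ".join(str(label).strip().split()).lower()


@dataclass(frozen=True)
class LinguisticScale:
    """Ordered verbal scale with crisp values, best label first.

    Invariants: at least two labels, values strictly decreasing along the
    label order, all values in [0, 1].
    """

    labels: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)
        if len(labels) != len(values):
            raise ElicitationError("scale labels and values differ in length")
        if len(labels) < 2:
            raise ElicitationError("a linguistic scale needs at least 2 labels")
        if any(not (0.0 <= v <= 1.0) for v in values):
            raise ElicitationError("scale values must lie in [0, 1]")
        if any(values[i] <= values[i + 1] for i in range(len(values) - 1)):
            raise ElicitationError(
                "scale values must be strictly decreasing from best to worst"
            )
        if len({_canon(l) for l in labels}) != len(labels):
            raise ElicitationError("scale labels must be distinct")

    @property
    def lookup(self) -> dict[str, float]:
        return {_canon(l): v for l, v in zip(self.labels, self.values)}

    def __len__(self) -> int:
        return len(self.labels)


#: The 5-point verbal scale used for the inhibitor case study.
FIVE_POINT_SCALE = LinguisticScale(
    labels=("High", "Average", "Low", "Very Low", "Null"),
    values=(1.000, 0.666, 0.333, 0.250, 0.000),
)


def to_crisp(label: str, scale: LinguisticScale = FIVE_POINT_SCALE) -> float:
    """Crisp score of a scale label (case-insensitive, whitespace-trimmed)."""
    try:
        return scale.lookup[_canon(label)]
    except KeyError:
        raise ElicitationError(
            f"unknown label {label!r}; allowed labels: "
            f"{', '.join(scale.labels)}"
        ) from None


def from_crisp(value: float, scale: LinguisticScale = FIVE_POINT_SCALE) -> str:
    """Label whose crisp value is nearest to ``value``; ties go to the
    higher-valued (better) label.

    Distances are compared with a 1e-12 slack so that exact decimal ties
    (e.g. 0.2915 between 0.250 and 0.333) resolve upward regardless of
    binary floating-point representation.
    """
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise DomainError(f"crisp value must lie in [0, 1], got {value!r}")
    best_label, best_dist = scale.labels[0], abs(value - scale.values[0])
    for label, v in zip(scale.labels[1:], scale.values[1:]):
        d = abs(value - v)
        if d < best_dist - 1e-12:  # strict improvement only: keep better label on ties
            best_label, best_dist = label, d
    return best_label


@dataclass(frozen=True)
class ExpertPanel:
    """Long-format panel of linguistic ratings.

    ``responses`` has one row per (expert, alternative, criterion) with
    columns ``expert_id``, ``alternative``, ``criterion``, ``label``. Every
    expert must rate every cell exactly once (a complete crossing).
    """

    responses: pd.DataFrame
    scale: LinguisticScale = field(default=FIVE_POINT_SCALE)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.responses).copy()
        required = ["expert_id", "alternative", "criterion", "label"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ElicitationError(
                f"panel is missing column(s): {', '.join(missing)}"
            )
        if df.empty:
            raise ElicitationError("panel contains no responses")
        lookup = self.scale.lookup
        for label in df["label"].unique():
            if _canon(label) not in lookup:
                raise ElicitationError(
                    f"unknown label {label!r} in panel; allowed labels: "
                    f"{', '.join(self.scale.labels)}"
                )
        counts = df.groupby(["expert_id"], sort=False).size()
        n_cells = df[["alternative", "criterion"]].drop_duplicates().shape[0]
        dup = df.duplicated(["expert_id", "alternative", "criterion"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ElicitationError(
                f"expert {row['expert_id']!r} rates cell "
                f"({row['alternative']!r}, {row['criterion']!r}) more than once"
            )
        if counts.nunique() != 1 or counts.iloc[0] != n_cells:
            raise ElicitationError(
                "panel is ragged: every expert must rate every "
                "(alternative, criterion) cell"
            )
        object.__setattr__(self, "responses", df)

    @property
    def n_experts(self) -> int:
        return self.responses["expert_id"].nunique()

    @property
    def alternatives(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.responses["alternative"]))

    @property
    def criteria(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.responses["criterion"]))


def _aggregate_cell(labels: list[str], scale: LinguisticScale, method: str) -> float:
    crisp = [to_crisp(l, scale) for l in labels]
    if method == "mode":
        counts = Counter(to_crisp(l, scale) for l in labels)
        # most frequent crisp value; ties resolved toward the higher value
        return max(counts, key=lambda v: (counts[v], v))
    if method == "mean-of-crisp":
        return float(np.mean(crisp))
    if method == "median-of-crisp":
        return float(np.median(crisp))
    raise ElicitationError(
        f"unknown aggregation method {method!r}; expected one of "
        f"{', '.join(AGGREGATION_METHODS)}"
    )


def aggregate_panel(
    panel: ExpertPanel,
    scale: LinguisticScale | None = None,
    method: str = "mode",
    criteria: list[Criterion] | None = None,
) -> DecisionMatrix:
    """Collapse a multi-expert panel into one crisp decision matrix.

    ``mode`` (default) takes the crisp value of the most frequent label per
    cell, ties toward the higher value — the output then stays on the scale.
    ``mean-of-crisp`` / ``median-of-crisp`` take the statistic of the crisp
    conversions. The chosen method is recorded in the matrix metadata.

    If ``criteria`` is given it supplies weights/directions/preference
    functions (names must match the panel); otherwise criteria default to
    beneficial with equal weights.
    """
    scale = scale if scale is not None else panel.scale
    alts, crits = panel.alternatives, panel.criteria
    if criteria is not None:
        names = tuple(c.name for c in criteria)
        if set(names) != set(crits) or len(names) != len(crits):
            raise ElicitationError(
                f"criteria config names {names} do not match panel criteria {crits}"
            )
        crits = names
        crit_objs = tuple(criteria)
    else:
        crit_objs = tuple(
            Criterion(name=c, weight=1.0 / len(crits)) for c in crits
        )

    grouped = panel.responses.groupby(["alternative", "criterion"], sort=False)[
        "label"
    ].agg(list)
    scores = np.empty((len(alts), len(crits)), dtype=float)
    for i, a in enumerate(alts):
        for j, c in enumerate(crits):
            scores[i, j] = _aggregate_cell(grouped[(a, c)], scale, method)

    return DecisionMatrix(
        alternatives=alts,
        criteria=crit_objs,
        scores=scores,
        meta={"aggregation": method, "n_experts": panel.n_experts},
    )
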