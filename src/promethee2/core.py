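"""Decision problem containers: criteria, preference-function specs, matrices.

A decision problem is a set of alternatives scored against weighted criteria.
Each criterion has a direction (``beneficial`` — higher is better — or
``cost``), a nonnegative weight, and a preference-function spec used by the
outranking pipeline. The module also packages the nine-inhibitor /
three-growth-factor case study so the full analysis runs with no external
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PF_KINDS",
    "PreferenceFunctionSpec",
    "Criterion",
    "DecisionMatrix",
    "ValidationReport",
    "validate_matrix",
    "normalize_weights",
    "paper_case_study",
]

#: Preference-function kinds. The six classical generalized criteria plus
#: ``paper-linear``: identity on positive deviations (zero otherwise), the
#: natural choice when deviations are already min-max normalized to [0, 1].
PF_KINDS = (
    "usual",
    "u-shape",
    "v-shape",
    "level",
    "v-shape-indifference",
    "gaussian",
    "paper-linear",
)

_REQUIRED_THRESHOLDS = {
    "usual": (),
    "paper-linear": (),
    "u-shape": ("q",),
    "v-shape": ("p",),
    "level": ("q", "p"),
    "v-shape-indifference": ("q", "p"),
    "gaussian": ("s",),
}


@dataclass(frozen=True)
class PreferenceFunctionSpec:
    """How a positive deviation on one criterion maps to a preference degree.

    Parameters
    ----------
    kind
        One of :data:`PF_KINDS`.
    q
        Indifference threshold (deviations ≤ q carry no preference).
    p
        Strict-preference threshold (deviations > p carry full preference).
    s
        Gaussian inflection point (> 0).
    """

    kind: str = "paper-linear"
    q: float | None = None
    p: float | None = None
    s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PF_KINDS:
            raise ConfigurationError(
                f"unknown preference function kind {self.kind!r}; "
                f"expected one of {', '.join(PF_KINDS)}"
            )
        for name in _REQUIRED_THRESHOLDS[self.kind]:
            if getattr(self, name) is None:
                raise ConfigurationError(
                    f"preference function {self.kind!r} requires threshold {name!r}"
                )
        if self.q is not None and self.q < 0:
            raise ConfigurationError("indifference threshold q must be >= 0")
        if self.p is not None and self.q is not None and self.p < self.q:
            raise ConfigurationError("thresholds must satisfy q <= p")
        if self.kind == "gaussian" and (self.s is None or self.s <= 0):
            raise ConfigurationError("gaussian inflection s must be > 0")


@dataclass(frozen=True)
class Criterion:
    """A named, weighted, directed criterion with its preference function."""

    name: str
    direction: str = "beneficial"
    weight: float = 1.0
    pf: PreferenceFunctionSpec = field(default_factory=PreferenceFunctionSpec)

    def __post_init__(self) -> None:
        if self.direction not in ("beneficial", "cost"):
            raise ConfigurationError(
                f"criterion {self.name!r}: direction must be 'beneficial' or "
                f"'cost', got {self.direction!r}"
            )
        if not math.isfinite(self.weight) or self.weight < 0:
            raise ConfigurationError(
                f"criterion {self.name!r}: weight must be a finite nonnegative "
                f"number, got {self.weight!r}"
            )


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives × criteria table of crisp performance scores.

    ``scores[i, j]`` is the performance of alternative ``i`` on criterion
    ``j``. Row and column order is preserved through every downstream table.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[Criterion, ...]
    scores: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        scores = np.array(self.scores, dtype=float)
        if scores.ndim != 2:
            raise ConfigurationError("scores must be a 2-D table")
        if scores.shape != (len(self.alternatives), len(self.criteria)):
            raise ConfigurationError(
                f"scores shape {scores.shape} does not match "
                f"{len(self.alternatives)} alternatives x "
                f"{len(self.criteria)} criteria"
            )
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    # -- convenience views -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.alternatives)

    @property
    def k(self) -> int:
        return len(self.criteria)

    @property
    def criterion_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.criteria)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.criteria], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.alternatives),
            columns=list(self.criterion_names),
        )

    def with_criteria(self, criteria: Sequence[Criterion]) -> "DecisionMatrix":
        return replace(self, criteria=tuple(criteria))


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_matrix`: hard failures and soft warnings."""

    failures: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.failures

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = ["valid" if self.ok else "INVALID"]
        lines += [f"  failure: {f}" for f in self.failures]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def validate_matrix(dm: DecisionMatrix) -> ValidationReport:
    """Check a decision matrix for structural defects.

    Hard failures: fewer than two alternatives or one criterion, missing
    (NaN) or non-finite cells, duplicate alternative/criterion names, an
    all-zero weight vector. Degenerate criteria (constant columns) are
    flagged as warnings — they carry no discriminating information but do
    not invalidate the problem.
    """
    failures: list[str] = []
    warnings: list[str] = []

    if dm.m < 2:
        failures.append(f"need at least 2 alternatives, got {dm.m}")
    if dm.k < 1:
        failures.append("need at least 1 criterion")

    seen: set[str] = set()
    for a in dm.alternatives:
        if a in seen:
            failures.append(f"duplicate alternative name {a!r}")
        seen.add(a)
    seen = set()
    for c in dm.criterion_names:
        if c in seen:
            failures.append(f"duplicate criterion name {c!r}")
        seen.add(c)

    for i, alt in enumerate(dm.alternatives):
        for j, crit in enumerate(dm.criteria):
            v = dm.scores[i, j]
            if np.isnan(v):
                failures.append(f"missing score in cell ({alt}, {crit.name})")
            elif not np.isfinite(v):
                failures.append(f"non-finite score in cell ({alt}, {crit.name})")

    w = dm.weights
    if dm.k >= 1 and not np.any(w > 0):
        failures.append("all criterion weights are zero")
    elif abs(float(w.sum()) - 1.0) > 1e-9:
        warnings.append(
            f"criterion weights sum to {w.sum():.6g}, not 1; they will be "
            "renormalized by the pipeline"
        )

    if not failures:
        for j, crit in enumerate(dm.criteria):
            col = dm.scores[:, j]
            if col.max() == col.min():
                warnings.append(
                    f"criterion {crit.name!r} is degenerate (constant column); "
                    "it cannot discriminate between alternatives"
                )

    return ValidationReport(tuple(failures), tuple(warnings))


def normalize_weights(criteria: Sequence[Criterion]) -> list[Criterion]:
    """Rescale criterion weights to sum to one, preserving order.

    Weights already summing to 1 within 1e-9 are returned unchanged (no
    silent reweighting). Any negative weight, or an all-zero vector, is a
    configuration error.
    """
    criteria = list(criteria)
    w = np.array([c.weight for c in criteria], dtype=float)
    if np.any(w < 0):
        bad = [c.name for c in criteria if c.weight < 0]
        raise ConfigurationError(f"negative weight for criteria: {', '.join(bad)}")
    total = float(w.sum())
    if total <= 0:
        raise ConfigurationError("criterion weights must not all be zero")
    if abs(total - 1.0) <= 1e-9:
        return criteria
    return [replace(c, weight=c.weight / total) for c in criteria]


# ---------------------------------------------------------------------------
# Packaged case study
# ---------------------------------------------------------------------------

#: Nine anti-angiogenic receptor-tyrosine-kinase inhibitors scored on the
#: three angiogenic growth-factor criteria (VEGF, FGF, PDGF) on the 5-point
#: linguistic scale, as elicited from a 72-expert panel. In1=ponatinib,
#: In2=SU 5402, In3=regorafenib, In4=nintedanib, In5=linifanib,
#: In6=dovitinib, In7=sorafenib, In8=pazopanib HCl, In9=lenvatinib.
_CASE_STUDY_SCORES = [
    # GF1    GF2    GF3
    [0.333, 0.250, 0.333],  # In1
    [0.333, 0.250, 0.333],  # In2
    [1.000, 0.000, 0.333],  # In3
    [1.000, 0.666, 0.666],  # In4
    [0.333, 0.000, 0.333],  # In5
    [1.000, 0.333, 0.666],  # In6
    [0.666, 0.000, 0.333],  # In7
    [1.000, 0.250, 0.333],  # In8
    [1.000, 1.000, 0.333],  # In9
]

_CASE_STUDY_WEIGHTS = {"GF1": 0.45, "GF2": 0.35, "GF3": 0.20}

CASE_STUDY_ALIASES = {
    "In1": "AP24534 (ponatinib)",
    "In2": "SU 5402",
    "In3": "BAY73-4506 (regorafenib)",
    "In4": "BIBF 1120 (nintedanib)",
    "In5": "ABT-869 (linifanib)",
    "In6": "CHIR-258 (dovitinib)",
    "In7": "Bay43-9006 (sorafenib)",
    "In8": "GW786034 HCl (pazopanib)",
    "In9": "E7080 (lenvatinib)",
}


def paper_case_study() -> DecisionMatrix:
    """The packaged inhibitor / growth-factor case study.

    Nine alternatives (In1…In9) by three beneficial criteria (GF1, GF2, GF3)
    with weights 0.45 / 0.35 / 0.20 and the paper-linear preference function.
    Every cell is a value of the 5-point linguistic scale.
    """
    criteria = tuple(
        Criterion(name=n, direction="beneficial", weight=w,
                  pf=PreferenceFunctionSpec("paper-linear"))
        for n, w in _CASE_STUDY_WEIGHTS.items()
    )
    return DecisionMatrix(
        alternatives=tuple(f"In{i}" for i in range(1, 10)),
        criteria=criteria,
        scores=np.array(_CASE_STUDY_SCORES, dtype=float),
        meta={"source": "packaged RTK-inhibitor case study",
              "aliases": dict(CASE_STUDY_ALIASES)},
    )
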