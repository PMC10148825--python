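"""File formats: decision matrices, panels, criteria configs, result tables.

Delimited text throughout (tab or comma, '.' decimal point). Result tables
mirror the standard worked-example layout: normalized matrix, long-form
pairwise preference table, flow table with ranks, plus a DOT export of the
valued outranking graph and a JSON run manifest sufficient to reproduce the
run.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    Criterion,
    DecisionMatrix,
    PreferenceFunctionSpec,
    validate_matrix,
)
from .elicitation import FIVE_POINT_SCALE, ExpertPanel, LinguisticScale
from .errors import ConfigurationError, ParseError
from .pipeline import PrometheeResult, export_outranking_graph

__all__ = [
    "read_decision_matrix",
    "write_decision_matrix",
    "read_panel",
    "write_panel",
    "load_criteria_config",
    "load_scale",
    "write_results",
    "read_flows",
    "edges_to_dot",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    try:
        # sep=None sniffs comma vs tab
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as e:  # pandas raises several parser error types
        raise ParseError(f"could not parse {path}: {e}") from e


def read_decision_matrix(
    path: str | Path,
    criteria: Sequence[Criterion] | None = None,
) -> DecisionMatrix:
    """Read a decision matrix: first column alternative id, one column per
    criterion, header row of criterion names.

    When a criteria config is supplied, the file header must list exactly the
    configured names (in any order); otherwise criteria default to beneficial
    with equal weights.
    """
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError(
            f"{path}: need an alternative column plus at least one criterion column"
        )
    alt_col = df.columns[0]
    alts = [str(a) for a in df[alt_col]]
    dup = {a for a in alts if alts.count(a) > 1}
    if dup:
        raise ParseError(
            f"{path}: duplicate alternative id(s): {', '.join(sorted(dup))}"
        )
    names = [str(c) for c in df.columns[1:]]
    if criteria is not None:
        wanted = [c.name for c in criteria]
        if sorted(wanted) != sorted(names):
            raise ParseError(
                f"{path}: header criteria {names} do not match configured "
                f"criteria {wanted}"
            )
        by_name = {c.name: c for c in criteria}
        crit_objs = tuple(by_name[n] for n in names)
    else:
        crit_objs = tuple(Criterion(name=n, weight=1.0 / len(names)) for n in names)

    scores = np.empty((len(alts), len(names)), dtype=float)
    for j, n in enumerate(names):
        for i, v in enumerate(df[n]):
            try:
                scores[i, j] = float(v)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell at row {i + 2} (alternative "
                    f"{alts[i]!r}), column {n!r}: {v!r}"
                ) from None
    return DecisionMatrix(
        alternatives=tuple(alts), criteria=crit_objs, scores=scores,
        meta={"source": str(path)},
    )


def write_decision_matrix(dm: DecisionMatrix, path: str | Path,
                          sep: str = "\t", float_format: str = "%.6g") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = dm.to_frame()
    df.index.name = "alternative"
    df.to_csv(path, sep=sep, float_format=float_format)
    return path


def read_panel(path: str | Path,
               scale: LinguisticScale = FIVE_POINT_SCALE) -> ExpertPanel:
    """Read a long-format panel (expert_id, alternative, criterion, label)."""
    df = _read_table(path)
    return ExpertPanel(responses=df, scale=scale)


def write_panel(panel: ExpertPanel, path: str | Path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    panel.responses.to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_scale(obj: dict | None) -> LinguisticScale:
    """Scale from a config block {labels: [...], values: [...]}; defaults to
    the 5-point scale when omitted."""
    if obj is None:
        return FIVE_POINT_SCALE
    if not isinstance(obj, dict) or "labels" not in obj or "values" not in obj:
        raise ConfigurationError(
            "scale config must be a mapping with 'labels' and 'values'"
        )
    return LinguisticScale(labels=tuple(obj["labels"]), values=tuple(obj["values"]))


def _parse_pf(obj) -> PreferenceFunctionSpec:
    if obj is None:
        return PreferenceFunctionSpec()
    if isinstance(obj, str):
        return PreferenceFunctionSpec(kind=obj)
    if not isinstance(obj, dict):
        raise ConfigurationError(f"pf spec must be a name or mapping, got {obj!r}")
    unknown = set(obj) - {"kind", "q", "p", "s"}
    if unknown:
        raise ConfigurationError(f"unknown pf field(s): {sorted(unknown)}")
    return PreferenceFunctionSpec(
        kind=obj.get("kind", "paper-linear"),
        q=obj.get("q"), p=obj.get("p"), s=obj.get("s"),
    )


def load_criteria_config(source: str | Path | dict | list) -> list[Criterion]:
    """Criteria from JSON/YAML: a list (or a mapping with key ``criteria``)
    of per-criterion blocks {name, direction, weight, pf}."""
    if isinstance(source, (str, Path)):
        source = _load_structured(source)
    if isinstance(source, dict):
        source = source.get("criteria", source)
    if not isinstance(source, list) or not source:
        raise ConfigurationError(
            "criteria config must be a non-empty list of criterion blocks"
        )
    out: list[Criterion] = []
    for i, block in enumerate(source):
        if not isinstance(block, dict) or "name" not in block:
            raise ConfigurationError(
                f"criterion block #{i + 1} must be a mapping with a 'name'"
            )
        unknown = set(block) - {"name", "direction", "weight", "pf"}
        if unknown:
            raise ConfigurationError(
                f"criterion {block['name']!r}: unknown field(s) {sorted(unknown)}"
            )
        out.append(
            Criterion(
                name=str(block["name"]),
                direction=block.get("direction", "beneficial"),
                weight=float(block.get("weight", 1.0)),
                pf=_parse_pf(block.get("pf")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def edges_to_dot(edges: list[tuple[str, str, float]],
                 name: str = "outranking") -> str:
    """DOT source for a weighted directed outranking graph."""
    lines = [f"digraph {name} {{"]
    for z, y, w in edges:
        lines.append(f'  "{z}" -> "{y}" [weight={w:.6f}, label="{w:.3f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_results(
    result: PrometheeResult,
    out_dir: str | Path,
    seed: int | None = None,
    graph_threshold: float = 0.0,
    config_echo: dict | None = None,
    notes: Sequence[str] = (),
) -> dict[str, Path]:
    """Write the standard result file set.

    ``normalized.tsv``, ``preferences.tsv`` (long form: z, y, per-criterion
    P, pi), ``flows.tsv`` (phi+, phi-, phi, rank; 6 decimals), ``graph.dot``
    and ``run_manifest.json``. Intermediates use 3 decimals in paper mode and
    6 otherwise. Returns the paths, keyed by file stem.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inter_fmt = "%.3f" if result.mode == "paper" else "%.6f"

    paths: dict[str, Path] = {}

    norm = result.normalized.values.copy()
    norm.index.name = "alternative"
    paths["normalized"] = out / "normalized.tsv"
    norm.to_csv(paths["normalized"], sep="\t", float_format=inter_fmt)

    alts = list(result.preferences.aggregated.index)
    crit_names = list(result.preferences.per_criterion)
    rows = []
    for z in alts:
        for y in alts:
            if z == y:
                continue
            row = {"z": z, "y": y}
            for c in crit_names:
                row[f"P_{c}"] = result.preferences.per_criterion[c].loc[z, y]
            row["pi"] = result.preferences.aggregated.loc[z, y]
            rows.append(row)
    paths["preferences"] = out / "preferences.tsv"
    pd.DataFrame(rows).to_csv(paths["preferences"], sep="\t", index=False,
                              float_format=inter_fmt)

    flows = result.flows.table.copy()
    flows.index.name = "alternative"
    paths["flows"] = out / "flows.tsv"
    flows.to_csv(paths["flows"], sep="\t", float_format="%.6f")

    edges = export_outranking_graph(result.preferences.aggregated,
                                    threshold=graph_threshold)
    paths["graph"] = out / "graph.dot"
    paths["graph"].write_text(edges_to_dot(edges))

    manifest = {
        "package": "promethee2",
        "version": __version__,
        "mode": result.mode,
        "rounding": result.rounding,
        "seed": seed,
        "graph_threshold": graph_threshold,
        "alternatives": list(result.decision_matrix.alternatives),
        "criteria": [
            {
                "name": c.name,
                "direction": c.direction,
                "weight": c.weight,
                "pf": {"kind": c.pf.kind, "q": c.pf.q, "p": c.pf.p, "s": c.pf.s},
            }
            for c in result.decision_matrix.criteria
        ],
        "validation_warnings": list(validate_matrix(result.decision_matrix).warnings),
        "config": config_echo or {},
        "notes": list(notes),
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    paths["manifest"] = out / "run_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


def read_flows(path: str | Path) -> pd.DataFrame:
    """Read back a flows.tsv written by :func:`write_results`."""
    df = _read_table(path)
    if "alternative" not in df.columns:
        raise ParseError(f"{path}: missing 'alternative' column")
    df = df.set_index("alternative")
    expected = {"phi_plus", "phi_minus", "phi_net", "rank"}
    missing = expected - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    df["rank"] = df["rank"].astype(int)
    return df
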