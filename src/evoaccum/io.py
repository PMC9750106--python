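"""Readers and writers for the artifact formats.

* Cross-sectional data: CSV, header row of event names, 0/1 cells.
* Models: one JSON schema for all five families (bit-exact round trip).
* Genotype distributions, rate/transition matrices, paths: labelled CSV
  (genotypes as ``"WT"`` or comma-joined event names, canonical order).
* Graphs: DOT text (restriction DAGs annotated with relation and
  parameter; transition graphs annotated with rates/probabilities).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctmc import RateMatrix, TransitionMatrix
from .models import (
    MHN as MHN_FAMILY, SINGLE,
    CrossSectionalData, EventSet, GenotypeDistribution, MHNModel,
    RestrictionDAG, canonical_states, genotype_label, validate_model,
)
from .paths import EvolutionaryPath

__all__ = [
    "read_csd", "write_csd", "genotype_counts", "data_from_counts",
    "model_to_dict", "model_from_dict", "read_model", "write_model",
    "distribution_frame", "write_distribution",
    "matrix_frame", "write_matrix",
    "paths_frame", "write_paths",
    "export_dot",
]


# ---------------------------------------------------------------------------
# Cross-sectional data


def read_csd(path: str | Path) -> CrossSectionalData:
    """Read a cross-sectional 0/1 matrix from CSV (header = event names)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    rows = list(csv.reader(text.splitlines()))
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate column name(s) {dupes}")
    n = len(header)
    matrix = np.zeros((len(rows) - 1, n), dtype=np.int8)
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n:
            raise ValueError(
                f"{path}: ragged row at line {r} ({len(row)} cells, expected {n})"
            )
        for c, cell in enumerate(row):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise ValueError(
                    f"{path}: non-binary cell {cell!r} at line {r}, "
                    f"column {header[c]!r}"
                )
            matrix[r - 2, c] = int(cell)
    return CrossSectionalData(EventSet(header), matrix)


def write_csd(data: CrossSectionalData, path: str | Path) -> None:
    pd.DataFrame(data.rows, columns=list(data.events.names)).to_csv(
        path, index=False
    )


def genotype_counts(data: CrossSectionalData) -> dict[int, int]:
    """Genotype bit mask -> number of individuals, canonical order."""
    ints = data.genotype_ints()
    vals, counts = np.unique(ints, return_counts=True)
    pairs = {int(g): int(c) for g, c in zip(vals, counts)}
    return {
        g: pairs[g]
        for g in sorted(pairs, key=lambda g: (g.bit_count(), g))
    }


def data_from_counts(
    events: EventSet, counts: Mapping[int, int]
) -> CrossSectionalData:
    """Inverse of :func:`genotype_counts` up to row order."""
    gs = np.repeat(
        np.fromiter(counts.keys(), dtype=np.int64),
        np.fromiter(counts.values(), dtype=np.int64),
    )
    rows = (gs[:, None] >> np.arange(events.n) & 1).astype(np.int8)
    return CrossSectionalData(events, rows)


# ---------------------------------------------------------------------------
# Model JSON (single interchange format)


def model_to_dict(model: RestrictionDAG | MHNModel) -> dict:
    if isinstance(model, MHNModel):
        return {
            "family": MHN_FAMILY,
            "events": list(model.events.names),
            "theta": model.theta.tolist(),
        }
    return {
        "family": model.family,
        "events": list(model.events.names),
        "nodes": [
            {
                "name": e,
                "parents": sorted(model.parents[e]),
                "relation": model.relation[e],
                "param": model.param[e],
            }
            for e in model.events.names
        ],
    }


def model_from_dict(d: Mapping) -> RestrictionDAG | MHNModel:
    events = EventSet(d["events"])
    if d["family"] == MHN_FAMILY:
        model: RestrictionDAG | MHNModel = MHNModel(events, np.array(d["theta"]))
    else:
        nodes = d["nodes"]
        model = RestrictionDAG(
            events,
            {nd["name"]: set(nd["parents"]) for nd in nodes},
            {nd["name"]: nd.get("relation", SINGLE) for nd in nodes},
            {nd["name"]: nd["param"] for nd in nodes},
            d["family"],
        )
    violations = validate_model(model)
    if violations:
        raise ValueError("invalid model: " + "; ".join(violations))
    return model


def read_model(path: str | Path) -> RestrictionDAG | MHNModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def write_model(model: RestrictionDAG | MHNModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Tabular writers (canonical genotype order throughout)


def distribution_frame(dist: GenotypeDistribution) -> pd.DataFrame:
    states = [g for g in canonical_states(dist.events.n) if g in dist.probs]
    return pd.DataFrame(
        {
            "genotype": [genotype_label(g, dist.events) for g in states],
            "probability": [dist[g] for g in states],
        }
    )


def write_distribution(dist: GenotypeDistribution, path: str | Path) -> None:
    distribution_frame(dist).to_csv(path, index=False)


def matrix_frame(mat: RateMatrix | TransitionMatrix) -> pd.DataFrame:
    labels = [genotype_label(g, mat.events) for g in mat.states]
    values = mat.Q if isinstance(mat, RateMatrix) else mat.P
    return pd.DataFrame(values, index=labels, columns=labels)


def write_matrix(mat: RateMatrix | TransitionMatrix, path: str | Path) -> None:
    matrix_frame(mat).to_csv(path)


def paths_frame(paths: Sequence[EvolutionaryPath]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "path": [p.label() for p in paths],
            "probability": [p.probability for p in paths],
        }
    )


def write_paths(paths: Sequence[EvolutionaryPath], path: str | Path) -> None:
    paths_frame(paths).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DOT export


def _dot_escape(s: str) -> str:
    return s.replace('"', '\\"')


def export_dot(
    obj: RestrictionDAG | MHNModel | RateMatrix | TransitionMatrix
    | Sequence[EvolutionaryPath],
) -> str:
    """Render a restriction DAG (nodes annotated with relation and
    parameter), a transition graph (edges annotated with rate or
    probability) or a path list as DOT text."""
    if isinstance(obj, RestrictionDAG):
        return _dag_dot(obj)
    if isinstance(obj, MHNModel):
        raise ValueError(
            "an MHN model has no restriction DAG; export its transition "
            "graph (rate matrix) instead"
        )
    if isinstance(obj, (RateMatrix, TransitionMatrix)):
        return _matrix_dot(obj)
    return _paths_dot(list(obj))


def _dag_dot(dag: RestrictionDAG) -> str:
    lines = ["digraph restrictions {", '  Root [shape=box, label="Root"];']
    for e in dag.events.names:
        rel = dag.relation[e]
        note = f"\\n{rel}" if rel != SINGLE else ""
        lines.append(
            f'  "{_dot_escape(e)}" [label="{_dot_escape(e)}{note}"];'
        )
    for e in dag.events.names:
        ps = sorted(dag.parents[e]) or ["Root"]
        for p in ps:
            src = "Root" if p == "Root" else f'"{_dot_escape(p)}"'
            lines.append(
                f'  {src} -> "{_dot_escape(e)}" [label="{dag.param[e]:g}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _matrix_dot(mat: RateMatrix | TransitionMatrix) -> str:
    values = mat.Q if isinstance(mat, RateMatrix) else mat.P
    kind = "rates" if isinstance(mat, RateMatrix) else "probabilities"
    lines = [f"digraph transitions {{  // edge labels are {kind}"]
    for g in mat.states:
        lines.append(f'  "{_dot_escape(genotype_label(g, mat.events))}";')
    for a, g in enumerate(mat.states):
        for b, h in enumerate(mat.states):
            if a != b and values[a, b] > 0:
                lines.append(
                    f'  "{_dot_escape(genotype_label(g, mat.events))}" -> '
                    f'"{_dot_escape(genotype_label(h, mat.events))}" '
                    f'[label="{values[a, b]:.6g}"];'
                )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _paths_dot(paths: list[EvolutionaryPath]) -> str:
    if not paths:
        return "digraph paths {\n}\n"
    events = paths[0].events
    lines = ["digraph paths {"]
    seen_edges = {}
    for p in paths:
        for a, b in zip(p.genotypes, p.genotypes[1:]):
            seen_edges[(a, b)] = seen_edges.get((a, b), 0.0) + p.probability
    nodes = {g for edge in seen_edges for g in edge}
    for g in sorted(nodes, key=lambda g: (g.bit_count(), g)):
        lines.append(f'  "{_dot_escape(genotype_label(g, events))}";')
    for (a, b), w in sorted(seen_edges.items()):
        lines.append(
            f'  "{_dot_escape(genotype_label(a, events))}" -> '
            f'"{_dot_escape(genotype_label(b, events))}" [label="{w:.6g}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
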