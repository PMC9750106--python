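"""Random model generation for simulation studies and property tests.

DAG models are built by drawing a random topological order and adding
edges downward with a given density; relations are assigned per node
(forced Single for one parent, family-appropriate otherwise).  Default
parameter ranges — rates in [0.5, 2], probabilities in [0.1, 0.9] —
keep the expected number of events per sample moderate, so generated
data are neither all wild type nor all fully mutated.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .models import (
    AND, CBN, HESBCN, ONCOBN, OR, OT, SINGLE, XOR,
    DAG_FAMILIES, TIMED_FAMILIES,
    EventSet, MHNModel, RestrictionDAG, validate_model,
)

__all__ = ["random_dag_model", "random_mhn", "default_event_names"]


def default_event_names(n: int) -> tuple[str, ...]:
    """A, B, ..., L (n <= 12)."""
    return tuple("ABCDEFGHIJKL"[:n])


def random_dag_model(
    family: str,
    n: int,
    seed: int,
    *,
    density: float = 0.35,
    rate_range: tuple[float, float] = (0.5, 2.0),
    prob_range: tuple[float, float] = (0.1, 0.9),
    relation_mix: Mapping[str, float] | None = None,
    disjunctive: bool = False,
    event_names: Sequence[str] | None = None,
) -> RestrictionDAG:
    """Random restriction-DAG model of the given family.

    Parameters
    ----------
    family:
        OT, CBN, OncoBN or HESBCN.
    density:
        Probability of an edge between each earlier/later event pair
        (ignored for OT, which draws a uniform random rooted tree).
    relation_mix:
        H-ESBCN only: weights over {AND, OR, XOR} for multi-parent
        nodes; default uniform.
    disjunctive:
        OncoBN only: use OR (disjunctive form) instead of AND
        (conjunctive form) for multi-parent nodes.
    """
    if family not in DAG_FAMILIES:
        raise ValueError(f"unknown DAG family {family!r}")
    if n < 2:
        raise ValueError("random models need n >= 2")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = tuple(event_names) if event_names is not None else default_event_names(n)
    events = EventSet(names)
    order = [names[i] for i in rng.permutation(n)]

    parents: dict[str, set[str]] = {e: set() for e in names}
    if family == OT:
        # each event picks one parent among the root and its predecessors
        for k, e in enumerate(order):
            choice = rng.integers(0, k + 1)  # 0 = virtual root
            if choice > 0:
                parents[e].add(order[choice - 1])
    else:
        for k, e in enumerate(order):
            for p in order[:k]:
                if rng.random() < density:
                    parents[e].add(p)

    if family == HESBCN:
        mix = dict(relation_mix) if relation_mix else {AND: 1.0, OR: 1.0, XOR: 1.0}
        rel_names = list(mix)
        rel_w = np.array([mix[r] for r in rel_names], dtype=float)
        rel_w /= rel_w.sum()
    multi_rel = OR if disjunctive else AND

    relation = {}
    for e in names:
        if len(parents[e]) <= 1:
            relation[e] = SINGLE
        elif family == CBN:
            relation[e] = AND
        elif family == ONCOBN:
            relation[e] = multi_rel
        else:  # HESBCN
            relation[e] = rel_names[rng.choice(len(rel_names), p=rel_w)]

    lo, hi = rate_range if family in TIMED_FAMILIES else prob_range
    param = {e: float(rng.uniform(lo, hi)) for e in names}

    model = RestrictionDAG(events, parents, relation, param, family)
    violations = validate_model(model)
    if violations:  # pragma: no cover - construction keeps invariants
        raise AssertionError(f"generated invalid model: {violations}")
    return model


def random_mhn(
    n: int,
    seed: int,
    *,
    diag_range: tuple[float, float] = (-3.0, 3.0),
    offdiag_range: tuple[float, float] = (-2.0, 2.0),
    sparsity: float = 0.5,
    event_names: Sequence[str] | None = None,
) -> MHNModel:
    """Random mutual hazard network: diagonal log-hazards uniform in
    ``diag_range``; each off-diagonal is nonzero with probability
    ``1 - sparsity``, uniform in ``offdiag_range``."""
    if n < 2:
        raise ValueError("random models need n >= 2")
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = tuple(event_names) if event_names is not None else default_event_names(n)
    theta = np.where(
        rng.random((n, n)) < sparsity, 0.0,
        rng.uniform(offdiag_range[0], offdiag_range[1], size=(n, n)),
    )
    theta[np.diag_indices(n)] = rng.uniform(diag_range[0], diag_range[1], size=n)
    return MHNModel(EventSet(names), theta)
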