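"""Domain types for evolutionary accumulation (cancer progression) models.

Five model families over a common event set:

* **OT** — oncogenetic trees: untimed, each event has at most one parent,
  edge weights are conditional probabilities of the child given the parent
  by observation time.
* **CBN** — conjunctive Bayesian networks: timed, DAG of restrictions with
  AND semantics, node parameters are exponential rates.
* **OncoBN** — untimed DAG model allowing AND (conjunctive) or OR
  (disjunctive) dependencies; one relation type per model.
* **H-ESBCN** — timed DAG model allowing AND, OR and XOR dependencies.
* **MHN** — mutual hazard networks: no DAG; an n x n log-hazard matrix
  theta fully specifies the process (diagonal = baseline log-hazards,
  off-diagonal theta[j, i] = log multiplicative effect of event i on the
  rate of event j).

Genotypes are subsets of the event set encoded as integer bit masks; the
wild type (WT) is 0.  All modules share one canonical genotype ordering:
by number of events, then by numeric value of the bit pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "SINGLE", "AND", "OR", "XOR", "RELATIONS",
    "OT", "CBN", "ONCOBN", "HESBCN", "MHN",
    "DAG_FAMILIES", "TIMED_FAMILIES", "UNTIMED_FAMILIES",
    "MAX_EVENTS",
    "EventSet", "RestrictionDAG", "MHNModel",
    "CrossSectionalData", "GenotypeDistribution",
    "canonical_states", "genotype_label", "genotype_from_names",
    "genotype_events",
    "validate_model", "dependency_satisfied", "reachable_genotypes",
    "is_timed",
]

# Dependency relations
SINGLE = "Single"
AND = "AND"
OR = "OR"
XOR = "XOR"
RELATIONS = (SINGLE, AND, OR, XOR)

# Model families
OT = "OT"
CBN = "CBN"
ONCOBN = "OncoBN"
HESBCN = "HESBCN"
MHN = "MHN"

DAG_FAMILIES = (OT, CBN, ONCOBN, HESBCN)
TIMED_FAMILIES = (CBN, HESBCN, MHN)
UNTIMED_FAMILIES = (OT, ONCOBN)

#: Hard cap on the number of events: dense 2^n structures stay desk-scale.
MAX_EVENTS = 12

_FAMILY_RELATIONS = {
    OT: {SINGLE},
    CBN: {SINGLE, AND},
    ONCOBN: {SINGLE, AND, OR},
    HESBCN: {SINGLE, AND, OR, XOR},
}


@dataclass(frozen=True)
class EventSet:
    """Ordered set of distinct event labels; the order is shared by every
    structure (genotype bit masks, data columns, theta rows) built on it."""

    names: tuple[str, ...]

    def __init__(self, names: Iterable[str]):
        object.__setattr__(self, "names", tuple(names))

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValueError(
                f"unknown event {name!r}: model/data mismatch "
                f"(known events: {list(self.names)})"
            ) from None

    def violations(self) -> list[str]:
        out = []
        if not (1 <= self.n <= MAX_EVENTS):
            out.append(f"event count {self.n} outside supported range 1..{MAX_EVENTS}")
        if len(set(self.names)) != self.n:
            out.append("event names are not unique")
        if any((not isinstance(x, str)) or x == "" for x in self.names):
            out.append("event names must be non-empty strings")
        if "WT" in self.names:
            out.append('"WT" is reserved for the wild type and cannot name an event')
        return out


def canonical_states(n: int) -> list[int]:
    """All 2^n genotypes ordered by (number of events, bit-pattern value)."""
    return sorted(range(1 << n), key=lambda g: (g.bit_count(), g))


def genotype_label(g: int, events: EventSet) -> str:
    """Human-readable label: ``"WT"`` or event names joined by ``", "``."""
    if g == 0:
        return "WT"
    return ", ".join(nm for i, nm in enumerate(events.names) if g >> i & 1)


def genotype_from_names(names: Iterable[str], events: EventSet) -> int:
    g = 0
    for nm in names:
        g |= 1 << events.index(nm)
    return g


def genotype_events(g: int, events: EventSet) -> tuple[str, ...]:
    return tuple(nm for i, nm in enumerate(events.names) if g >> i & 1)


@dataclass(frozen=True)
class RestrictionDAG:
    """DAG of restrictions over an event set plus an implicit virtual root.

    ``parents[e]`` is the set of parent events of ``e`` (empty = child of
    the virtual root).  ``relation[e]`` states how multiple parents combine
    (Single/AND/OR/XOR); ``param[e]`` is an exponential rate for the timed
    families (CBN, H-ESBCN) or a conditional probability in (0, 1) for the
    untimed ones (OT, OncoBN).  The virtual root never appears in
    genotypes or data.
    """

    events: EventSet
    parents: Mapping[str, frozenset[str]]
    relation: Mapping[str, str]
    param: Mapping[str, float]
    family: str

    def __init__(self, events, parents, relation, param, family):
        if not isinstance(events, EventSet):
            events = EventSet(events)
        object.__setattr__(self, "events", events)
        object.__setattr__(
            self, "parents", {e: frozenset(ps) for e, ps in dict(parents).items()}
        )
        object.__setattr__(self, "relation", dict(relation))
        object.__setattr__(self, "param", {e: float(v) for e, v in dict(param).items()})
        object.__setattr__(self, "family", family)

    def graph(self) -> nx.DiGraph:
        """The restriction DAG as a networkx digraph (events only, no root)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.events.names)
        for child, ps in self.parents.items():
            g.add_edges_from((p, child) for p in ps)
        return g


@dataclass(frozen=True)
class MHNModel:
    """Mutual hazard network: fully specified by the theta matrix; any
    finite real matrix is a valid model (no structural constraints)."""

    events: EventSet
    theta: np.ndarray

    def __init__(self, events, theta):
        if not isinstance(events, EventSet):
            events = EventSet(events)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "theta", np.asarray(theta, dtype=float))


@dataclass(frozen=True)
class CrossSectionalData:
    """N x n binary matrix of individuals by events — the universal
    input/output data format; column order matches the event set."""

    events: EventSet
    rows: np.ndarray

    def __init__(self, events, rows):
        if not isinstance(events, EventSet):
            events = EventSet(events)
        rows = np.asarray(rows, dtype=np.int8)
        if rows.ndim != 2 or rows.shape[1] != events.n:
            raise ValueError(
                f"data shape {rows.shape} does not match {events.n} events"
            )
        if not np.isin(rows, (0, 1)).all():
            raise ValueError("data entries must be 0 or 1")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "rows", rows)

    @property
    def n_samples(self) -> int:
        return self.rows.shape[0]

    def genotype_ints(self) -> np.ndarray:
        """Each row encoded as its genotype bit mask."""
        weights = (1 << np.arange(self.events.n)).astype(np.int64)
        return self.rows.astype(np.int64) @ weights


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probability mass over genotypes; absent genotypes have mass 0."""

    events: EventSet
    probs: Mapping[int, float] = field(default_factory=dict)

    def __init__(self, events, probs):
        if not isinstance(events, EventSet):
            events = EventSet(events)
        object.__setattr__(self, "events", events)
        object.__setattr__(
            self, "probs", {int(g): float(p) for g, p in dict(probs).items() if p != 0.0}
        )

    def __getitem__(self, g: int) -> float:
        return self.probs.get(int(g), 0.0)

    def total(self) -> float:
        return float(sum(self.probs.values()))

    def to_array(self) -> np.ndarray:
        """Dense vector over all 2^n genotypes, indexed by bit mask."""
        v = np.zeros(1 << self.events.n)
        for g, p in self.probs.items():
            v[g] = p
        return v

    @classmethod
    def from_array(cls, events: EventSet, v: np.ndarray) -> "GenotypeDistribution":
        return cls(events, {g: float(p) for g, p in enumerate(v) if p != 0.0})

    def violations(self) -> list[str]:
        out = []
        if any(p < 0 for p in self.probs.values()):
            out.append("negative probability mass")
        if abs(self.total() - 1.0) > 1e-9:
            out.append(f"probabilities sum to {self.total()}, not 1")
        return out


def is_timed(model: RestrictionDAG | MHNModel) -> bool:
    if isinstance(model, MHNModel):
        return True
    return model.family in TIMED_FAMILIES


def validate_model(model: RestrictionDAG | MHNModel) -> list[str]:
    """Check all type invariants; returns one message per violation
    (empty list = valid).  Violations are reported, never raised."""
    out = list(model.events.violations())
    if isinstance(model, MHNModel):
        th = model.theta
        n = model.events.n
        if th.shape != (n, n):
            out.append(f"theta shape {th.shape} does not match {n} events")
        elif not np.isfinite(th).all():
            out.append("theta contains non-finite entries")
        return out

    if model.family not in DAG_FAMILIES:
        out.append(f"unknown family {model.family!r}")
        return out

    names = set(model.events.names)
    for table, what in ((model.parents, "parents"), (model.relation, "relation"),
                        (model.param, "param")):
        missing = names - set(table)
        extra = set(table) - names
        for e in sorted(missing):
            out.append(f"event {e!r} missing from {what}")
        for e in sorted(extra):
            out.append(f"{what} mentions unknown event {e!r}")

    allowed = _FAMILY_RELATIONS[model.family]
    multi_parent_relations = set()
    for e in model.events.names:
        ps = model.parents.get(e, frozenset())
        unknown = ps - names
        if unknown:
            out.append(f"node {e!r} has unknown parent(s) {sorted(unknown)}")
        rel = model.relation.get(e)
        if rel is not None and rel not in RELATIONS:
            out.append(f"node {e!r} has unknown relation {rel!r}")
        elif rel is not None and rel not in allowed:
            out.append(f"node {e!r}: relation {rel} not allowed in family {model.family}")
        if model.family == OT and len(ps) > 1:
            out.append(f"node {e!r} has {len(ps)} parents; OT allows at most one")
        elif len(ps) > 1 and rel == SINGLE:
            out.append(f"node {e!r} has {len(ps)} parents but relation Single")
        if len(ps) > 1 and rel in (AND, OR, XOR):
            multi_parent_relations.add(rel)
        p = model.param.get(e)
        if p is not None:
            if model.family in TIMED_FAMILIES and not p > 0:
                out.append(f"node {e!r}: rate {p} must be strictly positive")
            if model.family in UNTIMED_FAMILIES and not (0.0 < p < 1.0):
                out.append(f"node {e!r}: probability {p} must lie in (0, 1)")

    if model.family == ONCOBN and len(multi_parent_relations) > 1:
        out.append(
            "OncoBN must be purely conjunctive (AND) or disjunctive (OR); "
            f"found {sorted(multi_parent_relations)}"
        )

    g = model.graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        out.append(f"restriction graph contains a cycle: {cyc}")
    return out


def dependency_satisfied(dag: RestrictionDAG, event: str, genotype: int) -> bool:
    """Can ``event`` be gained in ``genotype``?  Single/AND: all parents
    present; OR: at least one; XOR: exactly one; root children: always."""
    if event not in dag.parents and event not in dag.events.names:
        raise ValueError(
            f"unknown event {event!r}: model/data mismatch "
            f"(known events: {list(dag.events.names)})"
        )
    ps = dag.parents.get(event, frozenset())
    if not ps:
        return True
    present = sum(1 for p in ps if genotype >> dag.events.index(p) & 1)
    rel = dag.relation.get(event, SINGLE)
    if rel in (SINGLE, AND):
        return present == len(ps)
    if rel == OR:
        return present >= 1
    if rel == XOR:
        return present == 1
    raise ValueError(f"unknown relation {rel!r} for event {event!r}")


def reachable_genotypes(model: RestrictionDAG | MHNModel) -> list[int]:
    """Genotypes accessible from WT by gaining events one at a time.

    A gain of ``e`` from genotype ``g`` is allowed iff the dependency of
    ``e`` is satisfied within ``g`` (always, for MHN).  Accessibility is
    path-dependent under XOR — the constraint binds at the moment the
    child is gained, so a second XOR parent may be gained afterwards —
    hence the breadth-first closure is authoritative.  Returned in
    canonical order; always contains WT.
    """
    n = model.events.n
    if isinstance(model, MHNModel):
        return canonical_states(n)
    seen = {0}
    frontier = [0]
    while frontier:
        nxt = []
        for g in frontier:
            for i, e in enumerate(model.events.names):
                if g >> i & 1:
                    continue
                h = g | (1 << i)
                if h not in seen and dependency_satisfied(model, e, g):
                    seen.add(h)
                    nxt.append(h)
        frontier = nxt
    return sorted(seen, key=lambda g: (g.bit_count(), g))
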