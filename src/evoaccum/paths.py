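"""Evolutionary paths: WT-to-absorbing sequences of single-event gains
and their probabilities.

For the timed families the step probabilities come from the jump chain
(competing-risks normalization of the gain rates, observation
excluded), so a path's probability is the probability of that event
order conditional on full progression to absorption.  Untimed models
define no dynamics; by convention the step probability of event ``e``
at genotype ``g`` is ``param(e)`` normalized over all currently
satisfiable absent events.  Either way the probabilities over all
paths sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctmc import rate_matrix, transition_matrix
from .models import (
    EventSet, MHNModel, RestrictionDAG,
    dependency_satisfied, genotype_events, genotype_label, is_timed,
    reachable_genotypes,
)

__all__ = ["EvolutionaryPath", "PathExplosionError", "enumerate_paths", "top_paths"]

#: Default cap on the number of enumerated paths.
DEFAULT_PATH_CAP = 10**6


class PathExplosionError(RuntimeError):
    """Raised when the lattice admits more paths than the cap allows."""


@dataclass(frozen=True)
class EvolutionaryPath:
    """A WT -> absorbing genotype trajectory, one event gained per step."""

    events: EventSet
    genotypes: tuple[int, ...]
    probability: float

    @property
    def gained(self) -> tuple[str, ...]:
        """Event names in the order they were gained."""
        out = []
        for a, b in zip(self.genotypes, self.genotypes[1:]):
            out.extend(genotype_events(b & ~a, self.events))
        return tuple(out)

    def label(self) -> str:
        return " → ".join(genotype_label(g, self.events) for g in self.genotypes)


def _step_probabilities(model) -> tuple[list[int], dict[int, list[tuple[int, float]]]]:
    """Per-genotype successors with step probabilities (sum to 1 unless
    the genotype is absorbing)."""
    if is_timed(model):
        tm = transition_matrix(rate_matrix(model))
        idx = {g: i for i, g in enumerate(tm.states)}
        succ = {}
        for a, g in enumerate(tm.states):
            row = tm.P[a]
            succ[g] = [(tm.states[b], row[b]) for b in np.nonzero(row > 0)[0]]
        return list(tm.states), succ
    # untimed: normalize node probabilities over satisfiable absent events
    states = reachable_genotypes(model)
    succ = {}
    for g in states:
        avail = [
            (i, model.param[e])
            for i, e in enumerate(model.events.names)
            if not g >> i & 1 and dependency_satisfied(model, e, g)
        ]
        tot = sum(w for _, w in avail)
        succ[g] = [(g | (1 << i), w / tot) for i, w in avail]
    return states, succ


def _count_paths(states, succ) -> int:
    counts = {}
    for g in reversed(states):  # reverse canonical order = reverse topological
        nxt = succ[g]
        counts[g] = 1 if not nxt else sum(counts[h] for h, _ in nxt)
    return counts[states[0]]


def enumerate_paths(
    model: RestrictionDAG | MHNModel,
    cap: int = DEFAULT_PATH_CAP,
) -> list[EvolutionaryPath]:
    """All paths from WT to any absorbing genotype, sorted by descending
    probability then lexicographically by the gained-event sequence.

    Absorbing genotypes need not carry every event (XOR restrictions
    leave proper subsets with no available gain).  Raises
    :class:`PathExplosionError` if the count would exceed ``cap``.
    """
    states, succ = _step_probabilities(model)
    total = _count_paths(states, succ)
    if total > cap:
        raise PathExplosionError(
            f"{total} paths exceed the cap of {cap}; raise the cap or "
            "request only the top paths"
        )
    out: list[EvolutionaryPath] = []
    stack: list[tuple[int, ...]] = []

    def walk(g: int, prob: float) -> None:
        stack.append(g)
        nxt = succ[g]
        if not nxt:
            out.append(EvolutionaryPath(model.events, tuple(stack), prob))
        else:
            for h, p in nxt:
                walk(h, prob * p)
        stack.pop()

    walk(states[0], 1.0)
    out.sort(key=lambda pth: (-pth.probability, pth.gained))
    return out


def top_paths(model, k: int, cap: int = DEFAULT_PATH_CAP) -> list[EvolutionaryPath]:
    """First ``k`` paths of :func:`enumerate_paths` (ties broken
    lexicographically)."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    return enumerate_paths(model, cap=cap)[:k]
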