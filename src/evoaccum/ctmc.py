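"""Continuous-time Markov chain engine for the timed families (CBN,
H-ESBCN, MHN).

The process lives on the lattice of reachable genotypes: from genotype
``g`` the only transitions are single-event gains ``g -> g + e``, with
rate ``param(e)`` if the restriction DAG permits the gain (CBN/H-ESBCN)
or the mutual-hazard product ``exp(theta_ee) * prod_{i in g}
exp(theta_ei)`` (MHN).  Cross-sectional observation censors the process
at an independent time ``T ~ Exponential(sampling_rate)``; the exact
distribution of the genotype seen at ``T`` follows from a single forward
pass over the lattice (states in canonical order are topologically
sorted, so the linear system is triangular).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    CBN, HESBCN,
    EventSet, GenotypeDistribution, MHNModel, RestrictionDAG,
    dependency_satisfied, is_timed, reachable_genotypes,
)

__all__ = [
    "ObservationModel", "RateMatrix", "TransitionMatrix",
    "gain_rate", "rate_matrix", "transition_matrix",
    "observation_distribution",
]


@dataclass(frozen=True)
class ObservationModel:
    """Observation (sampling) time: T ~ Exponential(sampling_rate).

    The default rate 1 fixes the time unit; only the ratio of event
    rates to the sampling rate is identifiable from cross-sectional
    data.
    """

    sampling_rate: float = 1.0

    def __post_init__(self):
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")


@dataclass(frozen=True)
class RateMatrix:
    """Transition rate matrix of the evolutionary CTMC (observation not
    included).  ``states[i]`` is the genotype bit mask of row/column i;
    off-diagonals are single-gain rates, diagonal = -(row sum)."""

    events: EventSet
    states: tuple[int, ...]
    Q: np.ndarray

    def index(self, g: int) -> int:
        return self.states.index(g)


@dataclass(frozen=True)
class TransitionMatrix:
    """Jump-chain probabilities: competing-risks normalization of the
    rate matrix, observation excluded.  Absorbing rows are all zero so
    that path enumeration terminates cleanly."""

    events: EventSet
    states: tuple[int, ...]
    P: np.ndarray


def _require_timed(model):
    if not is_timed(model):
        raise ValueError(
            f"family {model.family} is untimed (no rates defined); "
            "use the untimed prediction module instead"
        )


def gain_rate(model: RestrictionDAG | MHNModel, genotype: int, event: str) -> float:
    """Rate of gaining ``event`` from ``genotype``.

    DAG families: the node's exponential rate if its dependency is
    satisfied, else 0.  MHN: baseline hazard times the multiplicative
    effects of the events already present.
    """
    _require_timed(model)
    if isinstance(model, MHNModel):
        j = model.events.index(event)
        if genotype >> j & 1:
            raise ValueError(f"event {event!r} already present in genotype")
        log_rate = model.theta[j, j] + sum(
            model.theta[j, i] for i in range(model.events.n) if genotype >> i & 1
        )
        return float(np.exp(log_rate))
    if model.family not in (CBN, HESBCN):  # pragma: no cover - guarded above
        raise ValueError(f"family {model.family} has no rates")
    if genotype >> model.events.index(event) & 1:
        raise ValueError(f"event {event!r} already present in genotype")
    return model.param[event] if dependency_satisfied(model, event, genotype) else 0.0


def _gain_rates(model, genotype: int) -> list[tuple[int, float]]:
    """(event index, rate) for every absent event with positive rate."""
    out = []
    for i, e in enumerate(model.events.names):
        if genotype >> i & 1:
            continue
        r = gain_rate(model, genotype, e)
        if r > 0.0:
            out.append((i, r))
    return out


def rate_matrix(model: RestrictionDAG | MHNModel) -> RateMatrix:
    """Assemble Q over the reachable genotypes, canonical order.

    Q describes the evolutionary process only; the observation/sampling
    event is handled separately by :func:`observation_distribution`.
    """
    _require_timed(model)
    states = tuple(reachable_genotypes(model))
    idx = {g: i for i, g in enumerate(states)}
    m = len(states)
    Q = np.zeros((m, m))
    for a, g in enumerate(states):
        for i, r in _gain_rates(model, g):
            Q[a, idx[g | (1 << i)]] = r
        Q[a, a] = -Q[a].sum()
    return RateMatrix(model.events, states, Q)


def transition_matrix(rm: RateMatrix) -> TransitionMatrix:
    """Jump-chain matrix: P[g, h] = Q[g, h] / (-Q[g, g]); absorbing rows
    (no exit rate) are left all-zero."""
    P = rm.Q.copy()
    np.fill_diagonal(P, 0.0)
    exit_rate = -np.diag(rm.Q)
    active = exit_rate > 0
    P[active] /= exit_rate[active, None]
    P[~active] = 0.0
    return TransitionMatrix(rm.events, rm.states, P)


def observation_distribution(
    model: RestrictionDAG | MHNModel,
    obs: ObservationModel | None = None,
) -> GenotypeDistribution:
    """Exact distribution of the genotype observed at T ~ Exp(s).

    Forward pass over the lattice: with R(g) the total exit rate of g
    and s the sampling rate, the probability of ever reaching g before
    observation satisfies rho(WT) = 1, rho(h) = sum over predecessors g
    of rho(g) * Q[g, h] / (s + R(g)); the observed mass of g is
    rho(g) * s / (s + R(g)).  Masses sum to 1 over reachable genotypes.
    """
    _require_timed(model)
    s = (obs or ObservationModel()).sampling_rate
    rm = rate_matrix(model)
    m = len(rm.states)
    exit_rate = -np.diag(rm.Q)
    rho = np.zeros(m)
    rho[0] = 1.0
    for a in range(m):  # canonical order is topological on the lattice
        if rho[a] == 0.0:
            continue
        denom = s + exit_rate[a]
        row = rm.Q[a]
        for b in np.nonzero(row > 0)[0]:
            rho[b] += rho[a] * row[b] / denom
    mass = rho * s / (s + exit_rate)
    return GenotypeDistribution(
        model.events, {g: p for g, p in zip(rm.states, mass)}
    )
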