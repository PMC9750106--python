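"""Finite-sample generation and observational (genotyping) error.

Two independent routes produce cross-sectional samples from a timed
model: multinomial draws from the exact observation distribution
(:func:`sample_genotypes`) and a direct Gillespie simulation of the
generative story (:func:`gillespie_sample`).  Agreement between them is
the package's main self-check.

Observational noise is the simplest model consistent with genotyping
error: every cell of the data matrix flips independently with one
probability epsilon.  Its exact effect on a genotype distribution is a
product of per-bit binary channels, applied as a butterfly transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctmc import ObservationModel, rate_matrix
from .models import (
    CrossSectionalData, GenotypeDistribution, MHNModel, RestrictionDAG,
)

__all__ = [
    "NoiseSpec", "sample_genotypes", "apply_noise", "noisy_distribution",
    "gillespie_sample",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Per-cell symmetric flip probability, 0 <= epsilon <= 0.5."""

    epsilon: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must lie in [0, 0.5]")


def _rows_from_ints(gs: np.ndarray, n: int) -> np.ndarray:
    return (gs[:, None] >> np.arange(n) & 1).astype(np.int8)


def sample_genotypes(
    dist: GenotypeDistribution, N: int, seed: int
) -> CrossSectionalData:
    """N i.i.d. genotype draws from ``dist``; reproducible given seed."""
    if N <= 0:
        raise ValueError("N must be positive")
    rng = np.random.default_rng(seed)
    support = np.fromiter(dist.probs.keys(), dtype=np.int64)
    probs = np.fromiter(dist.probs.values(), dtype=float)
    probs = probs / probs.sum()
    gs = rng.choice(support, size=N, p=probs)
    return CrossSectionalData(dist.events, _rows_from_ints(gs, dist.events.n))


def apply_noise(
    data: CrossSectionalData, noise: NoiseSpec, seed: int
) -> CrossSectionalData:
    """Flip each cell independently with probability epsilon."""
    rng = np.random.default_rng(seed)
    flips = rng.random(data.rows.shape) < noise.epsilon
    return CrossSectionalData(data.events, data.rows ^ flips.astype(np.int8))


def noisy_distribution(
    dist: GenotypeDistribution, noise: NoiseSpec
) -> GenotypeDistribution:
    """Exact convolution with the flip kernel:
    P'(h) = sum_g P(g) eps^d(g,h) (1-eps)^(n-d(g,h)), d = Hamming distance.

    Computed one bit at a time (the kernel factorizes over bits), so the
    cost is n * 2^n rather than 4^n.
    """
    eps = noise.epsilon
    if eps == 0.0:
        return dist
    n = dist.events.n
    v = dist.to_array()
    for b in range(n):
        flipped = v.reshape(-1)[np.arange(1 << n) ^ (1 << b)]
        v = (1.0 - eps) * v + eps * flipped
    return GenotypeDistribution.from_array(dist.events, v)


def gillespie_sample(
    model: RestrictionDAG | MHNModel,
    obs: ObservationModel,
    N: int,
    seed: int,
) -> CrossSectionalData:
    """Simulate the generative story per individual: draw the observation
    time T ~ Exp(sampling_rate), then run competing exponential gains
    from WT until the next gain would pass T; record the genotype at T.

    Independent of the analytic lattice computation — this is the oracle
    the observation distribution is checked against.  Vectorized across
    individuals; at most n gain rounds are needed.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    rng = np.random.default_rng(seed)
    rm = rate_matrix(model)  # validates that the family is timed
    m = len(rm.states)
    exit_rate = -np.diag(rm.Q)
    # per-state successor tables for fast categorical draws
    succ_states: list[np.ndarray] = []
    succ_cum: list[np.ndarray] = []
    for a in range(m):
        nz = np.nonzero(rm.Q[a] > 0)[0]
        succ_states.append(nz)
        if nz.size:
            w = rm.Q[a, nz]
            succ_cum.append(np.cumsum(w) / w.sum())
        else:
            succ_cum.append(np.empty(0))

    T = rng.exponential(1.0 / obs.sampling_rate, size=N)
    t = np.zeros(N)
    state = np.zeros(N, dtype=np.int64)  # index into rm.states
    active = exit_rate[state] > 0
    while active.any():
        idx = np.nonzero(active)[0]
        t[idx] += rng.exponential(1.0, size=idx.size) / exit_rate[state[idx]]
        u = rng.random(idx.size)
        jumped = t[idx] <= T[idx]
        active[idx[~jumped]] = False  # observed before the next gain
        jidx, ju = idx[jumped], u[jumped]
        for a in np.unique(state[jidx]):
            sel = state[jidx] == a
            state[jidx[sel]] = succ_states[a][np.searchsorted(succ_cum[a], ju[sel])]
        active &= exit_rate[state] > 0
    gs = np.array([rm.states[a] for a in state], dtype=np.int64)
    return CrossSectionalData(model.events, _rows_from_ints(gs, model.events.n))
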