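"""Fitting the tractable model families from cross-sectional 0/1 data.

* :func:`fit_ot` — oncogenetic tree: structure by maximum-weight
  branching (Edmonds) over pairwise log-odds-style edge weights, edge
  probabilities by conditional frequencies.
* :func:`fit_mhn` — mutual hazard network: exact marginal likelihood on
  the full 2^n genotype lattice with an L1 penalty on the pairwise
  effects, optimized by proximal gradient descent with an analytic
  adjoint gradient.
* :func:`fit_cbn_rates` — exponential-rate MLE for a fixed CBN DAG
  (the sampling rate is fixed at 1 for identifiability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from .ctmc import ObservationModel, observation_distribution
from .models import (
    CBN, OT, SINGLE,
    CrossSectionalData, EventSet, MHNModel, RestrictionDAG,
    is_timed, validate_model,
)
from .simulate import NoiseSpec, noisy_distribution
from .untimed import untimed_distribution

__all__ = [
    "FitResult", "fit_ot", "fit_mhn", "fit_cbn_rates",
    "observed_log_likelihood",
]

_ROOT = "__root__"


@dataclass(frozen=True)
class FitResult:
    model: RestrictionDAG | MHNModel
    log_likelihood: float
    diagnostics: dict[str, Any] = field(default_factory=dict)


def _genotype_counts_vector(data: CrossSectionalData) -> np.ndarray:
    """Counts per genotype bit mask, length 2^n."""
    return np.bincount(data.genotype_ints(), minlength=1 << data.events.n).astype(float)


def observed_log_likelihood(
    model: RestrictionDAG | MHNModel,
    data: CrossSectionalData,
    epsilon: float = 0.0,
) -> float:
    """sum_g N_g log P_model(g), with the model's predicted distribution
    taken from the prediction modules (optionally convolved with a flip
    kernel of probability ``epsilon``).  Returns -inf if any observed
    genotype has zero predicted mass."""
    dist = (
        observation_distribution(model)
        if is_timed(model)
        else untimed_distribution(model)
    )
    if epsilon > 0.0:
        dist = noisy_distribution(dist, NoiseSpec(epsilon))
    counts = _genotype_counts_vector(data)
    ll = 0.0
    for g in np.nonzero(counts)[0]:
        p = dist[int(g)]
        if p <= 0.0:
            return -np.inf
        ll += counts[g] * np.log(p)
    return float(ll)


# ---------------------------------------------------------------------------
# Oncogenetic trees


def _ot_edge_weight(p_i: float, p_j: float, p_ij: float) -> float:
    """Edge weight for the maximum-weight branching: combines how often j
    occurs in the presence of i relative to either event
    (log p_ij - log(p_i + p_j)) with the pairwise association
    (log p_ij - log p_i - log p_j).  Isolated here because it is the one
    genuinely conventional choice in the tree reconstruction."""
    return 2.0 * np.log(p_ij) - np.log(p_i + p_j) - np.log(p_i) - np.log(p_j)


def fit_ot(data: CrossSectionalData) -> FitResult:
    """Fit an oncogenetic tree: pseudocount-regularized marginal and
    pairwise frequencies, Edmonds maximum-weight arborescence rooted at
    the virtual root, conditional edge probabilities."""
    rows = data.rows.astype(float)
    N, n = rows.shape
    col_sums = rows.sum(axis=0)
    bad = [
        data.events.names[j]
        for j in range(n)
        if col_sums[j] == 0 or col_sums[j] == N
    ]
    if bad:
        raise ValueError(
            f"constant column(s) {bad}: events present in none or all samples "
            "carry no tree signal; remove them before fitting"
        )

    # 2x2 tables with pseudocount 0.5 in every cell (total N + 2)
    denom = N + 2.0
    pair = (rows.T @ rows + 0.5) / denom
    marg = (col_sums + 1.0) / denom
    p_root = (N + 1.0) / denom

    G = nx.DiGraph()
    names = data.events.names
    for j, e in enumerate(names):
        G.add_edge(_ROOT, e, weight=_ot_edge_weight(p_root, marg[j], (col_sums[j] + 0.5) / denom))
    for i in range(n):
        for j in range(n):
            if i != j:
                G.add_edge(names[i], names[j],
                           weight=_ot_edge_weight(marg[i], marg[j], pair[i, j]))

    tree = nx.maximum_spanning_arborescence(G, attr="weight")

    parents: dict[str, set[str]] = {e: set() for e in names}
    param: dict[str, float] = {}
    tiny = 1e-9
    for u, v in tree.edges:
        if u == _ROOT:
            cond = marg[names.index(v)]
        else:
            parents[v].add(u)
            cond = pair[names.index(u), names.index(v)] / marg[names.index(u)]
        param[v] = float(np.clip(cond, tiny, 1.0 - tiny))

    model = RestrictionDAG(
        data.events, parents, {e: SINGLE for e in names}, param, OT
    )
    assert not validate_model(model)
    ll = observed_log_likelihood(model, data)
    return FitResult(model, ll, {"n_samples": N})


# ---------------------------------------------------------------------------
# Mutual hazard networks


def _mhn_rates(theta: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """rate[g, a] = exp(theta_aa + sum_{i in g} theta_ai), zeroed where a
    is already in g.  ``bits`` is the (2^n, n) 0/1 state table in plain
    bit-mask order (which is topological: adding a bit increases g)."""
    n = theta.shape[0]
    log_rate = np.diag(theta)[None, :] + bits @ theta.T
    rate = np.exp(log_rate)
    rate[bits.astype(bool)] = 0.0
    return rate


def _mhn_loglik_grad(
    theta: np.ndarray, counts: np.ndarray, s: float = 1.0
) -> tuple[float, np.ndarray]:
    """Log-likelihood sum_g c_g log p_theta(g) and its gradient wrt theta.

    p solves the triangular system (sI - Q)^T p = s e_WT (one forward
    pass over the lattice); the gradient needs one extra backward
    (adjoint) pass for w = (sI - Q)^{-1} (c / p), after which
    d L / d theta_ab = sum_{g: a not in g, b in g or b = a}
    rate_a(g) p_g (w_{g+a} - w_g).
    """
    n = theta.shape[0]
    m = 1 << n
    bits = (np.arange(m)[:, None] >> np.arange(n) & 1).astype(float)
    rate = _mhn_rates(theta, bits)
    R = rate.sum(axis=1)
    denom = s + R
    succ = np.arange(m)[:, None] | (1 << np.arange(n))[None, :]  # g + event a

    rho = np.zeros(m)
    rho[0] = 1.0
    for g in range(m):
        flow = rho[g] / denom[g]
        for a in range(n):
            if rate[g, a] > 0.0:
                rho[succ[g, a]] += flow * rate[g, a]
    p = rho * s / denom

    a_vec = np.where(counts > 0, counts / p, 0.0)
    ll = float(np.sum(counts[counts > 0] * np.log(p[counts > 0])))

    w = np.zeros(m)
    for g in range(m - 1, -1, -1):
        acc = a_vec[g]
        for a in range(n):
            if rate[g, a] > 0.0:
                acc += rate[g, a] * w[succ[g, a]]
        w[g] = acc / denom[g]

    C = rate * p[:, None] * (w[succ] - w[:, None])
    grad = C.T @ bits
    np.fill_diagonal(grad, C.sum(axis=0))
    return ll, grad


def fit_mhn(
    data: CrossSectionalData,
    lambda_penalty: float = 0.0,
    seed: int | None = None,
    max_iter: int = 500,
    rel_tol: float = 1e-8,
) -> FitResult:
    """Penalized maximum likelihood for the theta matrix.

    Maximizes ``sum_g N_g log p_theta(g) - lambda * sum_{i != j}
    |theta_ij|`` by proximal gradient (soft-thresholding the
    off-diagonals) with backtracking line search, so the penalized
    objective is non-decreasing over accepted iterates.  Deterministic
    given the data (the initialization is closed-form; ``seed`` is
    accepted for interface uniformity).  Non-convergence is flagged in
    the diagnostics, never raised.
    """
    n = data.events.n
    if n > 12:
        raise ValueError("theta fitting supports at most 12 events")
    counts = _genotype_counts_vector(data)
    N = counts.sum()

    # closed-form diagonal start: p(event) = r / (1 + r) per event alone
    f = np.clip(data.rows.mean(axis=0), 1.0 / (2 * N), 1.0 - 1.0 / (2 * N))
    theta = np.diag(np.log(f / (1.0 - f)))

    lam = float(lambda_penalty)
    off_mask = ~np.eye(n, dtype=bool)

    def objective(ll: float, th: np.ndarray) -> float:
        return ll - lam * np.abs(th[off_mask]).sum()

    ll, grad = _mhn_loglik_grad(theta, counts)
    F = objective(ll, theta)
    history = [F]
    t = 1.0 / max(N, 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        while True:
            step = theta + t * grad  # ascent on the smooth part
            new = step.copy()
            new[off_mask] = np.sign(step[off_mask]) * np.maximum(
                np.abs(step[off_mask]) - t * lam, 0.0
            )
            ll_new, grad_new = _mhn_loglik_grad(new, counts)
            d = new - theta
            # backtracking: require the quadratic upper-bound condition
            if ll_new >= ll + np.sum(grad * d) - np.sum(d * d) / (2.0 * t) - 1e-12:
                break
            t *= 0.5
            if t < 1e-15:
                break
        F_new = objective(ll_new, new)
        if F_new < F - 1e-12:  # numerically stalled; keep the best iterate
            break
        theta, ll, grad = new, ll_new, grad_new
        history.append(F_new)
        if abs(F_new - F) <= rel_tol * max(1.0, abs(F)):
            F = F_new
            converged = True
            break
        F = F_new
        t *= 1.5  # optimistic step growth; backtracking will shrink it again

    model = MHNModel(data.events, theta)
    return FitResult(
        model,
        float(ll),
        {
            "iterations": it,
            "converged": converged,
            "penalty": lam,
            "objective": float(F),
            "objective_history": [float(x) for x in history],
        },
    )


# ---------------------------------------------------------------------------
# CBN rates under a fixed DAG


def fit_cbn_rates(
    data: CrossSectionalData,
    dag: RestrictionDAG,
    epsilon: float = 0.001,
) -> FitResult:
    """MLE of the exponential rates of a fixed CBN DAG from observed
    genotype frequencies, optimized over log-rates; the sampling rate is
    fixed at 1 (only rate ratios are identifiable).

    Observations incompatible with the DAG are handled through a flip
    kernel with small probability ``epsilon`` (default 0.001) so the
    likelihood never hits log 0; pass ``epsilon=0`` for the pure model
    likelihood when all observations are DAG-compatible.
    """
    if dag.family != CBN:
        raise ValueError(f"expected a CBN model, got family {dag.family}")
    if tuple(dag.events.names) != tuple(data.events.names):
        raise ValueError(
            f"model events {list(dag.events.names)} do not match data events "
            f"{list(data.events.names)}"
        )
    counts = _genotype_counts_vector(data)
    N = counts.sum()
    names = dag.events.names
    noise = NoiseSpec(epsilon) if epsilon > 0 else None

    def build(log_rates: np.ndarray) -> RestrictionDAG:
        return RestrictionDAG(
            dag.events, dag.parents, dag.relation,
            dict(zip(names, np.exp(log_rates))), CBN,
        )

    def neg_ll(log_rates: np.ndarray) -> float:
        dist = observation_distribution(build(log_rates), ObservationModel(1.0))
        if noise is not None:
            dist = noisy_distribution(dist, noise)
        ll = 0.0
        for g in np.nonzero(counts)[0]:
            ll += counts[g] * np.log(max(dist[int(g)], 1e-300))
        return -ll / N

    f = np.clip(data.rows.mean(axis=0), 1.0 / (2 * N), 1.0 - 1.0 / (2 * N))
    x0 = np.log(f / (1.0 - f))
    res = minimize(neg_ll, x0, method="L-BFGS-B",
                   options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500})
    model = build(res.x)
    ll = observed_log_likelihood(model, data, epsilon=epsilon)
    return FitResult(
        model, ll,
        {
            "iterations": int(res.nit),
            "converged": bool(res.success),
            "epsilon": epsilon,
        },
    )
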