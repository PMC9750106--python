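"""Exact genotype distributions for the untimed families (OT, OncoBN).

Both are Bayesian networks over the restriction DAG: each node carries
the conditional probability that the event is present by observation
time given that its dependency is met.  An event whose dependency is
not met cannot be present, so genotypes violating a restriction get
probability zero.  OT is the tree-restricted special case of
conjunctive OncoBN and shares the same code path.
"""

from __future__ import annotations

from .models import (
    UNTIMED_FAMILIES,
    GenotypeDistribution, RestrictionDAG,
    dependency_satisfied,
)

__all__ = ["untimed_genotype_probability", "untimed_distribution"]


def _require_untimed(dag: RestrictionDAG) -> None:
    if not isinstance(dag, RestrictionDAG) or dag.family not in UNTIMED_FAMILIES:
        fam = getattr(dag, "family", type(dag).__name__)
        raise ValueError(
            f"family {fam} is timed; use the CTMC observation distribution instead"
        )


def untimed_genotype_probability(dag: RestrictionDAG, genotype: int) -> float:
    """Bayes-net factorization: product over events of

    * dependency satisfied:  param(e)      if e present,
                             1 - param(e)  if absent;
    * dependency violated:   0 if e present (impossible), 1 if absent.
    """
    _require_untimed(dag)
    p = 1.0
    for i, e in enumerate(dag.events.names):
        present = bool(genotype >> i & 1)
        # the event's own bit never counts toward its parents
        if dependency_satisfied(dag, e, genotype & ~(1 << i)):
            p *= dag.param[e] if present else 1.0 - dag.param[e]
        elif present:
            return 0.0
    return p


def untimed_distribution(dag: RestrictionDAG) -> GenotypeDistribution:
    """Probability of every genotype (all 2^n); sums to 1 exactly since
    the factorization is a proper Bayesian network."""
    _require_untimed(dag)
    n = dag.events.n
    return GenotypeDistribution(
        dag.events,
        {g: untimed_genotype_probability(dag, g) for g in range(1 << n)},
    )
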