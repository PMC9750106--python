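import numpy as np
import pytest

from evoaccum import (
    AND, CBN, OT, SINGLE,
    EventSet, MHNModel, RestrictionDAG,
)


@pytest.fixture
def two_unit_rates():
    """Two independent events, both rate 1: observed masses (1/3, 1/6, 1/6, 1/3)."""
    return RestrictionDAG(
        ["A", "B"], {"A": set(), "B": set()},
        {"A": SINGLE, "B": SINGLE}, {"A": 1.0, "B": 1.0}, CBN,
    )


@pytest.fixture
def two_rates_2_1():
    """Two independent events, rates 2 and 1: masses (1/4, 1/4, 1/12, 5/12)."""
    return RestrictionDAG(
        ["A", "B"], {"A": set(), "B": set()},
        {"A": SINGLE, "B": SINGLE}, {"A": 2.0, "B": 1.0}, CBN,
    )


@pytest.fixture
def and_example():
    """CBN: root->A, root->B, {A,B}->C with AND, all rates 1."""
    return RestrictionDAG(
        ["A", "B", "C"],
        {"A": set(), "B": set(), "C": {"A", "B"}},
        {"A": SINGLE, "B": SINGLE, "C": AND},
        {"A": 1.0, "B": 1.0, "C": 1.0},
        CBN,
    )


@pytest.fixture
def ot_example():
    """OT: root->A (0.8), A->B (0.5)."""
    return RestrictionDAG(
        ["A", "B"], {"A": set(), "B": {"A"}},
        {"A": SINGLE, "B": SINGLE}, {"A": 0.8, "B": 0.5}, OT,
    )


@pytest.fixture
def mhn_flat3():
    """3-event MHN with theta = 0: all gain rates are 1."""
    return MHNModel(EventSet(["A", "B", "C"]), np.zeros((3, 3)))


def genotype(events, *names):
    """Bit mask for the genotype containing the named events."""
    g = 0
    for nm in names:
        g |= 1 << events.names.index(nm)
    return g
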