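"""CTMC engine: gain rates, rate/transition matrices, observation distribution."""

import numpy as np
import pytest

from evoaccum import (
    CBN, SINGLE,
    EventSet, MHNModel, ObservationModel, RestrictionDAG,
    gain_rate, observation_distribution, rate_matrix, transition_matrix,
)
from evoaccum.randmodels import random_dag_model, random_mhn

from conftest import genotype


def linear_system_distribution(model, s=1.0):
    """Independent oracle: the observed-genotype distribution solves
    p^T (sI - Q) = s e_WT^T over the reachable states."""
    rm = rate_matrix(model)
    m = len(rm.states)
    M = s * np.eye(m) - rm.Q
    rhs = np.zeros(m)
    rhs[0] = s
    p = np.linalg.solve(M.T, rhs)
    return dict(zip(rm.states, p))


class TestGainRate:
    def test_mhn_multiplicative_effect(self):
        m = MHNModel(EventSet(["e1", "e2"]),
                     [[np.log(2), 0.0], [np.log(3), 0.0]])
        # event 2 from {e1}: exp(theta_22) * exp(theta_21) = 1 * 3
        assert gain_rate(m, 0b01, "e2") == pytest.approx(3.0)
        assert gain_rate(m, 0b00, "e1") == pytest.approx(2.0)

    def test_mhn_zero_theta_gives_unit_rates(self, mhn_flat3):
        for e in "ABC":
            assert gain_rate(mhn_flat3, 0, e) == pytest.approx(1.0)

    def test_cbn_and_blocks_until_all_parents(self, and_example):
        ev = and_example.events
        assert gain_rate(and_example, genotype(ev, "A"), "C") == 0.0
        assert gain_rate(and_example, genotype(ev, "A", "B"), "C") == 1.0

    def test_untimed_family_has_no_rates(self, ot_example):
        with pytest.raises(ValueError, match="untimed"):
            gain_rate(ot_example, 0, "A")

    def test_present_event_rejected(self, mhn_flat3):
        with pytest.raises(ValueError, match="already present"):
            gain_rate(mhn_flat3, 0b001, "A")


class TestRateMatrix:
    def test_two_independent_rates(self, two_rates_2_1):
        rm = rate_matrix(two_rates_2_1)
        ev = two_rates_2_1.events
        i = {g: k for k, g in enumerate(rm.states)}
        assert rm.Q[i[0], i[genotype(ev, "A")]] == 2.0
        assert rm.Q[i[0], i[genotype(ev, "B")]] == 1.0
        assert rm.Q[i[0], i[0]] == -3.0

    def test_rows_sum_to_zero_and_single_gain_sparsity(self):
        m = random_mhn(4, seed=3, sparsity=0.3)
        rm = rate_matrix(m)
        assert np.abs(rm.Q.sum(axis=1)).max() < 1e-12
        for a, g in enumerate(rm.states):
            nz = [b for b in range(len(rm.states)) if b != a and rm.Q[a, b] != 0]
            assert len(nz) <= m.events.n
            for b in nz:
                diff = rm.states[b] & ~g
                assert rm.states[b] > g and diff.bit_count() == 1

    def test_flat_mhn_unit_rates_from_wt(self, mhn_flat3):
        rm = rate_matrix(mhn_flat3)
        assert rm.Q[0, 0] == pytest.approx(-3.0)
        assert sorted(rm.Q[0, 1:4]) == [1.0, 1.0, 1.0]


class TestTransitionMatrix:
    def test_competing_exponentials_normalization(self, two_rates_2_1):
        tm = transition_matrix(rate_matrix(two_rates_2_1))
        ev = two_rates_2_1.events
        i = {g: k for k, g in enumerate(tm.states)}
        assert tm.P[i[0], i[genotype(ev, "A")]] == pytest.approx(2 / 3)
        assert tm.P[i[0], i[genotype(ev, "B")]] == pytest.approx(1 / 3)

    def test_single_available_event_probability_one(self, and_example):
        tm = transition_matrix(rate_matrix(and_example))
        ev = and_example.events
        i = {g: k for k, g in enumerate(tm.states)}
        row = tm.P[i[genotype(ev, "A", "B")]]
        assert row.sum() == pytest.approx(1.0)
        assert row[i[genotype(ev, "A", "B", "C")]] == pytest.approx(1.0)

    def test_absorbing_row_is_zero(self, and_example):
        tm = transition_matrix(rate_matrix(and_example))
        full = genotype(and_example.events, "A", "B", "C")
        assert (tm.P[tm.states.index(full)] == 0).all()


class TestObservationDistribution:
    def test_two_unit_rates_closed_form(self, two_unit_rates):
        d = observation_distribution(two_unit_rates)
        assert d[0b00] == pytest.approx(1 / 3, abs=1e-12)
        assert d[0b01] == pytest.approx(1 / 6, abs=1e-12)
        assert d[0b10] == pytest.approx(1 / 6, abs=1e-12)
        assert d[0b11] == pytest.approx(1 / 3, abs=1e-12)

    def test_rates_2_1_closed_form(self, two_rates_2_1):
        d = observation_distribution(two_rates_2_1)
        for g, want in [(0b00, 1 / 4), (0b01, 1 / 4), (0b10, 1 / 12),
                        (0b11, 5 / 12)]:
            assert d[g] == pytest.approx(want, abs=1e-12)

    def test_and_example_lattice_dp(self, and_example):
        d = observation_distribution(and_example)
        ev = and_example.events
        want = {0: 1 / 3, genotype(ev, "A"): 1 / 6, genotype(ev, "B"): 1 / 6,
                genotype(ev, "A", "B"): 1 / 6,
                genotype(ev, "A", "B", "C"): 1 / 6}
        for g, p in want.items():
            assert d[g] == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_normalized_and_matches_linear_system(self, seed):
        family = [CBN, "HESBCN", "MHN"][seed % 3]
        if family == "MHN":
            m = random_mhn(2 + seed % 5, seed)
        else:
            m = random_dag_model(family, 2 + seed % 5, seed, density=0.4)
        d = observation_distribution(m)
        assert d.total() == pytest.approx(1.0, abs=1e-9)
        oracle = linear_system_distribution(m)
        for g, p in oracle.items():
            assert d[g] == pytest.approx(p, abs=1e-9)

    def test_diagonal_mhn_equals_edgeless_cbn(self):
        diag = np.array([0.7, -0.4, 0.1])
        mhn = MHNModel(EventSet(["A", "B", "C"]), np.diag(diag))
        cbn = RestrictionDAG(
            ["A", "B", "C"], {e: set() for e in "ABC"},
            {e: SINGLE for e in "ABC"},
            {e: float(np.exp(v)) for e, v in zip("ABC", diag)}, CBN,
        )
        dm, dc = observation_distribution(mhn), observation_distribution(cbn)
        for g in range(8):
            assert dm[g] == pytest.approx(dc[g], abs=1e-9)

    @pytest.mark.parametrize("c", [0.1, 3.7])
    def test_time_unit_invariance(self, and_example, c):
        """Scaling every rate and the sampling rate by c leaves the
        observed distribution unchanged."""
        scaled = RestrictionDAG(
            and_example.events, and_example.parents, and_example.relation,
            {e: v * c for e, v in and_example.param.items()}, CBN,
        )
        d0 = observation_distribution(and_example)
        d1 = observation_distribution(scaled, ObservationModel(c))
        for g in d0.probs:
            assert d1[g] == pytest.approx(d0[g], abs=1e-12)

    def test_untimed_family_rejected(self, ot_example):
        with pytest.raises(ValueError, match="untimed"):
            observation_distribution(ot_example)
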