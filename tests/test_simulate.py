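"""Finite samples, observational noise and the Gillespie oracle."""

import numpy as np
import pytest
from scipy.stats import chisquare

from evoaccum import (
    CBN, SINGLE,
    CrossSectionalData, EventSet, GenotypeDistribution, NoiseSpec,
    ObservationModel, RestrictionDAG,
    apply_noise, gillespie_sample, noisy_distribution, observation_distribution,
    sample_genotypes,
)


def empirical(data: CrossSectionalData) -> np.ndarray:
    return np.bincount(data.genotype_ints(), minlength=1 << data.events.n) / \
        data.n_samples


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * np.abs(p - q).sum()


class TestSampleGenotypes:
    def test_point_mass_gives_identical_rows(self):
        d = GenotypeDistribution(EventSet(["A", "B"]), {0b11: 1.0})
        data = sample_genotypes(d, 50, seed=1)
        assert (data.rows == 1).all()

    def test_single_row_shape(self, two_unit_rates):
        d = observation_distribution(two_unit_rates)
        assert sample_genotypes(d, 1, seed=0).rows.shape == (1, 2)

    def test_nonpositive_n_rejected(self, two_unit_rates):
        d = observation_distribution(two_unit_rates)
        with pytest.raises(ValueError):
            sample_genotypes(d, 0, seed=0)

    def test_multinomial_frequencies_match_closed_form(self, two_unit_rates):
        d = observation_distribution(two_unit_rates)
        N = 100_000
        freq = empirical(sample_genotypes(d, N, seed=12345))
        for g, want in [(0b00, 1 / 3), (0b01, 1 / 6), (0b10, 1 / 6),
                        (0b11, 1 / 3)]:
            se = np.sqrt(want * (1 - want) / N)
            assert abs(freq[g] - want) < 3 * se

    def test_same_seed_reproduces(self, two_unit_rates):
        d = observation_distribution(two_unit_rates)
        a = sample_genotypes(d, 100, seed=9)
        b = sample_genotypes(d, 100, seed=9)
        assert (a.rows == b.rows).all()


class TestApplyNoise:
    def test_zero_epsilon_is_identity(self):
        rng = np.random.default_rng(0)
        data = CrossSectionalData(["A", "B"], rng.integers(0, 2, (50, 2)))
        out = apply_noise(data, NoiseSpec(0.0), seed=3)
        assert (out.rows == data.rows).all()

    def test_half_epsilon_forgets_the_input(self):
        data = CrossSectionalData(["A", "B"], np.ones((20_000, 2), dtype=int))
        out = apply_noise(data, NoiseSpec(0.5), seed=4)
        se = np.sqrt(0.25 / 20_000)
        assert np.abs(out.rows.mean(axis=0) - 0.5).max() < 3 * se

    def test_flip_fraction_matches_epsilon(self):
        data = CrossSectionalData(list("ABCD"), np.zeros((10_000, 4), dtype=int))
        out = apply_noise(data, NoiseSpec(0.1), seed=5)
        frac = out.rows.mean()
        se = np.sqrt(0.1 * 0.9 / (10_000 * 4))
        assert abs(frac - 0.1) < 3 * se

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(0.6)


class TestNoisyDistribution:
    def test_zero_epsilon_unchanged(self, two_unit_rates):
        d = observation_distribution(two_unit_rates)
        assert noisy_distribution(d, NoiseSpec(0.0)).probs == d.probs

    def test_half_epsilon_uniform_for_any_input(self):
        d = GenotypeDistribution(EventSet(list("ABC")), {0b101: 1.0})
        out = noisy_distribution(d, NoiseSpec(0.5))
        for g in range(8):
            assert out[g] == pytest.approx(1 / 8, abs=1e-12)

    def test_single_cell_flip(self):
        d = GenotypeDistribution(EventSet(["e"]), {0: 1.0})
        out = noisy_distribution(d, NoiseSpec(0.1))
        assert out[0] == pytest.approx(0.9)
        assert out[1] == pytest.approx(0.1)

    def test_matches_brute_force_flip_kernel(self):
        """Oracle: direct double sum over genotype pairs with the
        eps^d (1-eps)^(n-d) Hamming kernel."""
        rng = np.random.default_rng(7)
        n, eps = 4, 0.17
        v = rng.dirichlet(np.ones(1 << n))
        d = GenotypeDistribution.from_array(EventSet(list("ABCD")), v)
        out = noisy_distribution(d, NoiseSpec(eps))
        for h in range(1 << n):
            want = sum(
                v[g] * eps ** (g ^ h).bit_count()
                * (1 - eps) ** (n - (g ^ h).bit_count())
                for g in range(1 << n)
            )
            assert out[h] == pytest.approx(want, abs=1e-12)


class TestGillespie:
    def test_all_zero_rates_stay_wild_type(self):
        m = RestrictionDAG(
            ["A", "B"], {"A": set(), "B": set()},
            {"A": SINGLE, "B": SINGLE}, {"A": 0.0, "B": 0.0}, CBN,
        )
        data = gillespie_sample(m, ObservationModel(1.0), 200, seed=0)
        assert (data.rows == 0).all()

    def test_matches_analytic_distribution(self, two_unit_rates):
        d = observation_distribution(two_unit_rates).to_array()
        data = gillespie_sample(two_unit_rates, ObservationModel(1.0),
                                100_000, seed=21)
        assert tv_distance(empirical(data), d) < 0.02

    def test_and_dependency_never_violated(self, and_example):
        data = gillespie_sample(and_example, ObservationModel(1.0),
                                20_000, seed=8)
        a, b, c = data.rows.T
        assert not ((c == 1) & ((a == 0) | (b == 0))).any()

    def test_indistinguishable_from_multinomial_sampling(self, and_example):
        """Chi-square goodness of fit between the two sampling routes."""
        N = 100_000
        d = observation_distribution(and_example)
        route_a = empirical(gillespie_sample(and_example, ObservationModel(1.0),
                                             N, seed=31)) * N
        expected = d.to_array() * N
        keep = expected > 0
        _, pval = chisquare(route_a[keep], expected[keep])
        assert pval > 0.001

    def test_noise_commutes_with_sampling(self, two_unit_rates):
        """apply_noise on sampled data is distributed as sampling from
        noisy_distribution."""
        N, eps = 100_000, 0.12
        d = observation_distribution(two_unit_rates)
        noisy = noisy_distribution(d, NoiseSpec(eps))
        observed = empirical(
            apply_noise(sample_genotypes(d, N, seed=41), NoiseSpec(eps), seed=42)
        ) * N
        expected = noisy.to_array() * N
        _, pval = chisquare(observed, expected)
        assert pval > 0.001

    def test_same_seed_reproduces(self, and_example):
        a = gillespie_sample(and_example, ObservationModel(1.0), 500, seed=6)
        b = gillespie_sample(and_example, ObservationModel(1.0), 500, seed=6)
        assert (a.rows == b.rows).all()
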