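"""Galton-Watson amplification model: exact laws, convergence, density table."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from umicorrect import branching

from conftest import two_sample_ks


def enumerate_family_distribution(e: float, cycles: int) -> dict[int, float]:
    """Exact family-size distribution by exhaustive enumeration.

    Independent oracle: propagates the full probability vector through the
    binomial-increment recursion cycle by cycle.
    """
    dist = {1: 1.0}
    for _ in range(cycles):
        nxt: dict[int, float] = {}
        for size, p in dist.items():
            for delta in range(size + 1):
                nxt[size + delta] = nxt.get(size + delta, 0.0) + p * binom.pmf(
                    delta, size, e
                )
        dist = nxt
    return dist


class TestFamilySimulation:
    def test_deterministic_limits(self):
        rng = np.random.default_rng(0)
        assert branching.simulate_family(1.0, 3, rng) == 8
        assert branching.simulate_family(0.0, 10, rng) == 1

    def test_two_cycle_distribution_matches_enumeration(self):
        exact = enumerate_family_distribution(0.5, 2)
        assert exact == pytest.approx(
            {1: 0.25, 2: 0.375, 3: 0.25, 4: 0.125}
        )
        rng = np.random.default_rng(42)
        draws = branching.simulate_families(0.5, 2, 200_000, rng)
        for size, p in exact.items():
            freq = np.mean(draws == size)
            se = math.sqrt(p * (1 - p) / draws.size)
            assert abs(freq - p) < 4 * se

    @pytest.mark.parametrize(
        "e,cycles,expected",
        [
            (1.0, 3, (8.0, 0.0)),
            (0.5, 2, (2.25, 0.9375)),
            (0.9, 1, (1.9, 0.09)),
        ],
    )
    def test_family_moments_examples(self, e, cycles, expected):
        assert branching.family_moments(e, cycles) == pytest.approx(expected)

    @pytest.mark.parametrize("e", [0.3, 0.7])
    def test_family_moments_match_enumeration(self, e):
        dist = enumerate_family_distribution(e, 4)
        sizes = np.array(list(dist))
        probs = np.array(list(dist.values()))
        mean = float(sizes @ probs)
        var = float((sizes**2) @ probs - mean**2)
        assert branching.family_moments(e, 4) == pytest.approx(
            (mean, var), rel=1e-10
        )

    def test_rejects_negative_cycles_and_bad_efficiency(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            branching.simulate_family(0.5, -1, rng)
        with pytest.raises(ValueError):
            branching.family_moments(1.5, 3)


class TestNormalizedFamilySize:
    @pytest.mark.parametrize(
        "e,expected", [(0.5, 1 / 3), (1.0, 0.0), (0.1, 9 / 11)]
    )
    def test_variance_formula(self, e, expected):
        assert branching.variance_F(e) == pytest.approx(expected)

    def test_zero_efficiency_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            branching.variance_F(0.0)
        with pytest.raises(ValueError):
            branching.simulate_normalized_family(0.0, rng)

    def test_degenerate_at_full_efficiency(self):
        rng = np.random.default_rng(1)
        f = branching.simulate_normalized_family(1.0, rng, size=100)
        assert np.all(f == 1.0)

    def test_mean_is_one(self):
        rng = np.random.default_rng(2)
        f = branching.simulate_normalized_family(0.5, rng, size=100_000)
        se = f.std() / math.sqrt(f.size)
        assert abs(f.mean() - 1.0) < 3 * se

    def test_rescaled_variance_grows_to_limit(self):
        # V[M_i / (1+E)^i] = ((1-E)/(1+E)) (1 - (1+E)^(-i)), increasing in i
        e, n = 0.5, 200_000
        limit = branching.variance_F(e)
        prev = -1.0
        for i in (5, 20):
            rng = np.random.default_rng(100 + i)
            m = branching.simulate_families(e, i, n, rng)
            f = m / (1 + e) ** i
            expected = limit * (1 - (1 + e) ** (-i))
            sample_var = f.var(ddof=1)
            c = f - f.mean()
            se = math.sqrt(max((c**4).mean() - sample_var**2, 0) / n)
            assert abs(sample_var - expected) < 4 * se
            assert expected > prev
            prev = expected
        assert prev < limit


class TestDensityTable:
    def test_column_invariants(self, density_table):
        tab = density_table
        w, x = tab.widths, tab.x_mid
        assert np.all(tab.densities >= 0)
        for i, e in enumerate(tab.e_grid):
            col = tab.densities[i]
            integral = float(col @ w)
            mean = float((col * w) @ x)
            var = float((col * w) @ (x**2)) - mean**2
            assert 0.99 <= integral <= 1.01
            assert 0.97 <= mean <= 1.03
            if e >= 0.05:
                target = branching.variance_F(e)
                assert var == pytest.approx(target, rel=0.05, abs=1e-9)

    def test_fluctuations_decrease_with_efficiency(self, density_table):
        tab = density_table
        w, x = tab.widths, tab.x_mid
        variances = [
            float((col * w) @ (x**2)) - float((col * w) @ x) ** 2
            for col in tab.densities
        ]
        assert np.all(np.diff(variances) < 0)

    def test_full_efficiency_column_is_unit_spike(self, density_table):
        tab = density_table
        col = tab.column(1.0)
        mass = col * tab.widths
        spike = np.argmax(mass)
        assert tab.x_edges[spike] < 1.0 < tab.x_edges[spike + 1]
        assert mass[spike] == pytest.approx(1.0)

    def test_interpolation_node_exact_and_zero_beyond_support(self, density_table):
        tab = density_table
        e = float(tab.e_grid[24])
        j = 150
        assert tab.density(tab.x_mid[j], e) == tab.densities[24, j]
        assert tab.density(60.0, e) == 0.0
        with pytest.raises(ValueError):
            tab.density(1.0, 0.005)  # below the supported efficiency range
        with pytest.raises(ValueError):
            tab.density(-0.5, e)

    @pytest.mark.parametrize("e", [0.57, 0.87])
    def test_interpolated_cdf_matches_fresh_draws(self, density_table, e):
        # Monte-Carlo oracle at an off-grid efficiency: KS distance between
        # the interpolated CDF and the empirical CDF of fresh draws < 0.01
        assert e not in density_table.e_grid
        rng = np.random.default_rng(int(e * 1000))
        f = np.sort(branching.simulate_normalized_family(e, rng, size=100_000))
        ecdf_hi = np.arange(1, f.size + 1) / f.size
        model = density_table.cdf(f, e)
        ks = max(
            np.abs(model - ecdf_hi).max(),
            np.abs(model - (ecdf_hi - 1 / f.size)).max(),
        )
        assert ks < 0.01

    def test_inverse_cdf_sampling_matches_direct_process(self, density_table):
        e, n = 0.45, 150_000
        rng = np.random.default_rng(77)
        sampled = density_table.sample(e, n, rng)
        direct = branching.simulate_normalized_family(e, rng, size=n)
        assert two_sample_ks(sampled, direct) < 0.01

    def test_sampling_determinism(self, density_table):
        a = density_table.sample(0.6, 1000, np.random.default_rng(5))
        b = density_table.sample(0.6, 1000, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_roundtrip_through_file(self, density_table, tmp_path):
        path = tmp_path / "density.tsv"
        density_table.save(path)
        back = branching.FamilySizeDensity.load(path)
        np.testing.assert_array_equal(back.e_grid, density_table.e_grid)
        np.testing.assert_array_equal(back.x_edges, density_table.x_edges)
        np.testing.assert_array_equal(back.densities, density_table.densities)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            branching.build_density_table(replicates=5000, seed=0)

    def test_build_determinism(self):
        a = branching.build_density_table(
            e_grid=[0.3, 0.6, 0.9], replicates=10_000, seed=11
        )
        b = branching.build_density_table(
            e_grid=[0.3, 0.6, 0.9], replicates=10_000, seed=11
        )
        np.testing.assert_array_equal(a.densities, b.densities)
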