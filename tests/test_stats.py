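import numpy as np
import pytest
from scipy.stats import binomtest

from medipdmr import (SimulationConfig, bh_fdr, equalize_counts,
                      estimate_dispersion, exact_test, generate_genome,
                      simulate_dataset, tmm_factors)
from medipdmr import test_windows as window_tests
from medipdmr.model import WindowCounts
from medipdmr.stats import _conditional_pvalue

from conftest import nb_exact_pvalue_oracle


def make_counts(matrix, samples=None):
    matrix = np.asarray(matrix, dtype=np.int64)
    n = matrix.shape[0]
    samples = samples or [f"s{j+1}" for j in range(matrix.shape[1])]
    return WindowCounts(
        window_size=1000,
        chroms=np.full(n, "c1", dtype=object),
        starts=np.arange(n, dtype=np.int64) * 1000,
        ends=(np.arange(n, dtype=np.int64) + 1) * 1000,
        samples=samples, counts=matrix,
        library_sizes=matrix.sum(axis=0).astype(float))


class TestTmm:
    def test_identical_columns_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, size=500)
        wc = make_counts(np.stack([col, col, col], axis=1))
        assert np.allclose(tmm_factors(wc).factors, 1.0, atol=1e-12)

    def test_pure_scaling_unit_factors(self):
        """Doubling a column changes the library size, not the proportions."""
        rng = np.random.default_rng(2)
        col = rng.poisson(50, size=500) + 1
        wc = make_counts(np.stack([col, 2 * col], axis=1))
        assert np.allclose(tmm_factors(wc).factors, 1.0, atol=1e-12)

    def test_geometric_mean_always_one(self):
        rng = np.random.default_rng(3)
        mat = rng.negative_binomial(5, 0.1, size=(400, 6))
        factors = tmm_factors(make_counts(mat)).factors
        assert abs(np.exp(np.mean(np.log(factors))) - 1.0) < 1e-12

    def test_all_zero_sample_rejected(self):
        mat = np.array([[5, 0], [3, 0]])
        with pytest.raises(ValueError, match="s2"):
            tmm_factors(make_counts(mat))

    def test_compensates_composition_bias(self):
        """A sample with a few huge windows gets a factor below 1."""
        rng = np.random.default_rng(4)
        base = rng.poisson(100, size=(1000, 2)).astype(np.int64)
        skew = base.copy()
        skew[:20, 1] *= 50
        factors = tmm_factors(make_counts(skew)).factors
        assert factors[1] < factors[0]


class TestExactTest:
    def test_balanced_split_p_one(self):
        p, lfc = exact_test([5, 7, 6], [6, 5, 7], phi=0.1)
        assert p == pytest.approx(1.0)
        assert lfc == pytest.approx(0.0)

    def test_poisson_single_sample_binomial(self):
        # A=0, B=10, phi=0 -> Binomial(10, 1/2): only s=0 and s=10 qualify
        p, lfc = exact_test([0], [10], phi=0.0)
        assert p == pytest.approx(2 / 1024, rel=1e-10)
        assert lfc < 0

    def test_poisson_limit_matches_scipy_binomtest(self):
        for a, b in [(3, 12), (0, 7), (9, 2), (10, 10)]:
            p, _ = exact_test([a], [b], phi=0.0)
            ref = binomtest(a, a + b, 0.5).pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_zero_total_convention(self):
        assert exact_test([0, 0], [0, 0], phi=0.2) == (1.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_test([-1], [3], phi=0.1)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ya = rng.poisson(20, size=4)
            yb = rng.poisson(35, size=4)
            p1, l1 = exact_test(ya, yb, phi=0.15)
            p2, l2 = exact_test(yb, ya, phi=0.15)
            assert p1 == pytest.approx(p2, rel=1e-12)
            assert l1 == pytest.approx(-l2, rel=1e-12)

    def test_matches_enumeration_oracle(self):
        """Random (A,B,phi,nA,nB) instances agree with brute force to 1e-10."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n_a, n_b = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            a, b = int(rng.integers(0, 100)), int(rng.integers(0, 100))
            phi = float(rng.choice([0.0, 0.01, 0.1, 0.5, 2.0]))
            got = _conditional_pvalue(a, b, n_a, n_b, phi)
            want = nb_exact_pvalue_oracle(a, b, n_a, n_b, phi)
            assert got == pytest.approx(want, abs=1e-10)

    def test_more_extreme_split_smaller_p(self):
        baseline, _ = exact_test([30, 30], [30, 30], phi=0.1)
        skewed, _ = exact_test([50, 50], [10, 10], phi=0.1)
        assert skewed < baseline


class TestDispersion:
    def _simulate(self, phi, seed=21):
        cfg = SimulationConfig(seed=seed, n_chroms=1, chrom_length=2_000_000,
                               n_case=8, n_control=8, dispersion=phi,
                               n_planted=0, libsize_spread=(1.0, 1.0))
        genome = generate_genome(cfg)
        counts, _, _ = simulate_dataset(cfg, genome)
        return counts

    def test_recovers_moderate_phi(self):
        counts = self._simulate(0.2)
        est = estimate_dispersion(counts, ["case"] * 8 + ["control"] * 8)
        assert 0.12 <= est.phi <= 0.30
        assert est.n_windows_used == 2000

    def test_poisson_boundary(self):
        counts = self._simulate(0.0)
        est = estimate_dispersion(counts, ["case"] * 8 + ["control"] * 8)
        assert est.phi <= 0.02

    def test_deterministic(self):
        counts = self._simulate(0.1)
        groups = ["case"] * 8 + ["control"] * 8
        assert estimate_dispersion(counts, groups).phi == \
            estimate_dispersion(counts, groups).phi

    def test_needs_two_per_group(self):
        counts = self._simulate(0.1)
        with pytest.raises(ValueError, match=">= 2"):
            estimate_dispersion(counts, ["case"] + ["control"] * 15)


class TestBhFdr:
    def test_worked_vector(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.8])
        assert np.allclose(q, [0.004, 0.02, 0.02 * 4 / 3, 0.8], atol=1e-12)

    def test_equal_ps_rank_cancels(self):
        assert np.allclose(bh_fdr([0.05] * 10), 0.05)

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_monotone_and_order_invariant(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-6, 1, size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(200)
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.1])


class TestTestWindows:
    def test_planted_windows_surface(self, small_dataset):
        counts, truth, sheet = small_dataset
        results, norm, disp = window_tests(counts, sheet["group"])
        assert len(results) == counts.n_windows
        assert 0.03 <= disp.phi <= 0.3
        hits = results[results["p_value"] < 1e-4]
        planted_starts = set()
        for row in truth.itertuples(index=False):
            planted_starts.update(range(int(row.start), int(row.end), 1000))
        assert len(hits) >= 4
        assert set(hits["start"]) <= planted_starts

    def test_equalization_preserves_scale(self, small_dataset):
        counts, _, _ = small_dataset
        norm = tmm_factors(counts)
        eq, common = equalize_counts(counts, norm)
        col_means = eq.mean(axis=0)
        assert col_means.max() / col_means.min() < 1.2
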