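"""Rank tests, Mantel, path analysis — exact small-n oracles by enumeration."""
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from hrscan.errors import ConfigError
from hrscan.stats import (
    correlate,
    euclidean_distances,
    jonckheere_terpstra,
    kruskal_wallis,
    mantel,
    partial_mantel,
    path_analysis,
)


class TestKruskalWallis:
    def test_two_group_hand_value(self):
        h, p = kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert h == pytest.approx(2.4)
        assert p == pytest.approx(1 / 3)  # 2 of 6 assignments reach H >= 2.4

    def test_identical_values(self):
        h, p = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert h == 0.0 and p == 1.0

    def test_one_group_error(self):
        with pytest.raises(ConfigError):
            kruskal_wallis([1, 2], ["a", "a"])

    def test_exact_matches_enumeration_oracle(self, rng):
        values = rng.normal(size=7)
        groups = np.array(["a", "a", "b", "b", "b", "c", "c"])
        h, p = kruskal_wallis(values, groups, p_mode="exact")
        from hrscan.stats import _kw_statistic

        count = total = 0
        idx = range(7)
        for ga in itertools.combinations(idx, 2):
            rest = [i for i in idx if i not in ga]
            for gb in itertools.combinations(rest, 3):
                gc = [i for i in rest if i not in gb]
                stat = _kw_statistic(
                    [values[list(ga)], values[list(gb)], values[list(gc)]]
                )
                count += stat >= h - 1e-12
                total += 1
        assert p == pytest.approx(count / total)


class TestJonckheereTerpstra:
    ORDER = ["lo", "hi"]

    def test_hand_value(self):
        jt, p = jonckheere_terpstra([1, 2, 3, 4], ["lo", "lo", "hi", "hi"], order=self.ORDER)
        assert jt == 4.0
        assert p == pytest.approx(1 / 6)

    def test_all_equal_p_near_one(self):
        jt, p = jonckheere_terpstra([3, 3, 3, 3], ["lo", "lo", "hi", "hi"], order=self.ORDER)
        assert p == pytest.approx(1.0)

    def test_anti_ordered_p_near_one(self):
        _, p = jonckheere_terpstra([4, 3, 2, 1], ["lo", "lo", "hi", "hi"], order=self.ORDER)
        assert p > 0.9

    def test_unordered_factor_error(self):
        with pytest.raises(ConfigError):
            jonckheere_terpstra([1, 2], ["x", "y"], order=["lo", "hi"])


class TestMantel:
    @staticmethod
    def _dist(rng, n):
        x = rng.normal(size=(n, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        return d

    def test_identical_matrices(self, rng):
        d = self._dist(rng, 6)
        r, _ = mantel(d, d)
        assert r == pytest.approx(1.0)

    def test_exact_enumeration_matches_oracle(self, rng):
        a, b = self._dist(rng, 4), self._dist(rng, 4)
        r, p = mantel(a, b)
        iu = np.triu_indices(4, 1)

        def pear(x, y):
            return np.corrcoef(x, y)[0, 1]

        count = total = 0
        robs = pear(a[iu], b[iu])
        for perm in itertools.permutations(range(4)):
            pa = a[np.ix_(perm, perm)]
            count += pear(pa[iu], b[iu]) >= robs - 1e-12
            total += 1
        assert r == pytest.approx(robs)
        assert p == pytest.approx(count / total)

    def test_against_skbio(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        a, b = self._dist(rng, 12), self._dist(rng, 12)
        r, _ = mantel(a, b, n_permutations=499, seed=0)
        r_ref, _, _ = skbio_dist.mantel(a, b, method="pearson", permutations=0)
        assert r == pytest.approx(r_ref)

    def test_asymmetric_rejected(self):
        bad = np.arange(16).reshape(4, 4).astype(float)
        with pytest.raises(ConfigError):
            mantel(bad, bad)

    def test_partial_controls_confounder(self, rng):
        # A and B both driven by C: partial r should shrink toward 0
        n = 25
        c = self._dist(rng, n)
        noise_a, noise_b = self._dist(rng, n), self._dist(rng, n)
        a = c + 0.1 * noise_a
        b = c + 0.1 * noise_b
        r_plain, _ = mantel(a, b, n_permutations=99, seed=1)
        r_part, _ = partial_mantel(a, b, c, n_permutations=99, seed=1)
        assert r_part < r_plain

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(60):
            a, b = self._dist(rng, 12), self._dist(rng, 12)
            _, p = mantel(a, b, n_permutations=199, seed=int(rng.integers(2**31)))
            ps.append(p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestEuclideanDistances:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 2.0], "y": [3.0, 3.0, 1.0]})
        d = euclidean_distances(df, standardize=False)
        assert d.iloc[0, 1] == 0.0

    def test_three_four_five(self):
        df = pd.DataFrame({"x": [0.0, 3.0], "y": [0.0, 4.0]})
        d = euclidean_distances(df, standardize=False)
        assert d.iloc[0, 1] == pytest.approx(5.0)

    def test_standardization_scale_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        d1 = euclidean_distances(df)
        df2 = df.copy()
        df2["b"] *= 10
        d2 = euclidean_distances(df2)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "k": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning):
            d = euclidean_distances(df)
        assert d.shape == (3, 3)


class TestPathAnalysis:
    def test_single_edge_equals_pearson(self, rng):
        x = rng.normal(size=100)
        y = 0.7 * x + rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": y})
        fit = path_analysis(df, [("x", "y")])
        r = np.corrcoef(x, y)[0, 1]
        assert fit["coefficients"][("x", "y")] == pytest.approx(r)

    def test_chain_indirect_effect(self, rng):
        a, b = 0.6, 0.5
        estimates = []
        for _ in range(30):
            x = rng.normal(size=200)
            m = a * x + np.sqrt(1 - a**2) * rng.normal(size=200)
            y = b * m + np.sqrt(1 - b**2) * rng.normal(size=200)
            fit = path_analysis(pd.DataFrame({"x": x, "m": m, "y": y}), [("x", "m"), ("m", "y")])
            estimates.append(fit["effects"][("x", "y")]["indirect"])
        mean = np.mean(estimates)
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - a * b) < 4 * se + 0.02

    def test_cyclic_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"])
        with pytest.raises(ConfigError):
            path_analysis(df, [("x", "y"), ("y", "x")])

    def test_null_r_squared_small(self, rng):
        low = 0
        for _ in range(20):
            df = pd.DataFrame(rng.normal(size=(200, 2)), columns=["x", "y"])
            fit = path_analysis(df, [("x", "y")])
            low += fit["r_squared"]["y"] < 0.05
        assert low >= 18


class TestCorrelate:
    def test_perfect_linear(self):
        r, _ = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_spearman_rank_reversal(self):
        r, _ = correlate([1, 2, 3, 4], [8, 6, 4, 2], method="spearman")
        assert r == pytest.approx(-1.0)

    def test_exact_permutation_matches_enumeration(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, p = correlate(x, y, p_mode="exact")
        count = total = 0
        for perm in itertools.permutations(range(5)):
            rp = np.corrcoef(x, y[list(perm)])[0, 1]
            count += abs(rp) >= abs(r) - 1e-12
            total += 1
        assert p == pytest.approx(count / total)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning):
            r, p = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)


class TestSeedDeterminism:
    def test_permutation_tests_reproducible(self, rng):
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        r1 = jonckheere_terpstra(vals, groups, order=["a", "b", "c"], n_permutations=199, seed=7, p_mode="chi2")
        r2 = jonckheere_terpstra(vals, groups, order=["a", "b", "c"], n_permutations=199, seed=7, p_mode="chi2")
        assert r1 == r2
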