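"""Detection statistics against exhaustive brute-force oracles."""
import itertools
from math import comb

import numpy as np
import pytest
from scipy.stats import binom

from hrscan.alignio import AlignmentBlock
from hrscan.detect import (
    METHODS,
    ScanSettings,
    Triplet,
    chimaera_scan,
    chimaera_sites,
    exact_descent_p,
    geneconv_scan,
    iter_triplets,
    max_breakpoint_chi,
    max_descent,
    maxchi_scan,
    maxchi_tail_bound,
    polymorphic_sites,
    rdp_scan,
    scan_all,
    threeseq_test,
)
from hrscan.errors import ConfigError


def oracle_max_chi(x):
    """Plain-loop exhaustive breakpoint scan of the 2x2 Pearson chi-squared."""
    w = len(x)
    best = 0.0
    for t in range(1, w):
        a = sum(x[:t])
        b = t - a
        c = sum(x[t:])
        d = (w - t) - c
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if c1 == 0 or c2 == 0:
            continue
        best = max(best, w * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2))
    return best


def oracle_max_descent(steps):
    best = 0
    h = [0]
    for s in steps:
        h.append(h[-1] + s)
    for j in range(len(h)):
        for k in range(j, len(h)):
            best = max(best, h[j] - h[k])
    return best


def oracle_max_run(agree):
    best = cur = 0
    for v in agree:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


class TestPolymorphicSites:
    def test_identical_rows_empty(self):
        block = AlignmentBlock.from_strings(["a", "b", "c"], ["ACGT"] * 3)
        assert polymorphic_sites(block).size == 0

    def test_single_divergent_column(self):
        block = AlignmentBlock.from_strings(["a", "b"], ["ACGT", "ACTT"])
        assert list(polymorphic_sites(block)) == [2]

    def test_gap_and_n_are_missing_not_mismatch(self):
        block = AlignmentBlock.from_strings(["a", "b"], ["ACGT", "A-NT"])
        assert polymorphic_sites(block).size == 0

    def test_planted_snps_recovered_exactly(self, rng):
        base = rng.choice(list("ACGT"), size=300)
        other = base.copy()
        snps = sorted(rng.choice(300, size=12, replace=False))
        for s in snps:
            other[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[s]]
        block = AlignmentBlock.from_strings(["a", "b"], ["".join(base), "".join(other)])
        assert list(polymorphic_sites(block)) == snps


class TestMaxChi:
    def test_six_six_split_statistic(self):
        x = np.array([1] * 6 + [0] * 6)
        stat, t = max_breakpoint_chi(x)
        assert stat == pytest.approx(12.0)
        assert t == 6

    def test_uniform_vector_no_signal(self):
        stat, t = max_breakpoint_chi(np.ones(10, dtype=int))
        assert stat == 0.0 and t is None

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        x = (rng.random(rng.integers(5, 30)) < 0.5).astype(int)
        stat, _ = max_breakpoint_chi(x)
        assert stat == pytest.approx(oracle_max_chi(x))

    def test_permutation_p_matches_exact_enumeration(self):
        """6+6 perfect split: exact p over all C(12,6) site labelings."""
        x = [1] * 6 + [0] * 6
        count = total = 0
        for ones in itertools.combinations(range(12), 6):
            y = np.zeros(12, dtype=int)
            y[list(ones)] = 1
            count += oracle_max_chi(y) >= 12.0 - 1e-9
            total += 1
        exact = count / total
        # the scan's p on this triplet (one window) within binomial error
        block = _mosaic_block()
        trip = Triplet(block, "child", "pa", "pb")
        hits = maxchi_scan(trip, window_variable_sites=12, n_permutations=20_000, seed=0)
        assert len(hits) == 1
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(hits[0].raw_p - exact) < 4 * se + 1e-4

    def test_tail_bound_is_conservative(self, rng):
        """Exact hypergeometric union bound dominates the permutation tail."""
        for _ in range(4):
            x = (rng.random(40) < 0.3).astype(int)
            stat, _ = max_breakpoint_chi(x)
            if stat == 0:
                continue
            bound = maxchi_tail_bound(40, int(x.sum()), stat)
            perm = np.array([oracle_max_chi(rng.permutation(x)) for _ in range(400)])
            assert (perm >= stat - 1e-9).mean() <= bound + 3 * np.sqrt(bound * (1 - bound) / 400) + 0.02


def _mosaic_block():
    """Child matches parent A at the first 6 polymorphic sites, B at the last 6."""
    pa = "A" * 6 + "A" * 6
    pb = "C" * 6 + "C" * 6
    child = "A" * 6 + "C" * 6
    out = "G" * 12
    return AlignmentBlock.from_strings(["child", "pa", "pb", "out"], [child, pa, pb, out])


class TestChimaera:
    def test_child_identical_to_parent_no_hit(self):
        block = AlignmentBlock.from_strings(
            ["c", "a", "b"], ["ACGTACGTAC", "ACGTACGTAC", "GTACGTACGT"]
        )
        trip = Triplet(block, "c", "a", "b")
        assert chimaera_scan(trip, window_variable_sites=4) == []

    def test_mismatch_indicator_definition(self):
        # child matches neither parent only at the final column
        block = AlignmentBlock.from_strings(["c", "a", "b"], ["AAT", "AAA", "ACC"])
        trip = Triplet(block, "c", "a", "b")
        sites, y = chimaera_sites(trip)
        assert list(sites) == [1, 2]
        assert list(y) == [False, True]

    def test_parent_swap_symmetry(self):
        block = _mosaic_block()
        s1 = chimaera_sites(Triplet(block, "child", "pa", "pb"))
        s2 = chimaera_sites(Triplet(block, "child", "pb", "pa"))
        assert np.array_equal(s1[0], s2[0])
        assert np.array_equal(s1[1], s2[1])


class TestRdp:
    def test_equal_identities_no_regions(self):
        block = AlignmentBlock.from_strings(
            ["c", "a", "b"], ["A" * 200, "A" * 200, "A" * 200]
        )
        trip = Triplet(block, "c", "a", "b")
        assert rdp_scan(trip, window_nt=50) == []

    def test_binomial_tail_closed_form(self):
        # region with 50/50 child-parent matches at background rate 0.7
        p_direct = float(binom.sf(49, 50, 0.7))
        p_manual = sum(
            comb(50, k) * 0.7**k * 0.3 ** (50 - k) for k in range(50, 51)
        )
        assert p_direct == pytest.approx(p_manual)
        assert p_direct == pytest.approx(0.7**50)

    def test_window_shorter_than_block_required(self, tiny_block):
        trip = Triplet(tiny_block, "childR", "parentA", "parentB")
        assert rdp_scan(trip, window_nt=90) == []  # block shorter than window

    def test_window_floor(self, tiny_block):
        trip = Triplet(tiny_block, "childR", "parentA", "parentB")
        with pytest.raises(ConfigError):
            rdp_scan(trip, window_nt=5)


class TestGeneconv:
    def _pair_block(self, agree):
        """Two strains agreeing exactly where ``agree`` is True, plus two
        divergent fillers so every column is polymorphic."""
        s1, s2 = [], []
        for v in agree:
            s1.append("A")
            s2.append("A" if v else "C")
        filler1 = "G" * len(agree)
        filler2 = "T" * len(agree)
        return AlignmentBlock.from_strings(
            ["x", "y", "f1", "f2"], ["".join(s1), "".join(s2), filler1, filler2]
        )

    def test_unique_run_score_matches_linear_scan(self, rng):
        agree = rng.random(120) < 0.4
        agree[50:60] = True
        agree[49] = agree[60] = False
        block = self._pair_block(agree)
        hits = geneconv_scan(block, ("x", "y"), n_permutations=499, seed=1, p_emit=1.1)
        assert oracle_max_run(agree) == 11 or oracle_max_run(agree) == max(
            h.stat for h in hits
        )
        best = max(h.stat for h in hits)
        assert best == oracle_max_run(agree)

    def test_identical_pair_saturated_flag(self):
        agree = np.ones(30, dtype=bool)
        block = self._pair_block(agree)
        hits = geneconv_scan(block, ("x", "y"), n_permutations=199, seed=0, p_emit=1.1)
        assert hits and all("saturated" in h.flags for h in hits)

    def test_null_p_uniform_by_ks(self, rng):
        """Permutation p of the max run is calibrated for i.i.d. agreement.

        The max-run statistic is discrete, so the calibration check uses the
        randomized (tie-broken) p-value, which is exactly uniform when the
        test is valid.
        """
        from scipy.stats import kstest

        from hrscan.detect import _max_runs, _perm_max_run

        ps = []
        for _ in range(100):
            agree = rng.random(200) < 0.5
            runs = _max_runs(agree)
            obs = max(r[2] for r in runs)
            null = _perm_max_run(agree, 199, rng)
            greater = int((null > obs).sum())
            ties = int((null == obs).sum())
            ps.append((greater + rng.random() * (ties + 1)) / 200)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestThreeSeq:
    def test_descent_examples(self):
        assert max_descent(np.array([1, 1, -1, -1, -1]))[0] == 3
        assert max_descent(np.array([1, 1, 1]))[0] == 0

    def test_exact_p_small_case_bruteforce(self):
        """m=3, n=3, descent >= 3: enumerate all 20 orderings."""
        count = total = 0
        for pos in itertools.combinations(range(6), 3):
            steps = np.array([1 if i in pos else -1 for i in range(6)])
            count += oracle_max_descent(steps) >= 3
            total += 1
        assert total == 20
        assert exact_descent_p(3, 3, 3) == pytest.approx(count / total)

    @pytest.mark.parametrize("m,n", [(4, 5), (6, 3), (5, 5)])
    def test_exact_p_matches_enumeration(self, m, n):
        for d in range(1, n + 1):
            count = total = 0
            for pos in itertools.combinations(range(m + n), m):
                steps = np.array([1 if i in pos else -1 for i in range(m + n)])
                count += oracle_max_descent(steps) >= d
                total += 1
            assert exact_descent_p(m, n, d) == pytest.approx(count / total, abs=1e-12)

    def test_all_up_steps_no_hit(self):
        block = AlignmentBlock.from_strings(
            ["c", "a", "b"], ["AAAA", "AAAA", "CCCC"]
        )
        trip = Triplet(block, "c", "a", "b")
        assert threeseq_test(trip) == []

    def test_parent_labeling_symmetry(self):
        block = _mosaic_block()
        h1 = threeseq_test(Triplet(block, "child", "pa", "pb"), p_emit=1.1)
        h2 = threeseq_test(Triplet(block, "child", "pb", "pa"), p_emit=1.1)
        assert h1 and h2
        assert h1[0].stat == h2[0].stat
        assert h1[0].raw_p == pytest.approx(h2[0].raw_p)


class TestScanAll:
    def test_unknown_method_rejected(self, tiny_block):
        with pytest.raises(ConfigError):
            scan_all(tiny_block, methods=("MAXCHI", "BOGUS"))

    def test_three_strains_three_child_assignments(self):
        block = AlignmentBlock.from_strings(["a", "b", "c"], ["ACGT"] * 3)
        assert len(list(iter_triplets(block))) == 3

    def test_eight_strains_triplet_count(self, small_sim):
        _, block, _ = small_sim
        n = block.n_strains
        assert len(list(iter_triplets(block))) == n * (n - 1) * (n - 2) // 2

    def test_deterministic_given_seed(self, small_sim):
        _, block, _ = small_sim
        h1 = scan_all(block, methods=("MAXCHI", "GENECONV"), seed=3)
        h2 = scan_all(block, methods=("MAXCHI", "GENECONV"), seed=3)
        assert [(h.method, h.child, h.start_col, h.raw_p) for h in h1] == [
            (h.method, h.child, h.start_col, h.raw_p) for h in h2
        ]

    def test_corrected_p_dominates_raw(self, small_sim):
        _, block, _ = small_sim
        hits = scan_all(block, seed=3)
        assert all(h.corrected_p >= h.raw_p for h in hits)
        assert all(0 <= h.raw_p <= 1 and h.start_col < h.end_col for h in hits)
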