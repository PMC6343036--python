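"""Five nonparametric recombination scans over a multi-strain alignment.

Each method examines candidate recombinant/parent configurations and returns
:class:`MethodHit` records (interval in alignment columns, raw p, corrected p).
The formulations are self-contained and oracle-checkable:

* MAXCHI / CHIMAERA — maximum 2x2 chi-squared over single breakpoints in
  windows of consecutive qualifying sites; site-order permutation p.
* RDP — 90-column sliding windows; candidate regions are runs where the
  locally closest pair differs from the genome-wide closest pair; binomial
  tail p for the region's pair-agreement excess.
* GENECONV — maximal mismatch-free runs of pair agreement over polymorphic
  columns; permutation tail of the maximum run score.
* 3SEQ — maximum descent of the +/-1 walk over informative sites, exact
  dynamic-programming tail probability.

Sites with gaps or N in any member of the examined pair/triplet are excluded
from that test (complete-case per test). Corrected p-values are Bonferroni
across all tests (triplets x windows) per method, applied by :func:`scan_all`.

Permutation p-values use the add-one convention and therefore have a floor of
1/(n_permutations+1); when a tail saturates at that floor — or when the caller
only cares about far-below-floor hits (``scan_all``'s emission threshold) —
the scans substitute a conservative analytic bound: an exact hypergeometric
Bonferroni-over-breakpoints bound for MaxChi/Chimaera, a union bound on the
maximum run for GENECONV, the exact DP (or a Hoeffding union bound on the
maximum descent for long walks) for 3Seq. Only with such bounds can genuinely
strong signals survive the corrected p < 0.001 consensus threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import binom, hypergeom

from .alignio import AlignmentBlock
from .errors import ConfigError
from .seqcodes import encode

log = logging.getLogger(__name__)

METHODS = ("RDP", "GENECONV", "MAXCHI", "CHIMAERA", "3SEQ")


@dataclass
class MethodHit:
    """One method's candidate recombinant region."""

    method: str
    child: str
    parent_a: str
    parent_b: str | None
    start_col: int
    end_col: int
    raw_p: float
    corrected_p: float
    breakpoint: int | None = None
    stat: float = 0.0
    flags: tuple = ()

    def overlap(self, other) -> int:
        return max(0, min(self.end_col, other.end_col) - max(self.start_col, other.start_col))


@dataclass
class Triplet:
    """Candidate recombinant (child) and parent pair with informative sites.

    ``sites`` are the alignment columns where the parents differ and the child
    matches exactly one of them (gap/N-free in all three); ``match_a`` flags
    whether the child matches parent A at each site.
    """

    block: AlignmentBlock
    child: str
    parent_a: str
    parent_b: str
    sites: np.ndarray = field(default=None)
    match_a: np.ndarray = field(default=None)

    def __post_init__(self):
        if len({self.child, self.parent_a, self.parent_b}) != 3:
            raise ConfigError("triplet members must be distinct")
        if self.sites is None:
            codes, valid = _codes(self.block)
            c = self.block.index(self.child)
            a = self.block.index(self.parent_a)
            b = self.block.index(self.parent_b)
            ok = valid[c] & valid[a] & valid[b]
            parents_differ = codes[a] != codes[b]
            ma = codes[c] == codes[a]
            mb = codes[c] == codes[b]
            inf = ok & parents_differ & (ma | mb)
            self.sites = np.flatnonzero(inf)
            self.match_a = ma[self.sites]


_CODES_CACHE = {}


def _codes(block: AlignmentBlock):
    """Cached (codes, valid) encoding of a block (keyed by identity)."""
    key = id(block)
    hit = _CODES_CACHE.get(key)
    if hit is None or hit[0] is not block:
        _CODES_CACHE.clear()
        _CODES_CACHE[key] = (block, encode(block.rows))
        hit = _CODES_CACHE[key]
    return hit[1]


def polymorphic_sites(block: AlignmentBlock) -> np.ndarray:
    """Columns with at least two distinct non-gap, non-N residues."""
    codes, valid = _codes(block)
    if block.length == 0:
        return np.array([], dtype=int)
    first_idx = np.argmax(valid, axis=0)
    cols = np.arange(block.length)
    first_code = codes[first_idx, cols]
    any_valid = valid.any(axis=0)
    differs = ((codes != first_code[None, :]) & valid).any(axis=0)
    return np.flatnonzero(any_valid & differs)


def complete_case_columns(block: AlignmentBlock) -> np.ndarray:
    _, valid = _codes(block)
    return np.flatnonzero(valid.all(axis=0))


# ---------------------------------------------------------------------------
# MaxChi / Chimaera machinery


def max_breakpoint_chi(x: np.ndarray):
    """Maximum Pearson chi-squared over all single breakpoints of a 0/1 vector.

    Returns (stat, t) where the breakpoint separates x[:t] from x[t:].
    """
    w = len(x)
    K = int(x.sum())
    if w < 2 or K == 0 or K == w:
        return 0.0, None
    t = np.arange(1, w)
    a = np.cumsum(x)[:-1].astype(float)
    num = w * (a * ((w - t) - (K - a)) - (t - a) * (K - a)) ** 2
    den = t * (w - t) * K * (w - K)
    chi_vals = num / den
    k = int(np.argmax(chi_vals))
    return float(chi_vals[k]), k + 1


def _perm_max_chi(x, n_permutations, rng):
    """Vectorized permutation null of the max-breakpoint chi-squared."""
    w = len(x)
    K = int(x.sum())
    X = rng.permuted(np.tile(x, (n_permutations, 1)), axis=1)
    t = np.arange(1, w, dtype=float)
    a = np.cumsum(X, axis=1)[:, :-1].astype(float)
    num = w * (a * ((w - t) - (K - a)) - (t - a) * (K - a)) ** 2
    den = t * (w - t) * K * (w - K)
    return (num / den).max(axis=1)


def _maxchi_normal_screen(w: int, K: int, stat: float) -> float:
    """Cheap normal-approximation union estimate of the max-chi permutation
    tail, used only to skip clearly null windows before the exact
    hypergeometric bound (which remains the reported quantity)."""
    if stat <= 0 or K == 0 or K == w:
        return 1.0
    t = np.arange(1, w)
    eps = np.sqrt(stat * t * (w - t) * K * (w - K) / w**3)
    var = t * (K / w) * (1 - K / w) * (w - t) / max(w - 1, 1)
    return float(min(1.0, (2.0 * np.exp(-(eps**2) / (2 * var))).sum()))


def maxchi_tail_bound(w: int, K: int, stat: float) -> float:
    """Union (Bonferroni-over-breakpoints) upper bound on the permutation tail
    P(max breakpoint chi-squared >= stat) using the exact hypergeometric
    distribution of the left-cell count at each breakpoint.

    Valid for arbitrarily skewed match compositions, where the asymptotic
    chi-squared tail badly underestimates the permutation null.
    """
    if stat <= 0 or K == 0 or K == w:
        return 1.0
    t = np.arange(1, w)
    # chi = w*(a*w - t*K)^2 / (t(w-t)K(w-K)), so
    # chi >= stat  <=>  |a*w - t*K| >= sqrt(stat * t(w-t)K(w-K) / w)
    root = np.sqrt(stat * t * (w - t) * K * (w - K) / w)
    hi = (t * K + root) / w
    lo = (t * K - root) / w
    upper = hypergeom.sf(np.ceil(hi) - 1, w, K, t)
    lower = hypergeom.cdf(np.floor(lo), w, K, t)
    return float(min(1.0, (upper + lower).sum()))


def segment_boundaries(x: np.ndarray, alpha=0.01, min_size=4, max_depth=14):
    """Binary change-point segmentation of a 0/1 vector.

    Recursively splits at the maximal-chi breakpoint while the split is
    significant under the hypergeometric union bound; boundaries land on
    composition changes, i.e. on tract edges, even inside long uniform runs.
    Returns the sorted boundary list (including 0 and len(x)).
    """
    bounds = [0, len(x)]

    def rec(i, j, depth):
        if j - i < 2 * min_size or depth == 0:
            return
        seg = x[i:j]
        stat, t = max_breakpoint_chi(seg)
        if t is None:
            return
        if maxchi_tail_bound(j - i, int(seg.sum()), stat) < alpha:
            bounds.append(i + t)
            rec(i, i + t, depth - 1)
            rec(i + t, j, depth - 1)

    rec(0, len(x), max_depth)
    return sorted(set(bounds))


def anomalous_segment(x: np.ndarray, bounds, anchor: int):
    """Of the two segments flanking the boundary nearest ``anchor``, return
    the one whose composition deviates most from the global rate (binomial
    z-score)."""
    w = len(x)
    p_glob = x.mean()
    var = max(p_glob * (1 - p_glob), 1e-9)
    inner = [b for b in bounds if 0 < b < w]
    if not inner:
        return 0, w
    nearest = min(inner, key=lambda b: abs(b - anchor))
    k = bounds.index(nearest)
    candidates = [(bounds[k - 1], bounds[k]), (bounds[k], bounds[k + 1])]

    def zscore(seg):
        i, j = seg
        if j <= i:
            return -1.0
        return abs(float(x[i:j].mean()) - p_glob) * np.sqrt((j - i) / var)

    return max(candidates, key=zscore)


def _merge_hits(hits, min_frac=0.33):
    """Union same-triplet hits that overlap substantially, keeping the
    smallest p (chains of weakly touching intervals are left apart)."""
    if not hits:
        return hits
    hits = sorted(hits, key=lambda h: h.start_col)
    out = [hits[0]]
    for h in hits[1:]:
        last = out[-1]
        ov = min(last.end_col, h.end_col) - max(last.start_col, h.start_col)
        shorter = min(last.end_col - last.start_col, h.end_col - h.start_col)
        if ov > min_frac * max(shorter, 1):
            merged = replace(
                last,
                start_col=min(last.start_col, h.start_col),
                end_col=max(last.end_col, h.end_col),
                raw_p=min(last.raw_p, h.raw_p),
                corrected_p=min(last.corrected_p, h.corrected_p),
                stat=max(last.stat, h.stat),
            )
            out[-1] = merged
        else:
            out.append(h)
    return out


def _chi_window_scan(
    triplet,
    sites,
    match_a,
    method,
    window_variable_sites,
    n_permutations,
    seed,
    tally=None,
    p_emit=0.01,
):
    m = len(sites)
    if m < 4:
        log.debug("%s: %d informative sites, skipping triplet", method, m)
        return []
    if window_variable_sites < 4:
        raise ConfigError("window_variable_sites must be >= 4")
    w = min(window_variable_sites, m)
    # quarter-window step keeps some window edge near any true tract boundary,
    # where the single-breakpoint statistic peaks
    step = max(1, w // 4)
    starts = list(range(0, m - w + 1, step))
    if starts[-1] != m - w:
        starts.append(m - w)
    rng = np.random.default_rng(seed)
    xfull = match_a.astype(np.int64)
    floor = 1.0 / (n_permutations + 1)
    # when only far-below-floor hits can matter downstream, the analytic
    # bound is the p-value and permutations are pointless
    fast = p_emit < floor
    sig_windows = []
    for s in starts:
        if tally is not None:
            tally[method] = tally.get(method, 0) + 1
        x = xfull[s : s + w]
        stat, bp = max_breakpoint_chi(x)
        if stat == 0.0 or bp is None:
            continue
        screen = _maxchi_normal_screen(w, int(x.sum()), stat)
        if screen > (1e-3 if fast else 0.5):
            continue  # cannot reach the emission threshold
        bound = maxchi_tail_bound(w, int(x.sum()), stat)
        if fast or bound > 0.1 or bound < floor:
            raw = bound
        else:
            exceed = int((_perm_max_chi(x, 200, rng) >= stat - 1e-9).sum())
            if exceed >= 20:
                raw = (1 + exceed) / (1 + 200)
            else:
                exceed = int((_perm_max_chi(x, n_permutations, rng) >= stat - 1e-9).sum())
                raw = (1 + exceed) / (1 + n_permutations)
                if exceed == 0:
                    raw = min(raw, bound)  # permutation floor: analytic fallback
        if raw <= p_emit:
            sig_windows.append((s, stat, bp, raw))
    if not sig_windows:
        return []
    # tract edges announced by the significant windows: cluster their argmax
    # breakpoints, then report the anomalous segment next to each window's own
    bounds = cluster_breakpoints([s + bp for s, _, bp, _ in sig_windows], m)
    hits = []
    for s, stat, bp, raw in sig_windows:
        i, j = anomalous_segment(xfull, bounds, s + bp)
        if j <= i:
            continue
        # a window only witnesses its own vicinity: cap the reported interval
        # in column space (windows tiling a long tract merge below)
        start_col = int(sites[i])
        end_col = int(sites[j - 1]) + 1
        bp_col = int(sites[s + bp - 1])
        win_cols = int(sites[min(s + w - 1, m - 1)]) - int(sites[s]) + 1
        start_col = max(start_col, bp_col - 2 * win_cols)
        end_col = min(end_col, bp_col + 2 * win_cols)
        if end_col <= start_col:
            continue
        hits.append(
            MethodHit(
                method=method,
                child=triplet.child,
                parent_a=triplet.parent_a,
                parent_b=triplet.parent_b,
                start_col=start_col,
                end_col=end_col,
                raw_p=raw,
                corrected_p=raw,
                breakpoint=bp_col,
                stat=stat,
            )
        )
    return _merge_hits(hits)


def cluster_breakpoints(bps, m, tol=8):
    """Collapse breakpoints within ``tol`` site positions to their median and
    return them as segment boundaries of [0, m)."""
    edges = []
    group = []
    for b in sorted(bps):
        if group and b - group[-1] > tol:
            edges.append(int(np.median(group)))
            group = []
        group.append(b)
    if group:
        edges.append(int(np.median(group)))
    return sorted({0, m, *(e for e in edges if 0 < e < m)})


def maxchi_scan(
    triplet: Triplet,
    window_variable_sites=210,
    n_permutations=1999,
    seed=None,
    tally=None,
    p_emit=0.01,
):
    """Maximum chi-squared scan over windows of consecutive informative sites.

    Default window of 210 variable sites; statistic is the maximum single-
    breakpoint 2x2 chi-squared, significance by site-order permutation.
    """
    return _chi_window_scan(
        triplet,
        triplet.sites,
        triplet.match_a,
        "MAXCHI",
        window_variable_sites,
        n_permutations,
        seed,
        tally,
        p_emit,
    )


def chimaera_sites(triplet: Triplet):
    """Qualifying columns (child differs from at least one parent, gap/N-free
    in all three) and the child-vs-chimaera mismatch indicator on them.

    The best chimeric parent takes whichever parental residue matches the
    child, so the chimaera mismatches the child exactly where the child
    matches *neither* parent — the signature of DNA imported from a lineage
    outside the parent pair. A child identical to one parent never mismatches
    its chimaera and yields no signal. This makes Chimaera the divergence
    channel, complementary to MaxChi's parental-switch channel.
    """
    codes, valid = _codes(triplet.block)
    c = triplet.block.index(triplet.child)
    a = triplet.block.index(triplet.parent_a)
    b = triplet.block.index(triplet.parent_b)
    ok = valid[c] & valid[a] & valid[b]
    da = codes[c] != codes[a]
    db = codes[c] != codes[b]
    qual = ok & (da | db)
    sites = np.flatnonzero(qual)
    return sites, (da & db)[sites]


def chimaera_scan(triplet: Triplet, window_variable_sites=210, n_permutations=1999, seed=None, tally=None, p_emit=0.01):
    """Maximum chi-squared scan of child-vs-chimaera mismatches (see
    :func:`chimaera_sites`); windowing, permutation p and reporting follow the
    MaxChi machinery."""
    sites, mismatch = chimaera_sites(triplet)
    return _chi_window_scan(
        triplet, sites, mismatch, "CHIMAERA", window_variable_sites, n_permutations, seed, tally, p_emit
    )


# ---------------------------------------------------------------------------
# RDP


_PAIRS = ((0, 1), (0, 2), (1, 2))  # (child,A), (child,B), (A,B)


def rdp_scan(triplet: Triplet, window_nt=90, seed=None, tally=None, p_emit=0.01):
    """Sliding-window pairwise-identity scan (window in alignment columns).

    Candidate regions are maximal runs of windows whose locally closest pair
    differs from the genome-wide closest pair. The region p-value is the
    binomial tail of the local pair-agreement count at polymorphic columns
    given the pair's genome-wide agreement rate.
    """
    if window_nt < 10:
        raise ConfigError("window_nt must be >= 10")
    block = triplet.block
    codes, valid = _codes(block)
    idx = [block.index(triplet.child), block.index(triplet.parent_a), block.index(triplet.parent_b)]
    ok = valid[idx[0]] & valid[idx[1]] & valid[idx[2]]
    cols = np.flatnonzero(ok)
    M = len(cols)
    if M < window_nt:
        log.debug("RDP: window longer than usable columns, skipping")
        return []
    sub = codes[np.ix_(idx, cols)]
    match = np.array([sub[i] == sub[j] for i, j in _PAIRS])  # (3, M)
    gfrac = match.mean(axis=1)
    global_closest = int(np.argmax(gfrac))

    step = max(1, window_nt // 3)
    starts = np.arange(0, M - window_nt + 1, step)
    if tally is not None:
        tally["RDP"] = tally.get("RDP", 0) + len(starts)
    cs = np.concatenate([np.zeros((3, 1), dtype=int), np.cumsum(match, axis=1)], axis=1)
    local = (cs[:, starts + window_nt] - cs[:, starts]).astype(float)  # (3, W)
    local_closest = np.argmax(local, axis=0)
    discord = local_closest != global_closest

    # polymorphic complete-case columns, for the binomial model
    poly = np.flatnonzero((sub != sub[0]).any(axis=0) | (sub[1] != sub[2]))
    hits = []
    W = len(starts)
    i = 0
    while i < W:
        if not discord[i]:
            i += 1
            continue
        j = i
        while j + 1 < W and discord[j + 1]:
            j += 1
        lo = int(starts[i])
        hi = int(min(starts[j] + window_nt, M))
        # modal locally-closest pair over the run
        pairs, counts = np.unique(local_closest[i : j + 1], return_counts=True)
        pair = int(pairs[np.argmax(counts)])
        in_region = poly[(poly >= lo) & (poly < hi)]
        n = len(in_region)
        if n >= 2:
            k = int(match[pair][in_region].sum())
            q = match[pair][poly].mean() if len(poly) else 0.5
            raw = float(binom.sf(k - 1, n, q))
        else:
            raw = 1.0
        if raw <= p_emit:
            hits.append(
                MethodHit(
                    method="RDP",
                    child=triplet.child,
                    parent_a=triplet.parent_a,
                    parent_b=triplet.parent_b,
                    start_col=int(cols[lo]),
                    end_col=int(cols[hi - 1]) + 1,
                    raw_p=raw,
                    corrected_p=raw,
                    stat=float(k) if n >= 2 else 0.0,
                )
            )
        i = j + 1
    return _merge_hits(hits)


# ---------------------------------------------------------------------------
# GENECONV


def _max_runs(agree: np.ndarray):
    """Maximal runs of True; returns list of (start_idx, end_idx, length)."""
    runs = []
    i = 0
    n = len(agree)
    while i < n:
        if agree[i]:
            j = i
            while j + 1 < n and agree[j + 1]:
                j += 1
            runs.append((i, j + 1, j + 1 - i))
            i = j + 1
        else:
            i += 1
    return runs


def _perm_max_run(agree, n_permutations, rng):
    """Vectorized null distribution of the maximum run under column shuffles."""
    X = rng.permuted(np.tile(agree, (n_permutations, 1)), axis=1)
    c = np.cumsum(X, axis=1)
    reset = np.maximum.accumulate(np.where(X, 0, c), axis=1)
    return (c - reset).max(axis=1)


def geneconv_scan(block: AlignmentBlock, pair, n_permutations=1999, seed=None, tally=None, p_emit=0.01):
    """Sawyer-style inner fragments for one strain pair (g-scale 0).

    The block is condensed to polymorphic columns; fragments are maximal
    mismatch-free runs of pair agreement, scored by run length in condensed
    columns; significance is the permutation tail of the maximum run score.
    Two hits are emitted per significant fragment, one with each pair member in
    the recombinant role (the pairwise test cannot orient the transfer).
    """
    sa, sb = pair
    codes, valid = _codes(block)
    ia, ib = block.index(sa), block.index(sb)
    poly = polymorphic_sites(block)
    if len(poly) < 2:
        return []
    ok = valid[ia][poly] & valid[ib][poly]
    poly = poly[ok]
    if len(poly) < 2:
        return []
    agree = codes[ia][poly] == codes[ib][poly]
    runs = _max_runs(agree)
    if tally is not None:
        tally["GENECONV"] = tally.get("GENECONV", 0) + 1
    if not runs:
        return []
    obs_max = max(r[2] for r in runs)
    q = float(agree.mean())
    P = len(agree)
    if obs_max == P:
        # pair identical at every polymorphic site: degenerate full-length run,
        # reported at the permutation floor and flagged
        floor = 1.0 / (n_permutations + 1)
        return [
            MethodHit(
                method="GENECONV", child=child, parent_a=parent, parent_b=None,
                start_col=int(poly[0]), end_col=int(poly[-1]) + 1,
                raw_p=floor, corrected_p=floor, stat=float(P), flags=("saturated",),
            )
            for child, parent in ((sa, sb), (sb, sa))
        ]
    best_bound = min(1.0, (P - obs_max + 1) * q**obs_max) if 0 < q < 1 else 1.0
    if best_bound > max(0.5, p_emit):
        return []  # even the union bound on the best run is unremarkable
    null_max = None
    if p_emit >= 1.0 / (n_permutations + 1) and best_bound >= 1.0 / (n_permutations + 1):
        rng = np.random.default_rng(seed)
        null_max = _perm_max_run(agree, 150, rng)
        n_null = 150
        if int((null_max >= obs_max).sum()) < 10:
            null_max = np.concatenate(
                [null_max, _perm_max_run(agree, n_permutations - 150, rng)]
            )
            n_null = n_permutations
    hits = []
    flags = ()
    if obs_max == P:
        flags = ("saturated",)
    for start, end, length in runs:
        bound = min(1.0, (P - length + 1) * q**length) if 0 < q < 1 else 1.0
        if null_max is None:
            raw = bound
        else:
            exceed = int((null_max >= length).sum())
            raw = (1 + exceed) / (1 + n_null)
            if exceed == 0:
                # union bound on the max run when the permutation tail saturates
                raw = min(raw, bound)
        if raw > p_emit:
            continue
        for child, parent in ((sa, sb), (sb, sa)):
            hits.append(
                MethodHit(
                    method="GENECONV",
                    child=child,
                    parent_a=parent,
                    parent_b=None,
                    start_col=int(poly[start]),
                    end_col=int(poly[end - 1]) + 1,
                    raw_p=raw,
                    corrected_p=raw,
                    stat=float(length),
                    flags=flags,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# 3Seq


def max_descent(steps: np.ndarray):
    """Maximum descent of a +/-1 walk and its (start, end) step indices."""
    heights = np.concatenate([[0], np.cumsum(steps)])
    runmax = np.maximum.accumulate(heights)
    drop = runmax - heights
    k = int(np.argmax(drop))
    d = int(drop[k])
    if d == 0:
        return 0, 0, 0
    j = int(np.argmax(heights[: k + 1] == runmax[k]))
    return d, j, k


def exact_descent_p(m: int, n: int, d: int) -> float:
    """P(max descent >= d) over all C(m+n, m) orderings of m up / n down steps.

    Dynamic programme over (ups used, deficit below running maximum); counts
    are carried with a running power-of-two rescale so the result is exact to
    float precision for walks of thousands of steps.
    """
    if d <= 0:
        return 1.0
    if d > n:
        return 0.0
    from math import lgamma, log

    f = np.zeros((m + 1, d))
    f[0, 0] = 1.0
    scale_log = 0.0  # log of the factor taken out of f
    up_shift = np.zeros_like(f)
    for _ in range(m + n):
        up_shift[:, :] = 0.0
        # up step: i -> i+1, deficit s -> max(s-1, 0)
        up_shift[1:, 0] = f[:-1, 0] + (f[:-1, 1] if d > 1 else 0.0)
        if d > 2:
            up_shift[1:, 1 : d - 1] = f[:-1, 2:d]
        new = up_shift.copy()
        # down step: deficit s -> s+1 (paths reaching d are discarded)
        new[:, 1:] += f[:, : d - 1]
        f = new
        peak = f.max()
        if peak > 1e280:
            f /= 2.0**64
            scale_log += 64 * log(2.0)
    total_log = lgamma(m + n + 1) - lgamma(m + 1) - lgamma(n + 1)
    surv = float(f[m, :].sum())
    if surv <= 0.0:
        return 1.0
    p = 1.0 - np.exp(np.log(surv) + scale_log - total_log)
    return float(min(max(p, 0.0), 1.0))


def hoeffding_descent_bound(m: int, n: int, d: int) -> float:
    """Union/Hoeffding upper bound on P(max descent >= d) for an exchangeable
    walk with m up and n down steps (without-replacement sampling).

    Used only when the permutation tail has saturated on long walks; always
    conservative relative to the exact DP value.
    """
    if d <= 0:
        return 1.0
    N = m + n
    if d > n:
        return 0.0
    ell = np.arange(d, N + 1, dtype=float)
    mu = ell * (n - m) / N  # expected down-excess of an interval of length ell
    t = d - mu
    terms = np.where(t > 0, (N - ell + 1) * np.exp(-(t**2) / (2.0 * ell)), N - ell + 1)
    return float(min(1.0, terms.sum()))


def threeseq_test(triplet: Triplet, n_permutations=1999, seed=None, tally=None, p_emit=0.01):
    """Maximum-descent test on the informative-site walk of one triplet.

    The statistic is symmetrized over descent/ascent so parent labeling is
    immaterial. The tail probability is exact (dynamic programme) for walks up
    to 400 informative sites; longer walks use a two-stage seeded permutation
    tail, replaced by a conservative Hoeffding union bound when it saturates.
    The reported interval is the maximally anomalous segment of the walk.
    """
    sites = triplet.sites
    if len(sites) < 1:
        return []
    steps = np.where(triplet.match_a, 1, -1)
    m = int((steps == 1).sum())
    n = int((steps == -1).sum())
    if tally is not None:
        tally["3SEQ"] = tally.get("3SEQ", 0) + 1
    if m == 0 or n == 0:
        return []
    d_desc, j1, k1 = max_descent(steps)
    d_asc, j2, k2 = max_descent(-steps)
    if d_asc > d_desc:
        d, j, k, mm, nn = d_asc, j2, k2, n, m
    else:
        d, j, k, mm, nn = d_desc, j1, k1, m, n
    if d == 0:
        return []
    if m + n <= 400:
        raw = exact_descent_p(mm, nn, d)
    else:
        hb = hoeffding_descent_bound(mm, nn, d)
        if hb > 0.5 or p_emit < 1.0 / (n_permutations + 1):
            raw = hb  # valid bound; permutations could not sharpen a usable p
        else:
            rng = np.random.default_rng(seed)
            raw = None
            for nperm in (150, n_permutations):
                X = rng.permuted(np.tile(steps, (nperm, 1)), axis=1)
                H = np.cumsum(X, axis=1)
                drop = (np.maximum.accumulate(H, axis=1) - H).max(axis=1)
                rise = (H - np.minimum.accumulate(H, axis=1)).max(axis=1)
                exceed = int((np.maximum(drop, rise) >= d).sum())
                raw = (1 + exceed) / (1 + nperm)
                if exceed >= 10:
                    break
            if exceed == 0:
                raw = min(raw, hb)
    if raw > p_emit:
        return []
    # report the change-point segment around the steepest part of the run
    xfull = triplet.match_a.astype(np.int64)
    bounds = segment_boundaries(xfull)
    i, j = anomalous_segment(xfull, bounds, (j + k) // 2)
    if j <= i:
        return []
    return [
        MethodHit(
            method="3SEQ",
            child=triplet.child,
            parent_a=triplet.parent_a,
            parent_b=triplet.parent_b,
            start_col=int(sites[i]),
            end_col=int(sites[j - 1]) + 1,
            raw_p=raw,
            corrected_p=raw,
            stat=float(d),
        )
    ]


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class ScanSettings:
    """Per-method settings with the pipeline's printed defaults."""

    rdp_window_nt: int = 90
    maxchi_window_sites: int = 210
    chimaera_window_sites: int = 210
    n_permutations: int = 1999
    #: emission threshold on raw p inside scan_all; hits far above the
    #: Bonferroni-corrected consensus cutoff cannot support an event
    p_emit: float = 1e-6


def iter_triplets(block: AlignmentBlock):
    """All ordered-child triplets (child x unordered parent pair)."""
    ids = block.strain_ids
    for child in ids:
        rest = [s for s in ids if s != child]
        for i in range(len(rest)):
            for j in range(i + 1, len(rest)):
                yield child, rest[i], rest[j]


def scan_all(block: AlignmentBlock, methods=METHODS, settings=None, seed=None):
    """Run the configured methods over all triplets (pairs for GENECONV) and
    pool hits with Bonferroni-corrected p across tests per method."""
    settings = settings or ScanSettings()
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigError(f"unknown method(s): {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    tally = {}
    hits = []

    triplet_methods = [m for m in methods if m in ("MAXCHI", "CHIMAERA", "RDP", "3SEQ")]
    if triplet_methods:
        for t_i, (c, a, b) in enumerate(iter_triplets(block)):
            trip = Triplet(block, c, a, b)
            sub = np.random.SeedSequence(entropy=(seed if seed is not None else 0, 1, t_i))
            seeds = sub.generate_state(4)
            if "MAXCHI" in methods:
                hits += maxchi_scan(trip, settings.maxchi_window_sites, settings.n_permutations, int(seeds[0]), tally, settings.p_emit)
            if "CHIMAERA" in methods:
                hits += chimaera_scan(trip, settings.chimaera_window_sites, settings.n_permutations, int(seeds[1]), tally, settings.p_emit)
            if "RDP" in methods:
                hits += rdp_scan(trip, settings.rdp_window_nt, int(seeds[2]), tally, settings.p_emit)
            if "3SEQ" in methods:
                hits += threeseq_test(trip, settings.n_permutations, int(seeds[3]), tally, settings.p_emit)

    if "GENECONV" in methods:
        ids = block.strain_ids
        for p_i, (i, j) in enumerate((i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))):
            sub = np.random.SeedSequence(entropy=(seed if seed is not None else 0, 2, p_i))
            hits += geneconv_scan(
                block, (ids[i], ids[j]), settings.n_permutations, int(sub.generate_state(1)[0]), tally,
                settings.p_emit,
            )

    for h in hits:
        h.corrected_p = min(1.0, h.raw_p * max(tally.get(h.method, 1), 1))
    log.info("scan_all: %d hits, tests per method %s", len(hits), tally)
    return hits
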