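"""Group-difference, correlation, matrix-association and path-analysis tools.

These link per-species recombination summaries (events/strain, % recombined,
r/m) to lifestyle and genomic covariates: Kruskal-Wallis and the ordered-
alternative Jonckheere-Terpstra test across lifestyle classes, Pearson /
Spearman correlations, Mantel and partial Mantel tests on distance matrices,
and a recursive OLS path analysis decomposing standardized effects into direct
and indirect components.

All permutation p-values are seed-deterministic and use the add-one
convention; exact enumeration replaces sampling whenever the arrangement count
is small (<= ``EXACT_LIMIT`` group assignments; n <= 7 for Mantel).
"""
from __future__ import annotations

import itertools
import warnings
from math import comb, factorial

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, kruskal, pearsonr, rankdata, spearmanr

from .errors import ConfigError

EXACT_LIMIT = 100_000

LIFESTYLE_ORDER = (
    "endosymbiont",
    "obligate_pathogen",
    "commensal_free_living",
    "opportunistic_pathogen",
)


def _as_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    return [values[groups == g] for g in labels], labels


def _n_arrangements(sizes):
    n = sum(sizes)
    total = 1
    for s in sizes:
        total *= comb(n, s)
        n -= s
    return total


def _iter_partitions(indices, sizes):
    """All distinct assignments of ``indices`` into ordered groups of ``sizes``."""
    if len(sizes) == 1:
        yield (tuple(indices),)
        return
    first, rest = sizes[0], sizes[1:]
    idx = list(indices)
    for chosen in itertools.combinations(idx, first):
        chosen_set = set(chosen)
        remaining = [i for i in idx if i not in chosen_set]
        for tail in _iter_partitions(remaining, rest):
            yield (chosen,) + tail


def _kw_statistic(samples):
    all_vals = np.concatenate(samples)
    n = len(all_vals)
    ranks = rankdata(all_vals)
    offset = 0
    h = 0.0
    for s in samples:
        r = ranks[offset : offset + len(s)]
        h += r.sum() ** 2 / len(s)
        offset += len(s)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(values, groups, p_mode="auto"):
    """Tie-corrected Kruskal-Wallis H and its p-value.

    ``p_mode``: 'chi2' (asymptotic), 'exact' (enumeration over all group
    assignments) or 'auto' (exact when the arrangement count is small).
    """
    samples, labels = _as_groups(values, groups)
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ConfigError("need >=2 non-empty groups")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h = _kw_statistic(samples)
    sizes = [len(s) for s in samples]
    if p_mode == "exact" or (p_mode == "auto" and _n_arrangements(sizes) <= EXACT_LIMIT):
        count = total = 0
        for part in _iter_partitions(range(len(pooled)), sizes):
            stat = _kw_statistic([pooled[list(ix)] for ix in part])
            count += stat >= h - 1e-12
            total += 1
        return float(h), count / total
    try:
        p = float(kruskal(*samples).pvalue)
    except ValueError:
        p = float(chi2.sf(h, len(samples) - 1))
    return float(h), p


def _jt_statistic(samples):
    jt = 0.0
    for a, b in itertools.combinations(samples, 2):
        aa = np.asarray(a)[:, None]
        bb = np.asarray(b)[None, :]
        jt += (aa < bb).sum() + 0.5 * (aa == bb).sum()
    return float(jt)


def jonckheere_terpstra(values, groups, order=None, n_permutations=9999, seed=None, p_mode="auto"):
    """Jonckheere-Terpstra trend test for an increase along ordered groups.

    One-sided p (greater): exact enumeration when feasible, otherwise a seeded
    permutation tail with add-one correction.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if order is None:
        raise ConfigError("jonckheere_terpstra requires an explicit group order")
    order = list(order)
    present = [g for g in order if (groups == g).any()]
    extra = set(groups) - set(order)
    if extra:
        raise ConfigError(f"groups {sorted(extra)} missing from the declared order")
    if len(present) < 2:
        raise ConfigError("need >=2 ordered groups with data")
    samples = [values[groups == g] for g in present]
    jt = _jt_statistic(samples)
    sizes = [len(s) for s in samples]
    pooled = np.concatenate(samples)
    if p_mode == "exact" or (p_mode == "auto" and _n_arrangements(sizes) <= EXACT_LIMIT):
        count = total = 0
        for part in _iter_partitions(range(len(pooled)), sizes):
            stat = _jt_statistic([pooled[list(ix)] for ix in part])
            count += stat >= jt - 1e-12
            total += 1
        return jt, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        off = 0
        ss = []
        for s in sizes:
            ss.append(perm[off : off + s])
            off += s
        count += _jt_statistic(ss) >= jt - 1e-12
    return jt, (1 + count) / (1 + n_permutations)


# ---------------------------------------------------------------------------
# Mantel


def _check_dist(mat, name):
    m = np.asarray(mat, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] < 4:
        raise ConfigError(f"{name}: need a square matrix with n >= 4")
    if np.isnan(m).any():
        raise ConfigError(f"{name}: NaN entries")
    if not np.allclose(m, m.T):
        raise ConfigError(f"{name}: matrix not symmetric")
    if not np.allclose(np.diag(m), 0):
        raise ConfigError(f"{name}: diagonal not zero")
    return m


def _upper(m):
    return m[np.triu_indices(m.shape[0], k=1)]


def _pearson(x, y):
    x = x - x.mean()
    y = y - y.mean()
    den = np.sqrt((x**2).sum() * (y**2).sum())
    return float((x * y).sum() / den) if den > 0 else 0.0


def mantel(dist_a, dist_b, n_permutations=9999, seed=None):
    """Mantel matrix-correlation test.

    r is the Pearson correlation of the upper triangles; p (one-sided,
    greater) comes from simultaneous row/column permutations of the first
    matrix — exact enumeration for n <= 7, otherwise seeded sampling with the
    add-one convention.
    """
    a = _check_dist(dist_a, "dist_a")
    b = _check_dist(dist_b, "dist_b")
    if a.shape != b.shape:
        raise ConfigError("matrices differ in size")
    n = a.shape[0]
    r_obs = _pearson(_upper(a), _upper(b))
    ub = _upper(b)
    if n <= 7:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            pa = a[np.ix_(perm, perm)]
            count += _pearson(_upper(pa), ub) >= r_obs - 1e-12
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pa = a[np.ix_(perm, perm)]
        count += _pearson(_upper(pa), ub) >= r_obs - 1e-12
    return r_obs, (1 + count) / (1 + n_permutations)


def _partial_r(ra, rb, rc):
    den = np.sqrt((1 - rb**2) * (1 - rc**2))
    return (ra - rb * rc) / den if den > 0 else 0.0


def partial_mantel(dist_a, dist_b, dist_c, n_permutations=9999, seed=None):
    """Partial Mantel test of A ~ B controlling C (first-order partial r of
    the upper triangles; permutations applied to A)."""
    a = _check_dist(dist_a, "dist_a")
    b = _check_dist(dist_b, "dist_b")
    c = _check_dist(dist_c, "dist_c")
    if not (a.shape == b.shape == c.shape):
        raise ConfigError("matrices differ in size")
    n = a.shape[0]
    ub, uc = _upper(b), _upper(c)
    r_bc = _pearson(ub, uc)

    def partial_of(mat):
        ua = _upper(mat)
        return _partial_r(_pearson(ua, ub), _pearson(ua, uc), r_bc)

    r_obs = partial_of(a)
    if n <= 7:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            count += partial_of(a[np.ix_(perm, perm)]) >= r_obs - 1e-12
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        count += partial_of(a[np.ix_(perm, perm)]) >= r_obs - 1e-12
    return r_obs, (1 + count) / (1 + n_permutations)


def euclidean_distances(table: pd.DataFrame, columns=None, standardize=True) -> pd.DataFrame:
    """Pairwise Euclidean distances between species over selected columns.

    Numeric columns are z-standardized (constant columns dropped with a
    warning); categorical columns are expanded into 0/1 dummies first.
    """
    df = table[list(columns)] if columns is not None else table.copy()
    blocks = []
    for col in df.columns:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            arr = s.astype(float).values
            if standardize:
                sd = arr.std(ddof=0)
                if sd == 0:
                    warnings.warn(f"dropping constant column {col!r}")
                    continue
                arr = (arr - arr.mean()) / sd
            blocks.append(arr[:, None])
        else:
            dummies = pd.get_dummies(s).astype(float).values
            blocks.append(dummies)
    if not blocks:
        raise ConfigError("no usable columns for distance computation")
    X = np.hstack(blocks)
    d = squareform(pdist(X))
    idx = table.index if columns is not None else df.index
    return pd.DataFrame(d, index=idx, columns=idx)


# ---------------------------------------------------------------------------
# Path analysis


def path_analysis(table: pd.DataFrame, edges):
    """Recursive path model fitted by per-equation OLS on z-standardized data.

    ``edges`` is a list of (source, target) pairs forming a DAG. Returns a dict
    with per-edge standardized coefficients and p-values, per-equation R2, and
    a direct/indirect/total effect decomposition (indirect = sum over directed
    paths of the products of edge coefficients).
    """
    g = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ConfigError("path model must be acyclic")
    cols = list(g.nodes)
    data = table[cols].astype(float)
    z = (data - data.mean()) / data.std(ddof=1)
    coefs, pvals, r2 = {}, {}, {}
    for node in nx.topological_sort(g):
        parents = list(g.predecessors(node))
        if not parents:
            continue
        X = z[parents].values
        cond = np.linalg.cond(X.T @ X)
        if cond > 1e8:
            warnings.warn(f"collinear predictors for {node!r} (condition number {cond:.3g})")
        model = sm.OLS(z[node].values, sm.add_constant(X)).fit()
        for i, p in enumerate(parents):
            coefs[(p, node)] = float(model.params[i + 1])
            pvals[(p, node)] = float(model.pvalues[i + 1])
        r2[node] = float(model.rsquared)
    effects = {}
    for x in cols:
        for y in cols:
            if x == y:
                continue
            direct = coefs.get((x, y), 0.0)
            indirect = 0.0
            for path in nx.all_simple_paths(g, x, y):
                if len(path) <= 2:
                    continue
                prod = 1.0
                for a, b in zip(path[:-1], path[1:]):
                    prod *= coefs.get((a, b), 0.0)
                indirect += prod
            if direct or indirect:
                effects[(x, y)] = {
                    "direct": direct,
                    "indirect": indirect,
                    "total": direct + indirect,
                }
    return {"coefficients": coefs, "p_values": pvals, "r_squared": r2, "effects": effects}


def correlate(x, y, method="pearson", p_mode="auto"):
    """Pearson or Spearman correlation with two-sided p.

    Exact permutation p (enumeration of all orderings) replaces the t
    approximation for n <= 8 under ``p_mode='auto'``; zero-variance input
    yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance input: correlation undefined")
        return float("nan"), float("nan")
    fn = pearsonr if method == "pearson" else spearmanr
    if method not in ("pearson", "spearman"):
        raise ConfigError("method must be 'pearson' or 'spearman'")
    r, p = fn(x, y)
    r, p = float(r), float(p)
    n = len(x)
    if p_mode == "exact" or (p_mode == "auto" and factorial(n) <= 50_000):
        count = total = 0
        for perm in itertools.permutations(range(n)):
            rp = fn(x, y[list(perm)])[0]
            count += abs(rp) >= abs(r) - 1e-12
            total += 1
        p = count / total
    return r, p
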