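"""Functional-category enrichment of recombined genes, and profile clustering.

Genes overlapping consensus events (by >= 1 bp, per strain, de-duplicated by
ortholog id) are contrasted against the remaining annotated genes with a
two-sided Fisher exact test per category, Benjamini-Hochberg FDR across
categories, and an over/under direction from the odds ratio. Signed per-species
enrichment profiles (-1/0/+1) are compared with a simple matching coefficient
and clustered by average linkage.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, MissingDataError


def genes_in_events(events, gene_table: pd.DataFrame) -> set:
    """Ortholog ids of genes overlapping any event by at least 1 bp.

    ``gene_table`` needs columns strain, ortholog, start, end (0-based
    half-open). Gene/event intervals touch when gene.start < event.end and
    gene.end > event.start.
    """
    required = {"strain", "ortholog", "start", "end"}
    if not required <= set(gene_table.columns):
        raise ConfigError(f"gene table must have columns {sorted(required)}")
    strains = set(gene_table["strain"])
    out = set()
    for ev in events:
        strain = ev.strain if hasattr(ev, "strain") else ev["strain"]
        s = ev.genome_start if hasattr(ev, "genome_start") else ev["start"]
        e = ev.genome_end if hasattr(ev, "genome_end") else ev["end"]
        if strain not in strains:
            raise MissingDataError(f"no genes annotated for strain {strain!r}")
        g = gene_table[gene_table["strain"] == strain]
        hit = g[(g["start"] < e) & (g["end"] > s)]
        out |= set(hit["ortholog"])
    return out


def category_table(event_orthologs: set, gene_table: pd.DataFrame, category_col="cog") -> pd.DataFrame:
    """Per-category counts of event vs background orthologs.

    Background = annotated orthologs not in any event, so the 2x2 margins are
    disjoint. One row per category with in_events / background counts.
    """
    per_orth = gene_table.drop_duplicates("ortholog").set_index("ortholog")[category_col]
    in_ev = per_orth[per_orth.index.isin(event_orthologs)]
    bg = per_orth[~per_orth.index.isin(event_orthologs)]
    cats = sorted(set(per_orth))
    return pd.DataFrame(
        {
            "category": cats,
            "in_events": [int((in_ev == c).sum()) for c in cats],
            "background": [int((bg == c).sum()) for c in cats],
            "total_in_events": len(in_ev),
            "total_background": len(bg),
        }
    )


def fisher_enrichment(table: pd.DataFrame, alpha=0.05, fdr_q=0.10) -> pd.DataFrame:
    """Two-sided Fisher exact test per category with BH q-values.

    Significance requires p < alpha and q < fdr_q; direction is 'over' when the
    odds ratio of the 2x2 (events x category) exceeds 1, 'under' below 1.
    Zero-margin tables get p = 1 and a degenerate flag.
    """
    rows = []
    for r in table.itertuples():
        a = r.in_events
        b = r.total_in_events - r.in_events
        c = r.background
        d = r.total_background - r.background
        degenerate = (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0)
        if degenerate:
            odds, p = float("nan"), 1.0
        else:
            odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if a * d == b * c:
            direction = "none"
        else:
            direction = "over" if (a * d > b * c) else "under"
        rows.append(
            {
                "category": r.category,
                "in_events": a,
                "background": c,
                "odds": odds,
                "p": p,
                "direction": direction,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["p"] < alpha) & (out["q"] < fdr_q)
    return out


def signed_profile(enrichment: pd.DataFrame) -> pd.Series:
    """-1/0/+1 per category: significant under / none / significant over."""
    sign = np.where(
        enrichment["significant"] & (enrichment["direction"] == "over"),
        1,
        np.where(enrichment["significant"] & (enrichment["direction"] == "under"), -1, 0),
    )
    return pd.Series(sign, index=enrichment["category"].values)


def profile_similarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Matching coefficient between signed species profiles (rows)."""
    vals = profiles.values
    n = len(profiles)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = float((vals[i] == vals[j]).mean())
    return pd.DataFrame(sim, index=profiles.index, columns=profiles.index)


def _linkage_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.get_left(), labels)
    right = _linkage_to_newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.4f},{right}:{node.dist / 2:.4f})"


def cluster_profiles(profiles: pd.DataFrame):
    """Average-linkage clustering of species by signed enrichment profile.

    Rows are species, columns categories, entries in {-1, 0, +1}. Species are
    pre-sorted by label so ties break deterministically. Returns (linkage
    matrix, leaf-ordered labels, newick string, similarity matrix).
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ConfigError("need >=2 species and >=2 categories")
    profiles = profiles.sort_index()
    sim = profile_similarity(profiles)
    dist = 1.0 - sim.values
    condensed = dist[np.triu_indices(len(dist), k=1)]
    Z = hierarchy.average(condensed)
    order = hierarchy.leaves_list(Z)
    labels = list(profiles.index)
    tree = hierarchy.to_tree(Z)
    newick = _linkage_to_newick(tree, labels) + ";"
    ordered = [labels[i] for i in order]
    return Z, ordered, newick, sim
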