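"""Consensus event calling, breakpoint refinement and event characterization.

Per-method hits become a recombination event when hits on the same recombinant
strain overlap reciprocally by at least 50% and at least ``min_methods``
distinct methods support the cluster, every one at corrected p below ``alpha``
(defaults: 3 of 5 methods, alpha = 0.001). A final deterministic cross-strain
merge collapses co-located per-strain events into one event — the reproducible
replacement for manual curation — because a single import is typically flagged
through several observer strains.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .alignio import AlignmentBlock, column_to_genome
from .consensus_util import interval_union_length, reciprocal_overlap
from .detect import ScanSettings, Triplet, scan_all, segment_boundaries
from .errors import ConfigError, MissingDataError, UndefinedStatisticError
from .seqcodes import gc_fraction

log = logging.getLogger(__name__)


@dataclass
class RecombinationEvent:
    """A consensus recombination event on one recombinant strain."""

    strain: str
    donors: tuple
    start_col: int
    end_col: int
    genome_start: int
    genome_end: int
    size: int
    methods: frozenset
    method_p: dict
    gc: float = float("nan")
    candidate_strains: tuple = ()
    refined: bool = False
    flags: tuple = ()
    support: list = field(default_factory=list, repr=False)

    def validate(self, min_methods=3, alpha=0.001):
        assert len(self.methods) >= min_methods
        assert all(p < alpha for p in self.method_p.values())
        assert self.size > 0


def _cluster_intervals(items, get_iv, min_recip=0.5, priority=None):
    """Leader clustering by >=min_recip reciprocal overlap with the leader.

    Items are visited strongest-first (``priority``; default: narrower first
    by start); each joins the first existing leader its interval reciprocally
    overlaps, otherwise it founds a new cluster. Unlike single-link this
    cannot chain unrelated regions together through intermediate wide hits.
    """
    if priority is None:
        priority = lambda it: (get_iv(it)[0], get_iv(it)[1])  # noqa: E731
    order = sorted(items, key=priority)
    leaders = []
    clusters = []
    for it in order:
        iv = get_iv(it)
        for k, leader_iv in enumerate(leaders):
            if reciprocal_overlap(iv, leader_iv) >= min_recip:
                clusters[k].append(it)
                break
        else:
            leaders.append(iv)
            clusters.append([it])
    return clusters


def _event_from_cluster(strain, cluster, block):
    # robust interval: median of supporting starts/ends, so one noisy wide hit
    # cannot inflate the event
    start = int(np.median([h.start_col for h in cluster]))
    end = int(np.median([h.end_col for h in cluster]))
    if end <= start:
        start = min(h.start_col for h in cluster)
        end = max(h.end_col for h in cluster)
    method_p = {}
    for h in cluster:
        method_p[h.method] = min(method_p.get(h.method, 1.0), h.corrected_p)
    best = min(cluster, key=lambda h: h.corrected_p)
    donors = (best.parent_a, best.parent_b)
    if block is not None:
        g0 = column_to_genome(block, strain, start)
        g1 = column_to_genome(block, strain, end - 1) + 1
        genome_start, genome_end = min(g0, g1 - 1), max(g0 + 1, g1)
        row = block.row(strain)[start:end]
        gc = gc_fraction(row)
    else:
        genome_start, genome_end = start, end
        gc = float("nan")
    return RecombinationEvent(
        strain=strain,
        donors=donors,
        start_col=start,
        end_col=end,
        genome_start=genome_start,
        genome_end=genome_end,
        size=genome_end - genome_start,
        methods=frozenset(method_p),
        method_p=method_p,
        gc=gc,
        support=list(cluster),
    )


def attribute_recombinant(event, block: AlignmentBlock) -> str:
    """Pick the strain whose mean identity to the others drops most inside the
    event interval relative to outside (the imported tract makes the true
    recombinant locally distant from every other strain)."""
    from .detect import _codes

    codes, valid = _codes(block)
    s, e = event.start_col, event.end_col
    inside = np.zeros(block.length, dtype=bool)
    inside[s:e] = True
    drops = []
    for i, sid in enumerate(block.strain_ids):
        others = [j for j in range(block.n_strains) if j != i]
        match = (codes[others] == codes[i][None, :]) & valid[others] & valid[i][None, :]
        ok = valid[others] & valid[i][None, :]
        with np.errstate(invalid="ignore"):
            ident_in = match[:, inside].sum() / max(ok[:, inside].sum(), 1)
            ident_out = match[:, ~inside].sum() / max(ok[:, ~inside].sum(), 1)
        drops.append(ident_out - ident_in)
    return block.strain_ids[int(np.argmax(drops))]


def _set_interval(event, start, end, block, strain=None):
    strain = strain or event.strain
    if block is not None:
        g0 = column_to_genome(block, strain, start)
        g1 = column_to_genome(block, strain, end - 1) + 1
        genome_start, genome_end = min(g0, g1 - 1), max(g0 + 1, g1)
        gc = gc_fraction(block.row(strain)[start:end])
    else:
        genome_start, genome_end, gc = start, end, float("nan")
    event.strain = strain
    event.start_col, event.end_col = start, end
    event.genome_start, event.genome_end = genome_start, genome_end
    event.size = genome_end - genome_start
    event.gc = gc
    return event


def call_events(hits, min_methods=3, alpha=0.001, block=None, merge_strains=True, refine=True):
    """Cluster per-method hits into consensus recombination events.

    Hits sharing a recombinant strain are clustered at >=50% reciprocal
    overlap; clusters supported by >= ``min_methods`` distinct methods, all at
    corrected p < ``alpha``, become events. With a block available the
    per-strain events are breakpoint-refined first and then, with
    ``merge_strains``, co-located events are merged into one (a single import
    is usually flagged through several observer strains) and the recombinant
    is re-attributed by local identity drop.
    """
    sig = [h for h in hits if h.corrected_p < alpha]
    by_strain = {}
    for h in sig:
        by_strain.setdefault(h.child, []).append(h)
    events = []
    for strain, shits in sorted(by_strain.items()):
        for cluster in _cluster_intervals(
            shits,
            lambda h: (h.start_col, h.end_col),
            priority=lambda h: (h.corrected_p, h.start_col),
        ):
            # the >=min_methods rule is applied to the merged event below: one
            # import is witnessed through several strains (donor-side,
            # recipient and observers), and the methods split their votes
            # across those roles
            if merge_strains or len({h.method for h in cluster}) >= min_methods:
                events.append(_event_from_cluster(strain, cluster, block))
    if block is not None and refine:
        events = [refine_breakpoints(ev, block) for ev in events]
    if merge_strains and events:
        merged = []
        for cluster in _cluster_intervals(
            events,
            lambda ev: (ev.start_col, ev.end_col),
            priority=lambda ev: (-len(ev.methods), min(ev.method_p.values(), default=1.0)),
        ):
            start = int(np.median([e.start_col for e in cluster]))
            end = int(np.median([e.end_col for e in cluster]))
            if end <= start:
                end = start + 1
            rep = max(cluster, key=lambda e: (len(e.methods), e.strain))
            method_p = {}
            for e in cluster:
                for mname, p in e.method_p.items():
                    method_p[mname] = min(method_p.get(mname, 1.0), p)
            ev = RecombinationEvent(
                strain=rep.strain,
                donors=rep.donors,
                start_col=start,
                end_col=end,
                genome_start=start,
                genome_end=end,
                size=end - start,
                methods=frozenset(method_p),
                method_p=method_p,
                candidate_strains=tuple(sorted({e.strain for e in cluster})),
                refined=any(e.refined for e in cluster),
                support=[h for e in cluster for h in e.support],
            )
            _set_interval(ev, start, end, block)
            if block is not None:
                # triplet methods flag the observer strain, not the recombinant;
                # re-attribute by the local identity drop of the imported tract
                who = attribute_recombinant(ev, block)
                if who != ev.strain:
                    _set_interval(ev, start, end, block, strain=who)
                    ev.flags = ev.flags + ("reattributed",)
            merged.append(ev)
        events = [ev for ev in merged if len(ev.methods) >= min_methods]
    events.sort(key=lambda ev: (ev.start_col, ev.strain))
    log.info("call_events: %d significant hits -> %d events", len(sig), len(events))
    return events


def refine_breakpoints(event: RecombinationEvent, block: AlignmentBlock) -> RecombinationEvent:
    """Re-run the MaxChi breakpoint maximization inside the padded event
    interval (pad = 10% of the interval on each side) and replace the event
    boundaries with the two argmax breakpoints. Refinement is a fixpoint:
    refining an already refined event returns it unchanged."""
    if event.refined:
        return event
    chi_hits = [h for h in event.support if h.method in ("MAXCHI", "CHIMAERA") and h.parent_b]
    if not chi_hits:
        # RDP/GENECONV/3Seq intervals are already run-delimited; nothing to
        # re-maximize with the breakpoint machinery
        event.flags = event.flags + ("unrefined",)
        event.refined = True
        return event
    best = min(chi_hits, key=lambda h: h.corrected_p)
    trip = Triplet(block, best.child, best.parent_a, best.parent_b)
    if best.method == "CHIMAERA":
        from .detect import chimaera_sites

        sites, indicator = chimaera_sites(trip)
    else:
        sites, indicator = trip.sites, trip.match_a
    pad = max(1, int(0.1 * (event.end_col - event.start_col)))
    lo, hi = max(0, event.start_col - pad), min(block.length, event.end_col + pad)
    mask = (sites >= lo) & (sites < hi)
    x_local = indicator[mask].astype(np.int64)
    if mask.sum() < 3 or x_local.sum() in (0, len(x_local)):
        event.flags = event.flags + ("unrefined",)
        event.refined = True
        return event
    xfull = indicator.astype(np.int64)
    bounds = segment_boundaries(xfull)
    # take the change-point segment overlapping the event most
    best_seg, best_ov = None, 0
    for i, j in zip(bounds[:-1], bounds[1:]):
        s_col, e_col = int(sites[i]), int(sites[j - 1]) + 1
        ov = min(e_col, event.end_col) - max(s_col, event.start_col)
        if ov > best_ov:
            best_ov, best_seg = ov, (i, j)
    if best_seg is None:
        event.flags = event.flags + ("unrefined",)
        event.refined = True
        return event
    i, j = best_seg
    start, end = int(sites[i]), int(sites[j - 1]) + 1
    if reciprocal_overlap((start, end), (event.start_col, event.end_col)) < 0.33:
        # the breakpoint maximization wandered off the supported region:
        # keep the consensus interval
        event.flags = event.flags + ("unrefined",)
        event.refined = True
        return event
    g0 = column_to_genome(block, event.strain, start)
    g1 = column_to_genome(block, event.strain, end - 1) + 1
    return RecombinationEvent(
        strain=event.strain,
        donors=event.donors,
        start_col=start,
        end_col=end,
        genome_start=min(g0, g1 - 1),
        genome_end=max(g0 + 1, g1),
        size=max(g1, g0 + 1) - min(g0, g1 - 1),
        methods=event.methods,
        method_p=event.method_p,
        gc=gc_fraction(block.row(event.strain)[start:end]),
        candidate_strains=event.candidate_strains,
        refined=True,
        flags=event.flags,
        support=event.support,
    )


SIZE_BINS = ((0, 2_000), (2_000, 10_000), (10_000, 80_000), (80_000, float("inf")))
SIZE_BIN_LABELS = ("<2kb", "2-10kb", "10-80kb", ">80kb")


@dataclass
class SpeciesSummary:
    n_events: int
    events_per_strain: float
    fraction_genome_recombined: float
    fraction_genome_recombined_strain_mean: float
    size_histogram: dict
    gc_events: float
    gc_genome: float
    per_strain_events: dict


def summarize_species(events, block: AlignmentBlock) -> SpeciesSummary:
    """Events/strain, % of core alignment recombined (union over strains; the
    per-strain mean is also reported), size histogram and GC contrast."""
    if block is None or block.length == 0:
        raise UndefinedStatisticError("cannot summarize an empty alignment")
    n = len(events)
    union_cols = interval_union_length([(ev.start_col, ev.end_col) for ev in events])
    per_strain_cols = {}
    per_strain_counts = {s: 0 for s in block.strain_ids}
    for ev in events:
        per_strain_cols.setdefault(ev.strain, []).append((ev.start_col, ev.end_col))
        per_strain_counts[ev.strain] = per_strain_counts.get(ev.strain, 0) + 1
    strain_fracs = [
        interval_union_length(per_strain_cols.get(s, [])) / block.length for s in block.strain_ids
    ]
    hist = {label: 0 for label in SIZE_BIN_LABELS}
    for ev in events:
        for (lo, hi), label in zip(SIZE_BINS, SIZE_BIN_LABELS):
            if lo <= ev.size < hi or (hi == float("inf") and ev.size >= lo):
                hist[label] += 1
                break
    gc_events = float(np.mean([ev.gc for ev in events])) if events else float("nan")
    gc_genome = float(np.mean([gc_fraction(r) for r in block.rows]))
    return SpeciesSummary(
        n_events=n,
        events_per_strain=n / block.n_strains,
        fraction_genome_recombined=100.0 * union_cols / block.length,
        fraction_genome_recombined_strain_mean=100.0 * float(np.mean(strain_fracs)),
        size_histogram=hist,
        gc_events=gc_events,
        gc_genome=gc_genome,
        per_strain_events=per_strain_counts,
    )


def gc_compare(events, block: AlignmentBlock, n_background=20, seed=None):
    """Per-event GC versus matched-length random background windows (drawn from
    the same strain's row); two-sided Mann-Whitney rank test."""
    if not events:
        raise MissingDataError("gc_compare requires at least one event")
    rng = np.random.default_rng(seed)
    ev_gc = [ev.gc for ev in events]
    bg_gc = []
    for ev in events:
        length = max(1, ev.end_col - ev.start_col)
        row = block.row(ev.strain)
        hi = block.length - length
        if hi <= 0:
            bg_gc.append(gc_fraction(row))
            continue
        for _ in range(n_background):
            s = int(rng.integers(0, hi + 1))
            bg_gc.append(gc_fraction(row[s : s + length]))
    if len(set(ev_gc)) == 1 and len(set(bg_gc)) == 1 and ev_gc[0] == bg_gc[0]:
        return float(np.mean(ev_gc)), float(np.mean(bg_gc)), 1.0
    stat_p = mannwhitneyu(ev_gc, bg_gc, alternative="two-sided")
    return float(np.mean(ev_gc)), float(np.mean(bg_gc)), float(stat_p.pvalue)


def rarefaction(
    block: AlignmentBlock,
    subset_sizes,
    n_draws=5,
    seed=None,
    settings: ScanSettings | None = None,
    min_methods=3,
    alpha=0.001,
):
    """Mean (sd) consensus event count over random strain subsets of each size.

    Deterministic given the seed; a subset of the full strain panel is re-scanned
    with the same settings as the full analysis.
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    for size in subset_sizes:
        if size < 3 or size > block.n_strains:
            raise ConfigError(f"subset size {size} outside [3, n_strains]")
        counts = []
        for _ in range(n_draws):
            chosen = sorted(rng.choice(block.n_strains, size=size, replace=False))
            sub = AlignmentBlock(
                [block.strain_ids[i] for i in chosen],
                block.rows[chosen],
                {block.strain_ids[i]: block.anchors[block.strain_ids[i]] for i in chosen},
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            hits = scan_all(sub, settings=settings, seed=sub_seed)
            events = call_events(hits, min_methods=min_methods, alpha=alpha, block=sub)
            counts.append(len(events))
        rows.append(
            {
                "subset_size": size,
                "mean_events": float(np.mean(counts)),
                "sd_events": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
                "n_draws": n_draws,
            }
        )
    return pd.DataFrame(rows)
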