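"""Simulation benchmarks for the pipeline: recovery, calibration, estimators.

Each function re-runs the full machinery on freshly simulated data under the
study conditions and returns plain dictionaries of measured quantities. The
acceptance script and the acceptance test suite both call these, so the
numbers they report are always recomputed from scratch.

Problem sizes: planted-event recovery uses the full benchmark conditions
(8 strains, 100 kb); null calibration and the rate-estimator grid run on
6-strain, 30 kb genomes so that 50-60 replicates complete in minutes on one
core. The enrichment and path-analysis benchmarks need no detection step.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import ani, consensus, detect, enrich, simdata, stats
from .consensus_util import reciprocal_overlap
from .evol import estimate_recomb_params


def _subseed(seed, tag, i):
    return int(np.random.SeedSequence(entropy=(seed, tag, i)).generate_state(1)[0] % (2**31 - 1))


def planted_recovery(
    n_reps=20,
    seed=0,
    n_strains=8,
    genome_length=100_000,
    event_rate=1.0,
    tract_mean=2_000.0,
    donor_divergence=0.08,
    mutation_rate=0.01,
):
    """Sensitivity / PPV of consensus calling against the truth registry, and
    the median refined-breakpoint error of matched events.

    An event matches a planted tract at >= 50% reciprocal overlap.
    """
    tp = fn = fp = 0
    bp_errors = []
    for i in range(n_reps):
        cfg = simdata.SimConfig(
            n_strains=n_strains,
            genome_length=genome_length,
            event_rate=event_rate,
            tract_mean=tract_mean,
            donor_divergence=donor_divergence,
            mutation_rate=mutation_rate,
            seed=_subseed(seed, 4, i),
        )
        block, truth = simdata.evolve_alignment(cfg)
        hits = detect.scan_all(block, seed=_subseed(seed, 40, i))
        events = consensus.call_events(hits, block=block)
        for t in truth.events:
            t_iv = (t["start"], t["end"])
            matched = [
                ev for ev in events
                if reciprocal_overlap(t_iv, (ev.start_col, ev.end_col)) >= 0.5
            ]
            if matched:
                tp += 1
                best = max(
                    matched, key=lambda ev: reciprocal_overlap(t_iv, (ev.start_col, ev.end_col))
                )
                bp_errors.append(abs(best.start_col - t["start"]))
                bp_errors.append(abs(best.end_col - t["end"]))
            else:
                fn += 1
        for ev in events:
            if not any(
                reciprocal_overlap((t["start"], t["end"]), (ev.start_col, ev.end_col)) >= 0.5
                for t in truth.events
            ):
                fp += 1
    n_called = tp + fp
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "ppv": tp / max(n_called, 1),
        "breakpoint_error_bp_median": float(np.median(bp_errors)) if bp_errors else float("nan"),
        "n_truth": tp + fn,
        "n_called": n_called,
        "n_reps": n_reps,
    }


def null_calibration(n_reps=50, seed=0, n_strains=6, genome_length=30_000, alpha=0.001):
    """False consensus events under lambda = 0 (no recombination).

    With corrected p < alpha per supporting method and >= 3/5 methods the
    expected false-event count per replicate is far below alpha; the nominal
    bound reported here is alpha x methods x replicates.
    """
    false_events = 0
    for i in range(n_reps):
        cfg = simdata.SimConfig(
            n_strains=n_strains,
            genome_length=genome_length,
            event_rate=0.0,
            seed=_subseed(seed, 3, i),
        )
        block, _ = simdata.evolve_alignment(cfg)
        hits = detect.scan_all(block, seed=_subseed(seed, 30, i))
        events = consensus.call_events(hits, alpha=alpha, block=block)
        false_events += len(events)
    return {
        "false_events_total": false_events,
        "false_events_per_rep": false_events / n_reps,
        "nominal_bound_total": alpha * len(detect.METHODS) * n_reps,
        "n_reps": n_reps,
    }


def rate_estimator_grid(
    seed=0,
    reps_per_level=20,
    lambdas=(0.2, 1.0, 4.0),
    n_strains=6,
    genome_length=30_000,
    tract_mean=1_500.0,
):
    """Recovery of rho/theta across an event-rate grid.

    Returns the Spearman rank correlation between the realized true
    events-per-clonal-mutation ratio and the moment estimate from detected
    events, plus the largest absolute violation of the r/m identity
    r/m = (rho/theta) * delta_hat * nu_hat across all runs.
    """
    true_vals, est_vals = [], []
    identity_dev = 0.0
    for li, lam in enumerate(lambdas):
        for i in range(reps_per_level):
            cfg = simdata.SimConfig(
                n_strains=n_strains,
                genome_length=genome_length,
                event_rate=lam,
                tract_mean=tract_mean,
                seed=_subseed(seed, 50 + li, i),
            )
            block, truth = simdata.evolve_alignment(cfg)
            hits = detect.scan_all(block, seed=_subseed(seed, 60 + li, i))
            events = consensus.call_events(hits, block=block)
            params = estimate_recomb_params(block, events)
            true_vals.append(len(truth.events) / max(truth.n_clonal_mutations, 1))
            est_vals.append(params.rho_theta)
            if np.isfinite(params.r_m) and events:
                identity_dev = max(
                    identity_dev,
                    abs(params.r_m - params.rho_theta * params.delta_hat * params.nu_hat),
                )
    rho = spearmanr(true_vals, est_vals).statistic
    return {
        "spearman_rho_theta": float(rho),
        "rm_identity_max_abs_dev": float(identity_dev),
        "n_runs": len(true_vals),
    }


def enrichment_benchmark(n_reps=50, seed=0, odds=5.0, n_strains=6, genome_length=400_000, event_rate=12.0):
    """Power to flag the focal category 'over' with planted odds, and the
    false-flag rate under odds = 1, using the truth registry as the event set
    (the enrichment statistics are the subject, not the detector)."""
    power_hits = power_total = 0
    null_rates = []
    for i in range(n_reps):
        for planted, tag in ((True, 6), (False, 66)):
            cfg = simdata.SimConfig(
                n_strains=n_strains,
                genome_length=genome_length,
                event_rate=event_rate,
                enrichment_odds=odds if planted else 1.0,
                seed=_subseed(seed, tag, i),
            )
            block, truth = simdata.evolve_alignment(cfg)
            if not truth.events:
                continue
            rng = np.random.default_rng(_subseed(seed, tag + 1, i))
            genes = simdata.make_gene_table(block, truth, cfg, rng)
            ev = [
                {"strain": t["strains"][0], "start": t["start"], "end": t["end"]}
                for t in truth.events
            ]
            hit = enrich.genes_in_events(ev, genes)
            out = enrich.fisher_enrichment(enrich.category_table(hit, genes))
            if planted:
                power_total += 1
                row = out[out["category"] == cfg.focal_category]
                if len(row) and bool(row["significant"].iloc[0]) and row["direction"].iloc[0] == "over":
                    power_hits += 1
            else:
                null_rates.append(float(out["significant"].mean()))
    return {
        "planted_over_rate": power_hits / max(power_total, 1),
        "null_flag_rate": float(np.mean(null_rates)) if null_rates else 0.0,
        "n_reps": n_reps,
    }


def path_benchmark(n_reps=50, seed=0, n=200, a=0.6, b=0.5):
    """Indirect-effect recovery on the X -> M -> Y chain and the single-edge
    coefficient = Pearson r identity."""
    rng = np.random.default_rng(seed)
    indirect = []
    single_edge_dev = 0.0
    for _ in range(n_reps):
        x = rng.normal(size=n)
        m = a * x + np.sqrt(1 - a**2) * rng.normal(size=n)
        y = b * m + np.sqrt(1 - b**2) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        fit = stats.path_analysis(df, [("x", "m"), ("m", "y")])
        indirect.append(fit["effects"][("x", "y")]["indirect"])
        fit1 = stats.path_analysis(df[["x", "y"]], [("x", "y")])
        r = np.corrcoef(x, y)[0, 1]
        single_edge_dev = max(single_edge_dev, abs(fit1["coefficients"][("x", "y")] - r))
    arr = np.array(indirect)
    return {
        "indirect_mean": float(arr.mean()),
        "indirect_se": float(arr.std(ddof=1) / np.sqrt(len(arr))),
        "true_indirect": a * b,
        "single_edge_max_abs_dev_from_r": float(single_edge_dev),
        "n_reps": n_reps,
    }


def anib_reference_fixtures():
    """Hand-derivable coordinate fixtures exercising the join and containment
    rules; returns the computed and expected ANIb values."""
    F = ani.Fragment
    cases = {
        # single fragment
        "single": ([F(1, 500, 95.0)], 95.0),
        # disjoint size weighting: (100*90 + 300*98)/400
        "weighted": ([F(1, 100, 90.0), F(201, 500, 98.0)], 96.0),
        # containment: inner fragment removed
        "containment": ([F(1, 1000, 95.0), F(200, 300, 40.0)], 95.0),
        # join: overlap 101 > 10% of 301 -> one fragment, weighted identity
        "join": ([F(1, 1000, 95.0), F(900, 1200, 99.0)], (1000 * 95 + 301 * 99) / 1301),
        # sub-threshold overlap: overlap 6 <= 10% of 306 -> kept apart
        "no_join": (
            [F(1, 1000, 95.0), F(995, 1300, 99.0)],
            (1000 * 95 + 306 * 99) / 1306,
        ),
        # containment then join
        "mixed": (
            [F(1, 1000, 95.0), F(200, 300, 40.0), F(900, 1200, 99.0)],
            (1000 * 95 + 301 * 99) / 1301,
        ),
    }
    out = {}
    for name, (frags, expected) in cases.items():
        out[name] = {"computed": ani.anib(frags), "expected": expected}
    return out
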