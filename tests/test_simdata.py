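"""Simulator: coalescent expectations, truth bookkeeping, fixture round trips."""
import numpy as np
import pytest
from scipy.stats import chi2_contingency

from hrscan import simdata
from hrscan.alignio import read_xmfa
from hrscan.errors import ConfigError
from hrscan.simdata import SimConfig, emit_coords_fixture, evolve_alignment, simulate_genealogy


class TestGenealogy:
    def test_three_strains_forced_topology(self):
        tree = simulate_genealogy(3, seed=0)
        assert tree.n_internal() == 2
        assert len(tree.leaves()) == 3

    def test_too_few_strains(self):
        with pytest.raises(ConfigError):
            simulate_genealogy(2)

    def test_determinism(self):
        assert simulate_genealogy(6, seed=7).newick() == simulate_genealogy(6, seed=7).newick()

    def test_mean_total_branch_length_matches_coalescent(self):
        """E[total length] = 2 * sum_{k=1}^{n-1} 1/k for the Kingman coalescent."""
        n = 10
        rng = np.random.default_rng(77)
        totals = [
            simulate_genealogy(n, rng).total_branch_length() for _ in range(1000)
        ]
        expected = 2 * sum(1 / k for k in range(1, n))
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se


class TestEvolveAlignment:
    def test_no_recombination_clean_truth(self):
        cfg = SimConfig(n_strains=4, genome_length=5000, event_rate=0.0, seed=1)
        _, truth = evolve_alignment(cfg)
        assert truth.events == []
        assert not truth.origin_mask.any()

    def test_no_mutation_no_recombination_identical(self):
        cfg = SimConfig(n_strains=4, genome_length=3000, mutation_rate=0.0, event_rate=0.0, seed=2)
        block, _ = evolve_alignment(cfg)
        assert all(np.array_equal(block.rows[0], r) for r in block.rows)

    def test_determinism_byte_identical(self):
        cfg = SimConfig(n_strains=5, genome_length=8000, seed=33)
        b1, t1 = evolve_alignment(cfg)
        b2, t2 = evolve_alignment(cfg)
        assert np.array_equal(b1.rows, b2.rows)
        assert t1.events == t2.events
        assert t1.genealogy.newick() == t2.genealogy.newick()

    def test_clonal_mutation_count_poisson_expectation(self):
        """Total mutation draws across replicates match mu*L*sum(T_i)."""
        mu, L = 0.01, 50_000
        observed, expected_total = 0, 0.0
        for seed in range(50):
            cfg = SimConfig(n_strains=8, genome_length=L, mutation_rate=mu, event_rate=0.0, seed=seed)
            _, truth = evolve_alignment(cfg)
            observed += truth.n_clonal_mutations
            expected_total += mu * L * truth.genealogy.total_branch_length()
        sd = np.sqrt(expected_total)  # Poisson
        assert abs(observed - expected_total) < 3 * sd

    def test_conservation_mask_shape(self, small_sim):
        cfg, block, truth = small_sim
        assert truth.origin_mask.shape == (cfg.n_strains, cfg.genome_length)
        # every site is either clonal or imported; nothing else to conserve
        assert truth.origin_mask.dtype == bool

    def test_event_rate_scaling(self):
        """Doubling lambda doubles the expected import count."""
        counts = {}
        for lam in (0.5, 1.0):
            n = 0
            for seed in range(100):
                cfg = SimConfig(n_strains=5, genome_length=2000, event_rate=lam, seed=10_000 + seed)
                _, truth = evolve_alignment(cfg)
                n += len(truth.events)
            counts[lam] = n
        ratio = counts[1.0] / max(counts[0.5], 1)
        assert 1.6 < ratio < 2.5

    def test_tracts_more_divergent_than_background(self):
        cfg = SimConfig(n_strains=6, genome_length=40_000, event_rate=1.0, seed=5)
        block, truth = evolve_alignment(cfg)
        if not truth.events:
            pytest.skip("no events drawn at this seed")
        diffs = block.rows[:, None, :, ] != block.rows[None, :, :]
        pair_diff = diffs[np.triu_indices(cfg.n_strains, 1)].mean(axis=0)
        inside = truth.origin_mask.any(axis=0)
        assert pair_diff[inside].mean() > pair_diff[~inside].mean()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_strains=2)
        with pytest.raises(ConfigError):
            SimConfig(donor_divergence=0.9)
        with pytest.raises(ConfigError):
            SimConfig(tract_mean=0.5)
        with pytest.raises(ConfigError):
            SimConfig(mutation_rate=-1e-3)


class TestFixtures:
    def test_emit_round_trip_and_truth_rows(self, small_sim, tmp_path):
        cfg, block, truth = small_sim
        paths = simdata.emit_fixtures(block, truth, cfg, tmp_path)
        back = read_xmfa(paths["xmfa"])
        assert len(back) == 1
        assert np.array_equal(back[0].rows, block.rows)
        import pandas as pd

        tt = pd.read_csv(paths["truth"], sep="\t", comment="#")
        assert len(tt) == len(truth.events)
        genes = pd.read_csv(paths["genes"], sep="\t", comment="#")
        assert set(genes["strain"]) == set(block.strain_ids)

    def test_fixture_bytes_deterministic(self, small_sim, tmp_path):
        cfg, block, truth = small_sim
        p1 = simdata.emit_fixtures(block, truth, cfg, tmp_path / "a")
        p2 = simdata.emit_fixtures(block, truth, cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_neutral_category_assignment_independent(self):
        """With w=1, gene category is independent of event overlap."""
        sig = 0
        tested = 0
        for seed in range(40):
            cfg = SimConfig(n_strains=5, genome_length=50_000, event_rate=2.0,
                            enrichment_odds=1.0, seed=500 + seed)
            block, truth = evolve_alignment(cfg)
            if not truth.events:
                continue
            rng = np.random.default_rng(seed)
            genes = simdata.make_gene_table(block, truth, cfg, rng)
            one = genes[genes["strain"] == block.strain_ids[0]]
            in_ev = one.apply(
                lambda g: any(t["start"] < g["end"] and t["end"] > g["start"] for t in truth.events),
                axis=1,
            )
            focal = one["cog"] == cfg.focal_category
            table = np.array(
                [[int((in_ev & focal).sum()), int((in_ev & ~focal).sum())],
                 [int((~in_ev & focal).sum()), int((~in_ev & ~focal).sum())]]
            )
            if (table.sum(0) > 0).all() and (table.sum(1) > 0).all():
                tested += 1
                sig += chi2_contingency(table)[1] < 0.01
        assert tested >= 20
        assert sig <= max(2, 0.05 * tested)


class TestCoordsFixture:
    def test_disjoint_no_overlap(self):
        df = emit_coords_fixture(5, "disjoint", seed=3)
        iv = sorted(zip(df["ref_start"], df["ref_end"]))
        assert all(b1 < a2 for (_, b1), (a2, _) in zip(iv, iv[1:]))

    def test_containment_directive(self):
        df = emit_coords_fixture(3, "contained(1 in 0)", seed=3)
        assert df["ref_start"][0] < df["ref_start"][1] <= df["ref_end"][1] < df["ref_end"][0]

    def test_same_seed_same_bytes(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        emit_coords_fixture(4, "disjoint", seed=11, path=a)
        emit_coords_fixture(4, "disjoint", seed=11, path=b)
        assert a.read_bytes() == b.read_bytes()

    def test_contradictory_spec(self):
        with pytest.raises(ConfigError):
            emit_coords_fixture(2, "contained(0 in 0)", seed=0)
        with pytest.raises(ConfigError):
            emit_coords_fixture(2, "frobnicate", seed=0)


class TestSpeciesTable:
    def test_shape_and_lifestyle_levels(self):
        df = simdata.simulate_species_table(54, seed=1)
        assert len(df) == 54
        assert set(df["lifestyle"]) <= {
            "endosymbiont", "obligate_pathogen", "commensal_free_living", "opportunistic_pathogen",
        }

    def test_trend_induces_lifestyle_gradient(self):
        df = simdata.simulate_species_table(200, seed=2, trend=1.5)
        med = df.groupby("lifestyle")["events_per_strain"].median()
        assert med["opportunistic_pathogen"] > med["endosymbiont"]
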