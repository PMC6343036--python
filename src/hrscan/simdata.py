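"""Synthetic core-genome evolution with recorded recombination ground truth.

The generator emulates the data the recombination estimators assume: a clonal
genealogy (neutral Kingman coalescent), Jukes-Cantor-style point mutations
along branches, and homologous imports whose donor is a contemporaneous
lineage of the same genealogy — intraspecific exchange, the process the
detection statistics are built for — with fresh per-site divergence ``nu``
added to each copied tract (the sampled donor lineage stands in for the true,
unsampled donor). Tract lengths are geometric with mean ``delta``, truncated
at the linear chromosome end with the realized length recorded. All randomness
flows from one seed via deterministically spawned sub-streams, so identical
configs give byte-identical outputs.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .alignio import AlignmentBlock, write_fasta, write_xmfa
from .errors import ConfigError
from .seqcodes import rows_from_strings

BASES = np.frombuffer(b"ACGT", dtype="S1")

COG_LETTERS = list("CEGJKLMNOPTV")  # condensed single-letter functional classes


@dataclass
class SimConfig:
    """Parameters of one simulated species.

    mutation_rate (mu) and event_rate (lambda) are per unit branch length on the
    coalescent time scale: expected clonal substitutions are mu * L * total
    branch length, expected imports are lambda * total branch length. The
    default mu of 0.01 corresponds to ~2% expected pairwise core diversity
    (E[pairwise coalescence time] = 1), the scale seen in recombinogenic
    enterobacteria. donor_divergence (nu) is the extra per-site substitution
    probability applied to an imported tract on top of the sampled donor
    lineage's sequence. enrichment_odds (w) biases the functional category of
    genes that overlap planted events when fixtures are emitted (w = 1: none).
    """

    n_strains: int = 8
    genome_length: int = 100_000
    mutation_rate: float = 0.01
    event_rate: float = 1.0
    tract_mean: float = 2_000.0
    donor_divergence: float = 0.08
    enrichment_odds: float = 1.0
    focal_category: str = "V"
    gene_length: int = 900
    gene_spacing: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.n_strains < 3:
            raise ConfigError("n_strains must be >= 3")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be > 0")
        if self.mutation_rate < 0 or self.event_rate < 0:
            raise ConfigError("rates must be >= 0")
        if not 0 <= self.donor_divergence <= 0.75:
            raise ConfigError("donor_divergence must be in [0, 0.75]")
        if self.tract_mean < 1:
            raise ConfigError("tract_mean must be >= 1")
        if self.enrichment_odds <= 0:
            raise ConfigError("enrichment_odds must be > 0")


@dataclass
class TreeNode:
    """Node of the clonal genealogy; ``blen`` is the branch to the parent."""

    label: str
    blen: float = 0.0
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.blen:.6f}"
        inner = ",".join(c._nwk() for c in self.children)
        return f"({inner}):{self.blen:.6f}"

    def total_branch_length(self) -> float:
        return sum(n.blen for n in self.walk() if n.blen)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def n_internal(self) -> int:
        return sum(1 for n in self.walk() if not n.is_leaf)


@dataclass
class SimTruth:
    """Ground-truth registry for one simulated alignment.

    events: list of dicts with the carrier strain set, tract coordinates
    (0-based half-open), realized length and donor divergence.
    origin_mask: (n_strains, L) boolean, True where the site descends from an
    imported tract.
    """

    events: list
    origin_mask: np.ndarray
    n_clonal_mutations: int
    genealogy: TreeNode

    def validate(self, genome_length: int):
        for ev in self.events:
            assert 0 <= ev["start"] < ev["end"] <= genome_length
        assert self.origin_mask.dtype == bool


def simulate_genealogy(n_strains: int, seed=None) -> TreeNode:
    """Sample a Kingman coalescent tree: with k active lineages the waiting
    time to the next coalescence is exponential with rate k(k-1)/2."""
    if n_strains < 3:
        raise ConfigError("n_strains must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = [TreeNode(f"strain_{i:02d}") for i in range(n_strains)]
    depth = {id(n): 0.0 for n in active}
    t = 0.0
    counter = itertools.count()
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        a.blen = t - depth[id(a)]
        b.blen = t - depth[id(b)]
        parent = TreeNode(f"node_{next(counter)}", children=[a, b])
        depth[id(parent)] = t
        active.append(parent)
    return active[0]


def evolve_alignment(config: SimConfig):
    """Evolve sequences down the genealogy; return (AlignmentBlock, SimTruth).

    The ancestral sequence is uniform over {A,C,G,T}. On every branch the number
    of substitutions is Poisson(mu * blen * L) at uniformly chosen sites (random
    different target base) and the number of recombination imports is
    Poisson(lambda * blen) at uniform times along the branch. Each import has a
    uniform start and geometric(mean delta) length truncated at the chromosome
    end. The donor is a contemporaneous lineage of the same clonal genealogy —
    intraspecific exchange, which creates the phylogenetic incongruence the
    detection statistics test for — and the copied tract additionally receives
    fresh per-site substitutions with probability nu (the sampled donor lineage
    stands in for the true, unsampled donor at divergence nu). Donor state is
    taken as the donor branch's clonal sequence at its lower endpoint, and
    within a branch mutations are applied before imports; both simplifications
    keep the truth registry exact.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_rng, evo_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    tree = simulate_genealogy(config.n_strains, tree_rng)
    L = config.genome_length

    # node depths measured from the root (leaves are contemporaneous)
    depth = {id(tree): 0.0}
    order = []  # preorder, root first
    stack = [tree]
    while stack:
        node = stack.pop()
        order.append(node)
        for c in node.children:
            depth[id(c)] = depth[id(node)] + c.blen
            stack.append(c)

    # clonal pass: per-branch mutation draws and clonal sequences
    root_seq = evo_rng.integers(0, 4, size=L, dtype=np.uint8)
    clonal = {id(tree): root_seq}
    mut_records = {}
    n_mut = 0
    for node in order:
        if node is tree:
            continue
        k = evo_rng.poisson(config.mutation_rate * node.blen * L)
        sites = evo_rng.integers(0, L, size=k)
        bases = np.empty(k, dtype=np.uint8)
        parent_seq = clonal[_parent_id(order, node)]
        seq = parent_seq.copy()
        if k:
            bases[:] = (seq[sites] + 1 + evo_rng.integers(0, 3, size=k)) % 4
            seq[sites] = bases
        clonal[id(node)] = seq
        mut_records[id(node)] = (sites, bases)
        n_mut += int(k)

    # import draws: recipient branch, time, tract, donor lineage alive then
    branches = [n for n in order if n is not tree]
    events = []
    imports = {id(n): [] for n in branches}
    for node in branches:
        t_top = depth[id(node)] - node.blen
        n_imp = evo_rng.poisson(config.event_rate * node.blen)
        for _ in range(n_imp):
            tau = t_top + evo_rng.random() * node.blen
            start = int(evo_rng.integers(0, L))
            length = int(evo_rng.geometric(1.0 / config.tract_mean))
            end = min(L, start + length)
            alive = [
                b
                for b in branches
                if b is not node and depth[id(b)] - b.blen < tau <= depth[id(b)] + 1e-12
            ]
            if not alive:
                continue
            donor = alive[int(evo_rng.integers(0, len(alive)))]
            tract = clonal[id(donor)][start:end].copy()
            hitmask = evo_rng.random(end - start) < config.donor_divergence
            nh = int(hitmask.sum())
            if nh:
                tract[hitmask] = (tract[hitmask] + 1 + evo_rng.integers(0, 3, size=nh)) % 4
            imports[id(node)].append((tau, start, end, tract))
            events.append(
                {
                    "strains": tuple(sorted(lf.label for lf in node.leaves())),
                    "donor": donor.label,
                    "time": tau,
                    "start": start,
                    "end": end,
                    "length": end - start,
                    "nu": config.donor_divergence,
                }
            )

    # final pass: inherit, replay mutations, then imports in time order
    leaf_seqs, leaf_masks = {}, {}

    def descend(node, seq, mask):
        seq = seq.copy()
        mask = mask.copy()
        if node is not tree:
            sites, bases = mut_records[id(node)]
            if len(sites):
                seq[sites] = bases
            for _, start, end, tract in sorted(imports[id(node)], key=lambda r: r[0]):
                seq[start:end] = tract
                mask[start:end] = True
        if node.is_leaf:
            leaf_seqs[node.label] = seq
            leaf_masks[node.label] = mask
        else:
            for c in node.children:
                descend(c, seq, mask)

    descend(tree, root_seq, np.zeros(L, dtype=bool))

    strain_ids = sorted(leaf_seqs)
    rows = np.array([BASES[leaf_seqs[s]] for s in strain_ids])
    mask = np.array([leaf_masks[s] for s in strain_ids])
    block = AlignmentBlock(strain_ids, rows, {s: (0, L, "+") for s in strain_ids})
    truth = SimTruth(events, mask, n_mut, tree)
    truth.validate(L)
    return block, truth


def _parent_id(order, node):
    for cand in order:
        if node in cand.children:
            return id(cand)
    raise RuntimeError("node has no parent")


def _provenance(config: SimConfig) -> str:
    return f"hrscan v{__version__} simdata seed={config.seed}"


def assign_gene_categories(genes: pd.DataFrame, truth: SimTruth, config: SimConfig, rng):
    """Draw a COG letter per gene; genes overlapping a planted event get the
    focal category with odds multiplied by ``enrichment_odds``."""
    cats = sorted(set(COG_LETTERS) | {config.focal_category})
    base = np.ones(len(cats))
    boosted = base.copy()
    boosted[cats.index(config.focal_category)] *= config.enrichment_odds
    out = []
    for _, g in genes.iterrows():
        in_event = any(ev["start"] < g["end"] and ev["end"] > g["start"] for ev in truth.events)
        w = boosted if in_event else base
        out.append(rng.choice(cats, p=w / w.sum()))
    return out


def make_gene_table(block: AlignmentBlock, truth: SimTruth, config: SimConfig, rng) -> pd.DataFrame:
    """Tile genes at fixed spacing along the (gapless) simulated chromosome and
    annotate them with COG letters and synthetic GO terms."""
    L = config.genome_length
    starts = np.arange(0, max(L - config.gene_length, 1), config.gene_spacing)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(len(starts))],
            "start": starts,
            "end": np.minimum(starts + config.gene_length, L),
        }
    )
    genes["cog"] = assign_gene_categories(genes, truth, config, rng)
    genes["go"] = [f"GO:{7000000 + i:07d}" for i in range(len(genes))]
    rows = []
    for strain in block.strain_ids:
        g = genes.copy()
        g.insert(0, "strain", strain)
        g["ortholog"] = g["gene_id"]
        rows.append(g)
    return pd.concat(rows, ignore_index=True)


def make_metadata_table(config: SimConfig, rng) -> pd.DataFrame:
    """One-row species metadata fixture (lifestyle, defense and competence
    gene counts), with columns matching the downstream SpeciesTable."""
    lifestyles = [
        "endosymbiont",
        "obligate_pathogen",
        "commensal_free_living",
        "opportunistic_pathogen",
    ]
    return pd.DataFrame(
        [
            {
                "species": f"sim_{config.seed}",
                "lifestyle": lifestyles[int(rng.integers(0, 4))],
                "competence": int(rng.integers(0, 2)),
                "rm_type_I": int(rng.poisson(2)),
                "rm_type_II": int(rng.poisson(3)),
                "rm_type_III": int(rng.poisson(1)),
                "crispr_diversity": float(np.round(rng.random(), 3)),
                "com_genes": int(rng.poisson(5)),
                "hgt_fraction": float(np.round(rng.random() * 0.2, 4)),
            }
        ]
    )


def truth_table(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strains": ";".join(ev["strains"]),
                "start": ev["start"],
                "end": ev["end"],
                "length": ev["length"],
                "nu": ev["nu"],
            }
            for ev in truth.events
        ],
        columns=["strains", "start", "end", "length", "nu"],
    )


def _write_tsv(df: pd.DataFrame, path, provenance: str):
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def emit_fixtures(block: AlignmentBlock, truth: SimTruth, config: SimConfig, outdir):
    """Write XMFA, aligned FASTA, truth/gene/metadata TSVs; returns the paths."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    fix_rng = np.random.default_rng(ss.spawn(3)[2])
    prov = _provenance(config)
    paths = {
        "xmfa": outdir / "alignment.xmfa",
        "fasta": outdir / "alignment.fasta",
        "truth": outdir / "truth.tsv",
        "genes": outdir / "genes.tsv",
        "metadata": outdir / "metadata.tsv",
        "tree": outdir / "genealogy.nwk",
    }
    write_xmfa([block], paths["xmfa"], provenance=prov)
    write_fasta(block, paths["fasta"], provenance=prov)
    _write_tsv(truth_table(truth), paths["truth"], prov)
    _write_tsv(make_gene_table(block, truth, config, fix_rng), paths["genes"], prov)
    _write_tsv(make_metadata_table(config, fix_rng), paths["metadata"], prov)
    paths["tree"].write_text(truth.genealogy.newick() + "\n")
    return paths


_CONTAINED = r"contained\((\d+) in (\d+)\)"
_OVERLAP = r"overlap\((\d+),(\d+),(\d+)\)"


def emit_coords_fixture(n_fragments: int, overlap_spec, seed=None, path=None) -> pd.DataFrame:
    """Coordinate-table fixture with controlled overlap structure.

    ``overlap_spec`` is a string or list of directives: ``"disjoint"``,
    ``"contained(i in j)"`` (fragment i strictly inside fragment j) or
    ``"overlap(i,j,bp)"`` (fragments i and j overlap by bp). Identities are
    drawn in [85, 100) from ``seed``; same seed gives identical file bytes.
    """
    import re as _re

    if n_fragments < 1:
        raise ConfigError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    specs = [overlap_spec] if isinstance(overlap_spec, str) else list(overlap_spec)
    lengths = rng.integers(300, 1500, size=n_fragments)
    starts = np.zeros(n_fragments, dtype=int)
    pos = 1
    for i in range(n_fragments):
        starts[i] = pos
        pos += int(lengths[i]) + int(rng.integers(50, 400))
    ends = starts + lengths - 1  # 1-based inclusive

    for spec in specs:
        if spec == "disjoint":
            continue
        m = _re.fullmatch(_CONTAINED, spec)
        if m:
            i, j = int(m.group(1)), int(m.group(2))
            if i == j or i >= n_fragments or j >= n_fragments:
                raise ConfigError(f"contradictory overlap_spec {spec!r}")
            if ends[j] - starts[j] < 10:
                raise ConfigError(f"fragment {j} too short to contain {i}")
            starts[i] = starts[j] + 2
            ends[i] = ends[j] - 2
            continue
        m = _re.fullmatch(_OVERLAP, spec)
        if m:
            i, j, bp = int(m.group(1)), int(m.group(2)), int(m.group(3))
            if i == j or i >= n_fragments or j >= n_fragments or bp < 1:
                raise ConfigError(f"contradictory overlap_spec {spec!r}")
            width = ends[i] - starts[i]
            starts[i] = ends[j] - bp + 1
            ends[i] = starts[i] + width
            continue
        raise ConfigError(f"unknown overlap_spec directive {spec!r}")

    ident = np.round(85 + 15 * rng.random(n_fragments), 2)
    df = pd.DataFrame(
        {
            "ref_start": starts,
            "ref_end": ends,
            "qry_start": starts,
            "qry_end": ends,
            "ref_len": ends - starts + 1,
            "qry_len": ends - starts + 1,
            "pct_identity": ident,
        }
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# hrscan v{__version__} coords fixture seed={seed}\n")
            df.to_csv(fh, sep="\t", index=False, header=False)
    return df


def simulate_species_table(n_species=54, seed=None, trend=1.0, noise=1.0) -> pd.DataFrame:
    """Synthetic per-species table linking lifestyle to recombination level.

    A latent recombination propensity increases along the lifestyle gradient
    (endosymbiont < obligate < commensal/free-living < opportunistic) with slope
    ``trend``; HR summaries and barrier/motility covariates are noisy functions
    of it. Used to exercise the group-difference and association statistics.
    """
    rng = np.random.default_rng(seed)
    lifestyles = [
        "endosymbiont",
        "obligate_pathogen",
        "commensal_free_living",
        "opportunistic_pathogen",
    ]
    level = rng.integers(0, 4, size=n_species)
    latent = trend * level + noise * rng.normal(size=n_species)
    df = pd.DataFrame(
        {
            "species": [f"sp_{i:02d}" for i in range(n_species)],
            "lifestyle": [lifestyles[k] for k in level],
            "competence": (latent + rng.normal(size=n_species) > 1.5).astype(int),
            "events_per_strain": np.round(np.exp(0.8 * latent + 0.3 * rng.normal(size=n_species)), 3),
            "pct_recombined": np.round(np.clip(3 * latent + rng.normal(size=n_species), 0, None), 3),
            "r_m": np.round(np.exp(0.5 * latent + 0.3 * rng.normal(size=n_species)), 3),
            "rm_type_I": rng.poisson(np.exp(0.3 * latent).clip(0.1, 20)),
            "rm_type_II": rng.poisson(np.exp(0.35 * latent).clip(0.1, 20)),
            "crispr_diversity": np.round(np.clip(1 - 0.2 * latent + 0.5 * rng.normal(size=n_species), 0, None), 3),
            "com_genes": rng.poisson(np.exp(0.25 * latent).clip(0.1, 20)),
            "hgt_fraction": np.round(np.clip(0.05 * latent + 0.02 * rng.normal(size=n_species), 0, 0.5), 4),
            "genome_size": np.round(rng.normal(4.0, 1.0, size=n_species).clip(0.5, 10), 3),
            "anib_mean": np.round(np.clip(99 - latent - rng.random(n_species), 80, 100), 3),
        }
    )
    return df
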