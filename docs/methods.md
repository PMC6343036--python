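# Methods

`hrscan` quantifies intraspecific homologous recombination (HR) in bacterial
core genomes: it scans multi-strain alignments with five nonparametric
detection statistics, calls consensus events, characterizes them
(size, GC, fraction of genome recombined), estimates the population-level
ratios rho/theta and r/m, computes ANIb from alignment coordinate tables and
NG86 dN/dS, and links the per-species summaries to lifestyle and genomic
covariates with enrichment and association statistics. A built-in simulator
generates all inputs with recorded ground truth, so every statistical claim in
the test suite is checked against planted events or exhaustive small-case
enumeration.

## The simulator (`hrscan.simdata`)

The clonal frame is a Kingman coalescent: with *k* active lineages the waiting
time to the next coalescence is exponential with rate *k(k−1)/2*, giving
expected total tree length 2·Σ₁^{n−1} 1/k. Sequences evolve down the tree from
a uniform-random ancestor; each branch receives Poisson(μ·ℓ·L) substitutions at
uniform sites (random different target base, Jukes–Cantor style) and
Poisson(λ·ℓ) homologous imports at uniform times along the branch.

An import copies a tract (geometric length, mean δ, truncated at the linear
chromosome end) from a **contemporaneous donor lineage of the same
genealogy** and then applies fresh substitutions with per-site probability ν.
The sampled donor lineage stands in for the true, unsampled donor at
divergence ν. This within-sample donor convention matters: intraspecific HR
creates *phylogenetic incongruence* (the recombinant locally clusters with the
donor lineage), which is the signal all five detection statistics are built
around. A purely external donor (fresh divergence with no lineage switch)
inflates one branch locally without changing any within-sample topology; such
tracts are largely invisible to incongruence-based scans — a known limitation,
not a bug, and one of the simulator design decisions documented here.

Two deliberate simplifications keep the truth registry exact and are recorded
in the event table: donor state is read at the donor branch's lower endpoint,
and within a branch mutations are replayed before imports. The truth registry
stores, per import, the carrier strain set (all leaves below the recipient
branch), the tract coordinates and realized length, the donor label and ν; a
per-strain, per-site origin mask marks every site descending from an import.

Defaults are chosen to emulate a moderately diverse, recombining species:
μ = 0.01 per site per coalescent unit (≈2% expected pairwise core diversity,
an *E. coli*-like scale), λ = 1 import per unit branch length, δ = 2 kb,
ν = 0.08, 8 strains, 100 kb of core alignment. Genes are tiled every 1 kb
(900 bp long, one ortholog per position across strains) and assigned one of 12
condensed functional category letters; when the enrichment odds parameter
*w* > 1, genes overlapping a planted event receive the focal category with
*w*-fold odds. What the generator does **not** emulate: indels and alignment
error (simulation is gapless; gap handling is exercised by hand-written
fixtures), rearrangements, accessory-genome dynamics, codon structure, rate
heterogeneity along the genome, and serial transfer of already-imported DNA.
Passing tests therefore demonstrate correctness of the statistics under the
model's assumptions, not robustness to alignment artefacts.

## Detection statistics (`hrscan.detect`)

All scans are complete-case per test (columns with gaps or N in any examined
sequence are dropped from that test) and examine every ordered-child triplet
(child × unordered parent pair; n(n−1)(n−2)/2 triplets) or strain pair.

* **MaxChi** — over the triplet's informative sites (parents differ, child
  matches exactly one), windows of 210 consecutive sites are scanned; at every
  internal breakpoint the 2×2 table (child-matches-A/B × left/right) gives a
  Pearson chi-squared, and the window statistic is the maximum. Windows
  advance by a quarter window so that some window edge always falls near a
  true tract boundary, where the single-breakpoint statistic peaks.
* **Chimaera** — same machinery on a different signal: the qualifying columns
  are those where the child differs from at least one parent, and the
  indicator marks columns where the child matches *neither* parent — i.e.
  where the best chimeric parent (which copies whichever parental residue
  matches the child) still mismatches it. Clustered child-vs-chimaera
  mismatches are the signature of DNA from outside the parent pair. A child
  identical to one parent yields no signal. This makes Chimaera the
  divergence channel, complementary to MaxChi's parental-switch channel (as
  specified verbatim, the two site definitions collapse into the same test).
* **RDP** — 90-column sliding windows of the three pairwise identities;
  candidate regions are maximal runs of windows whose locally closest pair
  differs from the genome-wide closest pair; the region p is the binomial
  upper tail of the locally closest pair's agreement count at polymorphic
  columns given its genome-wide agreement rate.
* **GENECONV** — for each strain pair, the alignment condensed to polymorphic
  columns; inner fragments are maximal mismatch-free runs of pair agreement
  (g-scale 0), scored by run length; significance from the permutation tail
  of the maximum run. Each significant fragment is emitted twice, once with
  each pair member in the recombinant role, because a pairwise test cannot
  orient the transfer. A pair identical at every polymorphic column is
  reported at the permutation floor and flagged `saturated`.
* **3Seq** — the ±1 walk over informative sites (up = child matches parent A);
  the statistic is the maximum descent, symmetrized over descent/ascent so the
  parent labeling is immaterial. For walks up to 400 informative sites the
  tail probability is computed exactly by a dynamic programme over all
  C(m+n, m) orderings (states: up-steps used × deficit below the running
  maximum, with a power-of-two rescale for long walks).

### p-values, bounds, and multiple testing

Raw p-values are site-order permutation tails (1999 permutations, add-one
convention, two-stage: a short first batch decides whether the full batch is
needed). Bonferroni correction is applied per method across all tests examined
(triplets × windows); an event requires corrected p < 0.001.

A permutation tail has a floor of 1/(n_perm+1) ≈ 5·10⁻⁴, which can never
survive a Bonferroni factor of 10³–10⁵ at α = 0.001; valid analytic bounds
take over whenever the permutation saturates (and, inside `scan_all`, whenever
only far-below-floor p-values could matter for the consensus):

* MaxChi/Chimaera: an exact Bonferroni-over-breakpoints bound from the
  hypergeometric distribution of the left-cell count at each breakpoint
  (chi ≥ s ⟺ |a·w − tK| ≥ √(s·t(w−t)K(w−K)/w)). Unlike the asymptotic χ²
  tail it stays valid for arbitrarily skewed match compositions. A cheap
  normal-approximation union estimate screens out clearly null windows first.
* GENECONV: the union bound (P−L+1)·q^L on the maximum run.
* 3Seq: the exact DP when feasible, else a Hoeffding union bound on the
  maximum descent over all interval lengths.

All bounds are conservative upper bounds on the permutation tail, so the null
calibration of the consensus is preserved (verified by simulation).

### Reported intervals

The test statistic locates a breakpoint; the reported candidate interval is
derived separately. For the chi-scans, the argmax breakpoints of all
significant windows of a triplet are clustered (±8 sites) into candidate
tract edges; each hit reports the adjacent segment whose composition deviates
most from the triplet's global rate (binomial z-score), capped to twice the
announcing window's column span. 3Seq reports the most anomalous change-point
segment from a recursive binary segmentation of its walk. RDP and GENECONV
intervals are their discordance runs and agreement runs directly. An
unconstrained maximum-contrast segment search is polarity-blind — with two
tracts in one triplet it returns the clean stretch *between* them — which is
why segments are anchored at breakpoints.

## Consensus events (`hrscan.consensus`)

Hits with corrected p < 0.001 are clustered per candidate strain by ≥50%
reciprocal overlap (overlap ≥ half the longer interval) using leader
clustering: hits are visited best-p-first and join the first leader they
reciprocally overlap. Leader clustering cannot chain unrelated regions
together through intermediate wide hits, which single-link does. Cluster
intervals are breakpoint-refined (below), clusters are merged across strains
by the same rule — one import is witnessed through several strain roles:
Chimaera flags the recombinant, MaxChi/3Seq flag observer children, GENECONV
flags pair members — and the merged event must be supported by at least three
of the five methods. The recombinant strain is then attributed by the local
identity drop: the strain whose mean identity to the others falls most inside
the interval relative to outside. The event interval is the median of the
supporting interval boundaries, which a single noisy wide hit cannot inflate.

Breakpoint refinement re-derives the interval from the best supporting
chi-method hit on that hit's own channel (match channel for MaxChi, chimaera
mismatch channel for Chimaera), using the change-point segment that overlaps
the event most within the 10%-padded interval; a refinement that no longer
overlaps the consensus interval by a third is rejected and the event flagged
`unrefined`. Refinement is idempotent by construction.

Species summaries report events/strain (total events ÷ strains sampled), the
percentage of the core alignment recombined (union of event intervals across
strains; the per-strain mean is also reported), a size histogram with
breakpoints at 2, 10 and 80 kb, GC inside events versus matched-length random
background windows (two-sided Mann–Whitney), and a rarefaction table over
random strain subsets.

### Detection power, honestly stated

On simulated data at the benchmark conditions (8 strains, 100 kb, ν = 0.08,
δ = 2 kb, μ = 0.01), measured over seeded replicates: PPV ≈ 1.0 and a median
refined-breakpoint error of a few tens of bp, with sensitivity ≈ 0.85 for
single-carrier (terminal-branch) events ≥1 kb but only ≈ 0.1–0.3 for
clade-shared (multi-carrier) events, giving ≈ 0.4 overall. The missed class is
structurally unidentifiable for incongruence-based statistics: an import
carried by an entire clade, received from a lineage ancestral to the rest of
the sample, leaves the within-sample topology unchanged — carriers remain a
clade — so no triplet has informative sites that distinguish it and the
closest-pair ranking never flips. Only the divergence channels (Chimaera,
GENECONV) see such tracts, and two methods cannot meet the three-method rule.
This mirrors the known real-data blindness of RDP-style scans to ancient,
clade-shared recombination, and it is the reason recombination surveys report
*detectable* (recent) events. Detected-event counts remain monotone in the
simulated rate, which is what the rho/theta rank-recovery benchmark measures.

## Evolutionary parameters (`hrscan.evol`)

rho/theta and r/m are **moment estimates** computed directly from consensus
events and polymorphic-site counts — deliberately not a ClonalFrame-style
Bayesian reconstruction (out of scope), and labeled as moment estimates in
every output:

    m̂        = polymorphic complete-case columns outside all events
    rho/theta = n_events / m̂
    ν̂         = polymorphic-column density inside events
    δ̂         = mean event span (bp)
    r/m       = (rho/theta) · δ̂ · ν̂        (an identity, by construction)

When m̂ = 0 the ratios are reported infinite and flagged saturated.

Pairwise dN/dS uses Nei–Gojobori (1986) counting: fractional synonymous sites
from the nine single-nucleotide neighbours of each codon with mutations to
stop codons excluded from the denominators (N + S = 3 per codon), observed
differences averaged over all minimal mutational pathways (pathways through
stop codons excluded unless all are), and Jukes–Cantor correction
d = −3/4·ln(1 − 4p/3). A pair with dS = 0 or a saturated distance reports the
ratio as missing, never infinite. Per-species dN/dS is the mean of defined
per-gene ratios with the undefined count reported alongside.

## ANIb (`hrscan.ani`)

From show-coords-style fragment tables (1-based inclusive coordinates,
reference frame): fragments wholly contained in a larger one are removed;
fragments overlapping by more than 10% of the **shorter** fragment's length
are joined into the spanning interval (the stricter of the two readings; the
longer-fragment denominator is available as a flag), with the joined identity
the length-weighted mean of the two members and the overlap counted once.
Rules apply left-to-right by start coordinate until a fixpoint. ANIb is then
Σ(lᵢ·idᵢ)/Σlᵢ over merged fragments; a pair's value is the mean of the two
directional values when both are available, and missing pairs stay missing.
Query-frame overlaps are not re-checked.

## Enrichment (`hrscan.enrich`)

Genes overlapping any event by ≥1 bp (half-open intervals), de-duplicated by
ortholog, are contrasted against all other annotated orthologs (the 2×2
margins are disjoint by construction) with a two-sided Fisher exact test per
category, Benjamini–Hochberg q-values across categories, and significance at
p < 0.05 with q < 0.10. Signed per-species profiles (−1/0/+1) are compared by
the simple matching coefficient and clustered with average linkage (species
pre-sorted by label so ties break deterministically); the dendrogram is also
written as newick.

## Association statistics (`hrscan.stats`)

Kruskal–Wallis (tie-corrected) and Jonckheere–Terpstra (ordered alternative,
Mann–Whitney counts with 0.5 for ties) compare HR levels across the lifestyle
gradient endosymbiont < obligate pathogen < commensal/free-living <
opportunistic pathogen; exact enumeration over group assignments replaces the
asymptotic/permutation p whenever the arrangement count is ≤10⁵. The Mantel
test correlates upper triangles of distance matrices with simultaneous
row/column permutations of the first matrix (exact for n ≤ 7); the partial
Mantel uses the first-order partial correlation controlling a third matrix.
Distances are Euclidean on z-standardized columns with categorical variables
dummy-coded and constant columns dropped with a warning. Path analysis fits a
recursive (acyclic) model by per-equation OLS on z-standardized data; the
indirect effect of X on Y is the sum over directed paths of the products of
edge coefficients, total = direct + indirect, with per-equation R² and
per-edge p-values; collinear predictor sets (condition number > 10⁸) warn but
still report. All permutation tests are seed-deterministic with add-one
p-values.

## Benchmark designs (`hrscan.benchmarks`)

Problem sizes were fixed a priori so that each benchmark answers its question
with adequate power on a single core:

* planted recovery: 20 replicates at the full benchmark conditions;
* null calibration: 50 replicates, 6 strains × 30 kb, λ = 0;
* rate-estimator grid: three well-separated event rates, 20 replicates each
  (rank recovery needs distinguishable levels, not a dense grid);
* enrichment: 50 replicates of a recombination-rich species (400 kb, λ = 12,
  ≈25% of the genome recombined — the upper range reported for natural
  recombinogenic species), sized for ≥95% design power at odds 5 over 12
  categories, with the truth registry as the event set, since the Fisher/BH
  machinery, not the detector, is under test;
* path analysis: 50 replicates of the X→M→Y chain at n = 200.

## Known limitations

* Clade-shared and root-branch imports are structurally undetectable (above);
  sensitivity figures refer to the event mix the coalescent generates, in
  which such events are common because deep branches are long.
* Closely spaced same-clade imports merge into one called region when their
  gap is below the 210-variable-site window resolution.
* The moment estimator undercounts rho/theta when events overlap heavily, and
  inherits the detector's sensitivity as a multiplicative bias; it tracks the
  true rate in rank but is not calibrated in level.
* GENECONV implements inner fragments only (no outer-sequence fragments,
  no mismatch-tolerant g-scale > 0).
* ANIb merging follows the reference frame only.
* The simulator's fixtures use one gene table shared across strains; there is
  no accessory genome.
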