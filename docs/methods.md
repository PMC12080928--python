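# Methods

This note documents the models implemented in `taxoforce`, the choices made
where the methodology was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Pairwise genomic indices

**AAI.** Average amino-acid identity between two proteomes is the
unweighted mean percent identity over reciprocal best hits (RBH): protein q
is p's best hit A→B and p is q's best hit B→A, best meaning highest bit
score, ties broken by lower E-value and then lexicographic subject id so
results are identical across search backends. Hits are filtered before
best-hit selection; the defaults (identity ≥ 30 %, query coverage ≥ 0.7,
E ≤ 1e-3) follow the widely used AAI-calculator convention. Whether
published AAI values used one- or two-way best hits and which coverage
filter is often unstated in application papers; here the filters are
explicit configuration and two-way matching is the default. The pipeline
consumes search results in BLAST tabular (outfmt 6) layout and never shells
out to an aligner itself.

**POCP.** The percentage of conserved proteins is the closed formula
`100·(C1+C2)/(T1+T2)`, where Ti is the proteome size of genome i and Ci the
number of its proteins with at least one qualifying hit in the other genome.
The qualifying filter is E < 1e-5 and identity ≥ 50 %; following the
original POCP definition an alignable-region ≥ 50 %-of-query condition is
also applied whenever protein lengths are available (it is toggleable).
POCP is monotone in the E-value cutoff by construction.

**OrthoANI-style ANI.** Both assemblies are cut into consecutive,
non-overlapping 1020-bp fragments (trailing remainder discarded), fragments
are searched in both directions, and the reported value is the mean
identity over reciprocal best fragment pairs. The aligner is a pluggable
contract; the built-in backend aligns fragments globally by edit distance
(via edlib) with identity `100·(L − d)/L` and discards hits below 35 %
identity, mirroring the published OrthoANI filter. The built-in backend is
exact but quadratic in fragment count — intended for tests and small
genomes; production runs supply externally produced fragment search
results.

**Species rule.** Same species requires ANI ≥ 96 (and dDDH ≥ 70 when a
dDDH value is supplied); different species requires ANI < 95 (and dDDH
< 70); the 95–96 ANI band, or any conflict between the two indices, yields
an explicit `ambiguous` verdict. dDDH is always consumed from a
user-supplied matrix (GGDC output), never computed.

## Threshold-stable genus delineation

Genus delineation treats the AAI matrix as a graph: at threshold t the
partition is the set of connected components over edges S ≥ t
(single-linkage clustering, the inclusive edge rule). Because the partition
changes only at observed matrix values, evaluating it at every distinct
off-diagonal value and merging equal runs enumerates *all* achievable
partitions. Each stable interval is displayed `[run_min–run_max]` over the
observed values of its run and additionally records the largest observed
value below the run (`prev_value`), so its full validity range is the
half-open `(prev_value, run_max]`. On a matrix with a clean gap (every
inter-genus value below every intra-genus value) the planted partition's
run therefore starts exactly at the smallest intra-genus value and is
entered immediately above the largest inter-genus value — both endpoints
are checked exactly in the tests.

Matrix values are rounded to two decimals on construction, matching the
precision of published AAI tables; without this, float noise can split one
conceptual interval into several.

Candidate intervals are ranked against a reference grouping (typically the
clades of a phylogenomic tree) by: adjusted Rand index (descending), number
of violated forbidden-merge constraints (ascending), number of singleton
groups (ascending) — partitions dominated by single-member genera are
taxonomy artefacts — and interval width (descending) as the final
tie-break. Whether width or phylogenomic congruence alone should break ties
is not settled usage; width is preferred here because a wide stable range
means the boundary is insensitive to measurement noise. The reference is
supplied as a two-column table; when only a tree is available the user must
cut it to groups themselves — automatic tree cutting is refused because the
cut level is exactly what is being estimated.

The single-linkage merge tree is exported as an ultrametric newick string
with node height `(100 − merge similarity)/2`, so cutting at height
`(100 − t)/2` reproduces the threshold partition; two genomes with
similarity 80 sit at depth 10 each.

## Constrained correspondence analysis and the forcing partition

Let Y be the binary genome × CDS matrix, `P = Y/y₊₊`, `r` and `c` the row
and column masses, and `Q_ij = (P_ij − r_i c_j)/√(r_i c_j)` the chi-square
residual matrix; total inertia `‖Q‖²_F` equals the chi-square statistic of
Y divided by its grand total. Habitat categories enter as indicator dummies,
weighted-centred with the row masses; Q is orthogonally projected onto the
span of `√r`-scaled centred dummies (via an SVD-derived basis with a
relative tolerance of 1e-9 — the centred dummies are exactly rank-deficient
and a naive least-squares solve leaks a spurious axis) and the projection is
decomposed by SVD. Squared singular values are the constrained eigenvalues;
with h habitats there are at most h − 1 axes, enforced explicitly. The
environmental (habitat-forced) fraction is constrained/total inertia and
the phylogenetic fraction is its complement. The implementation agrees with
`vegan::cca(Y ~ habitat)` to seven significant figures on random matrices
(development cross-check) and with an independent generalized-eigenproblem
solver to 1e-8 in the test suite.

Modelling choices, all stamped into run outputs:

* **No pre-transformation.** The binary matrix enters as-is (no Hellinger
  or rarefaction); presence/absence is the datum of interest.
* **Zero-mass rows and columns are dropped with a warning,** never imputed.
* **Scaling.** Reported site scores are linear combinations of the
  constraints; CDS and site scores are both scaled by the fourth root of
  the eigenvalues ("symmetric" scaling), keeping the two score sets on
  comparable magnitudes. `"sites"` and `"species"` scalings are available;
  the score-threshold rule below depends on this choice, so the effective
  scaling is recorded in every report.
* **Axis signs** are fixed by making the largest-|centroid| habitat
  positive on each axis, so sign-dependent downstream selections are
  reproducible.
* **Habitat–axis correlations** are row-mass-weighted Pearson correlations
  between a habitat's indicator and the site scores. They can also be
  computed for an arbitrary (e.g. permuted) assignment against a fixed
  fitted ordination; shuffled indicators correlate systematically more
  weakly than the true ones, which the tests verify. Both the
  indicator-level and CDS-level tables are emitted because published usage
  does not always state which correlation is meant.

**Permutation calibration.** The constrained fraction is biased upward by
construction (any h − 1 directions explain something), so it is calibrated
against a null distribution from refitting under random permutations of the
habitat labels (99 by default, seeded). A planted habitat effect should
exceed the null's 95th percentile. For the no-effect case one subtlety
matters: in the study-shaped default scenario the clade structure partially
aligns with the habitat assignment — as in real data, where relatives share
habitats — so even with zero planted habitat genes the habitat-constrained
fraction sits above the permutation null. That is a true positive for
*confounded* phylogenetic signal, not a calibration failure. The no-signal
null scenario therefore draws the habitat assignment independently of the
clades; under it the observed fraction falls inside the null's central 90 %.

## Habitat-specific gene calling

Two routes, emitted side by side:

* **Ordination route.** The per-axis rule selects CDS whose score on a
  named axis exceeds 0.15 in the habitat's direction; CDS within ±0.15 on
  *every* axis are reported separately as "core-like" (housekeeping
  functions behave this way, with no special-casing — neutrality emerges
  from the scores). With several habitats sharing five axes, a plain
  per-axis filter also sweeps up genes forced by *other* habitats that
  co-vary on the shared axis; the pipeline-level call therefore uses
  nearest-centroid-direction attribution: each CDS is attributed to the
  habitat whose centroid direction its full score vector projects onto most
  strongly, and called when that signed projection exceeds the same 0.15
  cutoff. With a single constrained axis the two procedures coincide. The
  0.15 default is a score magnitude in the configured scaling and is fully
  configurable.
* **Exclusivity route.** Strict mode calls CDS present in *all* genomes of
  a habitat and absent outside (sets are disjoint across habitats by
  construction); relaxed "any" mode requires presence in at least one
  member and absence outside — useful where within-habitat diversity is
  high and no gene is universal, as for sponge symbionts. Any-mode sets
  contain their strict counterparts.

Calls are summarised as a habitat × function table: ○ where a function is
supported by the ordination or strict-exclusive route, Δ where only by the
relaxed route; unannotated CDS are pooled under "hypothetical".

**KEGG modules.** A module is present when at most one of its component
blocks lacks any observed ortholog (a block is satisfied by any of its
interchangeable orthologs). Single-component modules require their
component observed — otherwise the ≤ 1-missing allowance would declare a
module present on no evidence.

## Synthetic data: what it emulates and what it does not

The matrix generator plants genus blocks and draws intra-/inter-genus
values from disjoint percent ranges (uniform by default, truncated normal
available), rounded to two decimals to exercise tie handling; the truth
records the planted partition and the exact gap. The study-shaped default
is 38 genomes in 17 groups with intra ≥ 78.5 and inter ≤ 71.9. The
pangenome generator plants core genes (everywhere), clade genes (exactly
their clade, then bit-flipped at 1 %), and habitat genes
(Bernoulli(penetrance 0.9) inside, Bernoulli(background 0.05) outside); the
study-shaped default is 16 genomes over six habitats (six sponge, two
coral, two flatworm, one eelgrass, four seawater, one sediment isolate)
with 2000 core + 5×400 clade + 6×100 habitat columns ≈ 4 600 CDS clusters,
comparable to a small pangenome. The proteome-pair generator applies
per-site substitutions at rate 1 − AAI/100 with exact hit tables. One
global seed feeds a named substream per generator, so stages are
reproducible independently; identical seeds give byte-identical outputs.

Not emulated: indels and codon structure (no sequence-evolution realism),
assembly fragmentation and annotation error, paralog splitting by pangenome
pipelines, geographically structured habitat effects, and gradual (rather
than block) phylogenetic signal. Consequently, passing the planted-recovery
tests shows the estimators are correct under their own assumptions — clean
block structure and independent noise — not that real pangenomes satisfy
those assumptions. In particular, genes forced jointly by phylogeny and
habitat are inherently unattributable to either; the recovery tests
therefore plant habitat genes without clade confounding, and the variance
partition is the quantity that measures the entangled remainder.
Habitat-call precision/recall is assessed pooled across habitats;
single-genome habitats are individually noisier.

## Problem sizes and numerics

The test suite and the acceptance script run the delineation stage at 38
genomes, the CCA stage at 16 × ~4 600 with 99-permutation nulls, oracle
comparisons at n ≤ 14, and 200-matrix brute-force cross-checks at n ≤ 8 —
sizes chosen so the full suite completes in seconds while covering every
code path at the study's own shape. Eigenvalues below 1e-10 (relative) are
treated as null axes; interval endpoints compare exactly after the 2-decimal
rounding; the permutation generator is seeded everywhere.

## Known limitations

* The candidate-interval method assumes single-linkage semantics; other
  linkage rules would give different (non-interval) stability structure.
* POCP is computed but known to discriminate poorly near the genus boundary
  in some families (values > 50 across genera); it is provided as a
  reference index, and no POCP threshold search is attempted.
* The built-in aligner ignores rearrangements and local alignment effects;
  ANI values from it are exact only for the toy regime it serves.
* CCA attributes *all* habitat-correlated inertia to the environment; with
  habitats confounded by geography or phylogeny the "environmental"
  fraction is an upper bound, as the permutation analysis makes explicit.
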