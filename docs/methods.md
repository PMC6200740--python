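# Methods

This note documents the statistical model behind each pipeline stage, the
generative model of the synthetic screens used for validation, the
numerical conventions, and the known limits of what the bundled tests can
show.

## Signature model

A screen is a log2-normalised genes × wells matrix joined to a plate
annotation (well → plate, phase, cell line, group, treatment, dose).
Groups are the three screening contexts: cancer cell lines (CCL),
control-donor neural progenitor cells (NPC_control), and
schizophrenia-donor NPCs (NPC_SZ).

The robust Z-score of gene *g* in a treated well is

RZS_g = (x_g − median(v_g)) / MAD(v_g),

where v_g are the vehicle (DMSO) wells of the **same plate and cell
line**. Consequences that the tests assert exactly:

- any additive plate-wide offset cancels (location invariance), and any
  positive plate-wide scaling cancels (numerator and MAD both scale);
- batch structure (plate, phase) contributes no variance to signatures
  beyond median/MAD estimation noise.

Conventions:

- **MAD** is the raw median absolute deviation — no 1.4826 normal
  consistency constant. The constant only rescales all signatures of a
  plate jointly, so threshold-based calls shift but rankings do not;
  `mad_constant="normal"` enables it for sensitivity analysis.
- **MAD floor.** A gene whose vehicle MAD is exactly 0 would give an
  infinite score; it instead uses the smallest positive vehicle MAD on
  that plate (fallback 1e−6 when the whole plate degenerates). This
  preserves the gene's rank position without manufacturing infinities.
- **Multiple treated wells** of one drug on one plate are averaged
  *before* the transform; replicate plates are collapsed to the per-gene
  median *after* it. The plate-matched transform always sees one plate.
- **Probe collapsing** keeps, per gene, the probe with the highest mean
  expression across all columns; exact ties go to the lexicographically
  smaller probe id so results are reproducible.

## DE accounting

DE within a group: |median RZS across the group's lines| ≥ 2
(inclusive). Differential DE between groups: |median_A − median_B| ≥ 2,
a condition on the difference alone. Defaults are configurable
(`AnalysisConfig`); thresholds are in RZS units.

Pairs DE in at least one of two groups are partitioned into four
disjoint, exhaustive response categories: both-DE with opposite signs
(`opposite_de`); exactly one DE with discordant signs
(`opposite_subthreshold`); exactly one DE with the other value
negligible, |value| < 0.5 (`single_group`); otherwise concordant signs
with a magnitude difference (`same_direction_magnitude`). The 0.5
negligibility bound separating "no response" from "same direction,
smaller" is a declared convention of this package — the category
boundaries are not fully determined by threshold calls alone — and is
configurable.

Responsiveness between groups is compared with a Cochran–Mantel–Haenszel
test: one 2×2 stratum per drug–gene pair, counting DE vs non-DE cell
lines per group (lines pool across phases). The common odds ratio is
Σ(a_i d_i / n_i) / Σ(b_i c_i / n_i); the chi-square uses the
hypergeometric variance with no continuity correction (exact agreement
with the single-table chi-square, up to the n/(n−1) variance convention,
is asserted in tests, as is agreement with
`statsmodels.StratifiedTable`). Degenerate strata (a zero margin)
contribute nothing and are dropped; Bonferroni correction is applied
across the declared family of group comparisons.

## Set enrichment

For each drug and gene set, two variants of an unpaired two-sample
t-comparison of the groups' RZS are exposed:

- **v1 (default):** each cell line is summarised to its mean RZS over
  the set's genes; Welch t between the group summaries. Cell lines are
  the biological replication unit, so this is the default.
- **v2:** set-gene RZS values pooled across each group's lines, Student
  t. This matches a literal matrix-vs-matrix reading of the comparison
  but treats gene-level values as exchangeable replicates.

p-values are two-sided; FDR is Benjamini–Hochberg within one family per
(comparison × set category), chosen over Storey's q-value for
determinism on small families. Sets intersected with the expressed-gene
background below 5 genes are reported `tested = False`, never
zero-filled. The background is estimated from a counts matrix as genes
with ≥ 10 reads in ≥ half the cell lines (ceiling); it is intended for
comparisons involving CCLs, whose expressed repertoire limits which
brain-derived sets are measurable.

## Connectivity and reversal screening

Genes are ranked by descending RZS, ties broken by gene id. For a tag
set at sorted ranks r_1 < … < r_t among n genes, the tag ECDF minus the
non-tag ECDF is extremised at tag positions:

a = max_j [ j/t − (r_j − j)/(n − t) ],
b = max_j [ (r_j − j)/(n − t) − (j − 1)/t ],

both floored at 0 (the running sum's boundary value), and
es = a if a > b else −b. When a = b — equally extreme deviation in both
directions, possible in discrete rank space — es is 0 (no dominant
direction). This two-sample ECDF form was chosen over the tag-only
approximation j/t − r_j/n because it is *exactly* antisymmetric under
rank reversal and reaches ±1 exactly at the extremes; the two agree as
t/n → 0. Scores are not rescaled by per-batch extrema (no cross-batch
pooling exists here).

The connectivity score is 0 when es_up and es_down share a sign, else
(es_up − es_down)/2 ∈ [−1, 1]. Group aggregation takes the per-gene
median RZS across a group's lines before ranking, consistent with the
pipeline's median conventions.

The reversal screen's null re-samples random tag sets of matching sizes
from the gene universe (gene-label permutation, matching the
signature-level granularity of the question); because random tag ranks
against any fixed ranking are a uniform draw of rank positions, one null
sample serves every entry. Two-sided
p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1), BH within each context
column; reversing ⇔ score < 0 and q < 0.1. A seed is required —
permutation results without one are not reproducible. When both NPC
contexts are present, reversers are classified both / SZ-only /
control-only.

Cell-line embedding uses classical (Torgerson) metric MDS on Euclidean
distances between drug-score profiles: double-centre the squared
distances, eigendecompose, keep the top axes scaled by √eigenvalue. The
sign of each axis is fixed by making its largest-magnitude coordinate
positive, so output is deterministic. (SMACOF-style iterative MDS was
deliberately not used; the classical solution is closed-form and exact
for intrinsically low-dimensional input, which the tests verify by
distance reconstruction.)

Drug prioritisation ranks drugs by their best |es| across target sets
(undirected tag sets), ties by drug id; directed screening goes through
the disease-signature path.

## Chemogenomic enrichment

Drug groups are the drugs that differentially regulate a set at
q < 0.1 (strict), kept only when ≥ 3 drugs qualify. For each annotation
class the background is the screened drugs carrying ≥ 1 annotation of
that class — side effects are only meaningful for clinically used
compounds, and the same logic generalises to every class. Each feature
is a one-sided (greater) Fisher exact test on (in group × has feature)
over that background, BH within the (set, class) family. Target-overlap
prioritisation applies the same Fisher machinery to (drug targets × set
membership) over the gene universe, ranking drugs by their best p.

## Motif analysis

Patterns are IUPAC-degenerate RNA strings (K = G/U, W = A/U, R = A/G,
Y = C/U, S = C/G, M = A/C, N = any); DNA input is accepted with T ≡ U.
Scanning reports all, possibly overlapping, 0-based start positions.
Only the ACUK pattern is named in the default catalog; further
FMRP-associated patterns are configuration, not code. Motif density is
occurrences per kb of the provided sequence (the transcript/UTR choice
belongs to the caller); group comparisons use a two-sided two-sample
Student t on per-sequence densities. A variant lies "in motif" when an
occurrence fully contained in its reference window spans the variant
offset — occurrences truncated by the window edge never count. Cohort
enrichment is a one-sided Fisher test of in-motif counts, case cohort vs
control, BH across the tested family, optionally within one annotation
stratum (e.g. essential splice sites).

## Synthetic screens

The generator emulates the structure the transform exploits, additively
on the log2 scale:

x[g, well] = baseline_g + cell-line offset + plate offset + phase offset
\+ effect + N(0, noise_sd)

- **Plate layout:** plates are dedicated to one cell line and carry one
  empty well, 12 vehicle wells, 2 positive-control wells in duplicate,
  and one well per drug (chunked across plates when drugs exceed
  capacity); the layout repeats per phase and replicate plate set.
- **Effects:** a sparse base effect (drug, gene) matrix, an NPC-only
  cell-type modifier, and an SZ-NPC-only diagnosis modifier, all of
  configured magnitude with random sign. A configurable fraction of base
  effects can be converted into NPC-only effects, planting a CCL
  responsiveness deficit. Reverser drugs carry base_effect =
  −disease_effect over a planted up/down disease signature. Gene-set
  shifts plant drug-independent group-wise effects on a set's genes.
- **Batch offsets** are scalars per plate and phase by default
  (`batch_per_gene` draws per-gene offsets); either way the plate-matched
  transform cancels them.
- **Defaults:** the scaled-down preset (20 drugs, 500 genes, 3+3+2
  lines, 2 phases × 2 replicate plates, noise_sd 0.3, batch_sd 1.0,
  effect size 2.0) keeps the full suite under a minute of simulation
  time; the full-size preset (135 drugs, 8+12+12 lines) mirrors the
  dimensions of a two-phase screen. Effect size 2.0 at noise 0.3 puts
  planted effects at ≈ 10 RZS units — comfortably recoverable — while
  the null RZS median across replicates keeps the false-positive rate
  under 1% at the ≥ 2 threshold.
- Sequences are uniform-random RNA scrubbed of chance motif hits, then
  given Poisson-distributed planted occurrences at the configured per-kb
  rate; variant windows (±10 nt) contain a motif spanning the offset
  with exactly the configured probability.
- Drug annotations assign features per class at a base prevalence of 0.2
  to the ~80% of drugs annotated in that class; planted (group, feature)
  pairs are over-represented at prevalence 0.8.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: bead-measurement and imputation error
of the landmark→transcriptome step, count-based mean–variance
relationships (data are Gaussian on the log2 scale by design, matching
already-normalised input), correlated gene modules (effects are planted
independently per gene except for set shifts), dose–response structure
(one dose per drug, dose carried but never modelled), and cell-line
baseline differences beyond a scalar offset. Recovery rates measured
here are upper bounds on what identically parameterised real screens
would give.

## Numerical choices and degenerate inputs

- Thresholds are inclusive (≥) everywhere a threshold is named; FDR
  gates are strict (<).
- BH via `statsmodels.multipletests`; Fisher via
  `scipy.stats.fisher_exact` (verified against the hypergeometric tail
  closed form); Welch/Student t via `scipy.stats.ttest_ind`.
- Permutation p-values use the add-one estimator, never exactly 0.
- Ranking ties (genes, drugs) always break lexicographically.
- Errors, not silent defaults: fewer than 3 vehicle wells, empty
  backgrounds, overlapping group definitions, missing seeds for
  randomised stages, and empty cohorts after filtering all raise.

## Pipeline

`run_pipeline` executes simulate → signatures → de → enrich →
connectivity → chemgen → motifs from one YAML config; stage dependencies
are validated up front and every violation (not just the first) is
reported. The manifest records a config hash, the seed, per-stage output
paths with row counts, and the package version; identical configs
reproduce identical outputs for deterministic stages. All randomised
stages derive their seeds from the single config seed.

## Known limitations

- The enrichment t-comparison treats cell lines (v1) or gene values (v2)
  as independent; gene–gene correlation within sets inflates v2's
  significance on real data, which is why v1 is the default.
- The CMH responsiveness test conditions on per-line DE calls, which are
  themselves threshold summaries; it measures DE-proportion differences,
  not effect-size differences.
- Classical MDS assumes Euclidean geometry of score profiles; strongly
  non-metric structure would need a different embedding.
- The motif scanner treats sequence N as matching only motif code N;
  ambiguous reference bases therefore under-count occurrences.
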