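# Methods

This note records the models, parameter choices and known limitations of
`pgcausal`, in the spirit of a statistical methods appendix.  Nothing here
reports an empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The synthetic generative model

The generator exists so that every downstream stage can be validated
against exact ground truth.  It emulates a two-layer proteogenomic matrix
(features × samples, 10–10 000 features, 8–15 samples) with three layers of
structure:

**Module latents from a linear Gaussian SEM.**  A DAG over module
identifiers carries edge weights; each node equals the weighted sum of its
parents plus N(0, 1) noise, evaluated in topological order
(`simulate_sem`).  The latent noise standard deviation is fixed at 1 so
edge weights are directly interpretable as standardized effects.  Random
DAGs (`random_dag`) draw a uniform node order, include each forward pair
with probability `edge_prob`, and give every edge a weight of magnitude
uniform in [0.5, 1.5] with random sign — bounded away from zero so effects
remain detectable; faithfulness of the induced distribution is assumed by
the PC algorithm and holds for almost all weight settings, but see §5.

**Member features.**  Each feature in each layer loads on its module's
latent with a loading drawn from `loading_range` (default [0.8, 1.2];
ranges straddling zero are rejected because the within-module correlation
sign would be ambiguous) plus feature noise of standard deviation
`feature_noise_sd` (default 0.3, giving within-module correlations around
1/(1 + 0.3²) ≈ 0.92 — the tight co-expression regime the module concept
presumes).  Cross-layer agreement is a probability-like fraction: at
`layer_agreement = 1` both layers load on the same latent; lowering it
gives the stated fraction of protein-layer features an independent latent
profile, degrading consensus.

**Abundance scale and filter fodder.**  Latent-scale values are shifted
per feature to a positive range (`x − min + 1`), which preserves all
correlation structure exactly; an exponential map is available for a more
FPKM-like skewed marginal but is off by default precisely because it
distorts correlations.  Background features are i.i.d. noise (the planted
analogue of unassigned "module 0"), and a configurable fraction of them is
rescaled into (0, 1) so the minimum-expression filter has something real
to remove.  An optional missingness fraction plants single missing cells
to exercise the complete-pairs filter.

**Identifiability of the planted partition.**  Module eigengenes inherit
the latent correlations, and the merge stage (cut height 0.25) collapses
modules whose eigengene correlation exceeds 0.75.  A planted partition is
therefore only a coherent ground truth when the SEM-implied pairwise
latent correlations stay below that threshold.  `identifiable_module_dag`
enforces this by rejection sampling: DAG draws (weight magnitudes
[0.5, 1.0]) are discarded until the analytic SEM correlation matrix
(`(I−W)^{-T}Σ(I−W)^{-1}`, normalized) has maximum off-diagonal
|correlation| ≤ 0.6 — below the merge threshold with margin while still
admitting multi-edge DAGs.  What no constraint can remove is *empirical*
latent correlation: with only 8–15 samples, two independent latents can
show sample |r| of 0.5–0.6 by chance, and at such seeds the procedure
correctly (given its inputs) lumps or trims a module.  Recovery scores on
real-scale sample counts should be read with that in mind.

**What the generator does not emulate:** tissue-specific biology, FPKM
normalization artifacts, mass-spectrometry missingness mechanisms
(censoring at the detection limit), count noise, or batch effects.
Passing tests on this generator show the chain recovers planted linear
Gaussian structure; they do not certify behavior under real proteomic
noise.

## 2. Filtering

Two rules, both applied pair-wise so the layers stay aligned:

* complete pairs: a feature is kept only if it has no missing value in any
  sample in either layer;
* minimum expression: a feature is kept only if it exceeds the threshold
  (default 1, **strictly**: "greater than 1" is read literally as `>`) in
  at least `ceil(n_samples / 3)` samples in each layer (5 of 15).  Both
  the threshold and the count are configurable; whether the original rule
  was `>` or `≥` cannot be decided from the description it follows, so the
  strict reading is the default and the alternative is one flag away.

Zeros are valid observations, never missing values; missingness is encoded
as `NA` in the TSV dialect.  The filters are idempotent and commute on
complete data (property-tested).  Spearman per-pair correlations use
average ranks for ties.

## 3. Consensus modules

Per layer: Pearson correlation across samples → unsigned adjacency
`|r|^β` (signed `((1+r)/2)^β` available; unsigned is the default because
the upstream methodology's default is unsigned and the source procedure
does not state its choice) → topological overlap.  The soft power is the
smallest candidate in {1..10, 12, 14, 16, 18, 20} whose *cross-layer
minimum* signed scale-free fit R² reaches 0.85; when no candidate
qualifies — common for strongly block-structured data, whose degree
distribution is not scale-free — the pipeline falls back to a configured
default of 9, the published choice for a 15-sample unsigned network.

The scale-free fit bins connectivity into 10 equal-width bins and
regresses log10(frequency) on log10(mean k); the sign of the returned
R² follows the negated slope, so decaying degree distributions score
positively.

Layer TOMs are calibrated by matching their off-diagonal 0.95 quantile to
the first (transcript) layer's, capped at 1, before taking the
element-wise minimum — without calibration the layer with the smaller
overall TOM scale would dominate the minimum.

**Tree cut.**  Modules are cut from the average-linkage dendrogram of
`1 − consensusTOM` at height `q + f(s)·(max_height − q)` where `q` is the
0.05 quantile of merge heights and the sensitivity `s` ∈ {0..4} maps to
`f` ∈ {0.95, 0.90, 0.80, 0.70, 0.55} (default s = 2, f = 0.80); clusters
below the minimum size (30) dissolve to label 0, survivors are relabeled
1..m by decreasing size.  This quantile-anchored static cut replaces the
full hybrid dynamic tree cut with its PAM stage: it keeps the same
user-facing knobs (minimum size, sensitivity), is transparent and exactly
testable, and recovers planted modules; it will differ from the hybrid
algorithm on dendrograms with nested or elongated cluster shapes.

**Merging.**  Iteratively, modules whose consensus eigengene
dissimilarity — max over layers of `1 − cor(E_p, E_q)` — joins below the
cut height 0.25 under average linkage are merged, eigengenes recomputed,
until a fixpoint.

Eigengenes are first right singular vectors of the standardized module
submatrix, unit-norm, sign-aligned so their correlation with the mean
member profile is nonnegative (PCA leaves the sign free; alignment makes
eigengene networks reproducible).

## 4. Eigengene networks and profiles

`A_pq = (1 + cor(E_p, E_q))/2` per layer; preservation
`P = 1 − |A − B|` element-wise; per-module mean preservation is the column
mean excluding the diagonal (the module's preservation "to all other"
modules — including the diagonal would add a constant 1/m to every mean).
Module z-score trend profiles average the per-feature z-scores (features
with zero variance contribute zero rows).  Module-by-tissue heatmaps order
modules by complete-linkage clustering under Euclidean distance; samples
are never reordered, so stage/tissue progressions stay readable.

## 5. Causal discovery

The PC algorithm under causal sufficiency (no unmeasured confounders) and
faithfulness:

* **Skeleton** — order-independent ("stable") search: at each level the
  adjacency sets are snapshotted and every ordered adjacent pair is tested
  against all conditioning subsets of the snapshotted neighborhood, in
  lexicographic order; the first separating set removes the edge and is
  recorded.  The conditioning size is capped at `n − 5` so the Fisher-z
  precondition `n − |S| − 3 ≥ 1` can never be violated — essential at
  eigengene sample sizes of 15–30.
* **v-structures** — every unshielded triple x−y−z with y outside
  sepset(x, z) becomes the collider x→y←z.  Conflicting orientations from
  overlapping triples resolve last-writer-wins in sorted triple order, with
  the conflict count logged (a strict mode could drop conflicted
  orientations instead; the lenient mode matches common reference
  implementations).
* **Meek completion** — rules R1–R4 to a fixpoint yield the CPDAG.

Gaussian CI tests: partial correlation from the inverse of the
sub-correlation matrix on {i, j} ∪ S (clamped to ±(1 − 1e−7)), Fisher
z = atanh(ρ), statistic `√(n − |S| − 3)·|z|`, two-sided normal p-value,
independence iff p > α.  α defaults to 0.05 and must be set explicitly in
pipeline configs — the choice materially changes edge counts at small n
and the source procedure does not state its level.

**Observation matrix for the eigengene stage.**  Which observations feed
the eigengene correlation matrix is genuinely open: with m modules and
only n_samples tissues a single-layer correlation matrix is rank-deficient
whenever m > n_samples.  The default stacks the transcript- and
protein-layer eigengene sample vectors (n = 2 × n_samples), which treats
the two layers as replicate observations of the same module activity;
single-layer modes are provided.  Neither mode claims to replicate any
particular published graph.

**Validation oracles.**  A d-separation oracle (via networkx) exposes the
same CI interface, so PC can be run with exact independence answers; its
output must equal `dag_to_cpdag` (skeleton + DAG-derived v-structures +
Meek), which is itself checked against brute-force enumeration of every
acyclic orientation of the skeleton with matching v-structures.  Recovery
from data is scored by the structural Hamming distance over pair statuses
{absent, undirected, →, ←}.

**Known limitation (measured, not hidden).**  On denser random DAGs the
finite-sample recovery error is dominated by conditioning-induced
near-cancellations: conditioning on a collider child opens a path whose
effect can almost exactly cancel a direct edge, leaving a true partial
correlation of ~0.005 that no realistic sample size rejects.  Bounding
individual edge weights away from zero does not prevent this, since the
cancellation is a property of path sums.  Consequently mean structural
Hamming distances over random 8-node, edge-probability-0.3 ensembles
plateau slightly above 2 at n = 2000 even though the implementation is
exact at the oracle level.

## 6. Pipeline and reproducibility

The runner executes simulate/load → filter → soft threshold → consensus
modules → eigengene networks → PC, writing every stage's output as TSV
before the next stage runs, plus a JSON manifest (feature counts, chosen
power, module sizes, CPDAG summary, and — when planted truth is available —
ARI and the SHD to the planted CPDAG via majority-overlap module
matching).  All randomness flows from one seed through
`numpy.random.SeedSequence` spawns; identical config + seed gives
byte-identical manifests and edge lists.  Degenerate paths (all features
filtered, fewer than two modules) end with explicit stage skips, not
crashes.

Default problem sizes (5 modules × 60 features, 40 background, 15 samples;
oracle checks on ≤ 6 nodes plus 50 sampled-recovery replicates at n = 2000)
were chosen so the entire test suite and the acceptance script each run in
well under a minute on a single CPU while still exercising every code
path at realistic proteogenomic scale.
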