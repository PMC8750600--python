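# pgcausal

Consensus co-expression modules and causal structure discovery for paired
transcript–protein expression data.

## The problem

Matched transcriptomic and proteomic profiles of the same tissues (a
proteogenomic atlas: mRNA abundance as FPKM, protein abundance from
quantitative proteomics, for thousands of gene/protein pairs across a
handful of samples) raise two linked questions:

1. Which gene/protein pairs co-vary consistently **in both omics layers**
   — the consensus co-expression modules?
2. How do those modules relate **causally** — which module drives which,
   beyond symmetric correlation?

`pgcausal` implements the full inference chain for desk-scale data:

* **Filtering** — keep pairs with valid values in every sample in both
  layers, then pairs with values > 1 in at least a third of samples in both
  layers; per-pair Spearman correlation summaries.
* **Consensus weighted network** — per layer, Pearson correlation across
  samples raised to a soft-thresholding power β (chosen by the approximate
  scale-free topology criterion, `signed R² ≥ 0.85`) gives the adjacency
  `a_ij = |r_ij|^β`; the topological overlap matrix
  `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
  `l_ij = Σ_u a_iu a_uj` rewards shared neighbors; layer TOMs are
  quantile-calibrated and combined by the element-wise minimum; modules come
  from average-linkage clustering of `1 − consensusTOM` (minimum size 30,
  detection sensitivity 2, eigengene-merge cut 0.25).
* **Eigengene networks** — each module is represented by its eigengene (the
  first principal component of the standardized member submatrix);
  per-layer eigengene adjacencies `A_pq = (1 + cor(E_p, E_q))/2`, their
  cross-layer preservation `P = 1 − |A_transcript − A_protein|`, module
  z-score trend profiles, and complete-linkage/Euclidean module clustering.
* **Causal discovery** — the PC algorithm over the module eigengenes, with
  Gaussian conditional-independence testing via the Fisher z transform
  (`z = atanh(ρ)`, statistic `√(n − |S| − 3)·|z|`) computed from the
  sufficient statistic (eigengene correlation matrix, sample size).  The
  output is the CPDAG of the Markov equivalence class: directed edges are
  cause→effect relations shared by every DAG in the class, undirected edges
  are direction-undetermined.
* **Synthetic data with ground truth** — a generator that plants modules
  whose latent variables follow a linear Gaussian structural equation model
  over a known DAG, so module recovery (adjusted Rand index) and causal
  recovery (structural Hamming distance) can be measured exactly.

## Worked example

Run the whole chain on simulated data (5 planted modules of 60 features
plus 40 background features, two layers, 15 samples, a planted 4-edge DAG):

```sh
pgcausal run-all --seed 11 --out demo_run
```

prints the stage summary (abridged):

```json
{
  "filter":     {"input": 340, "complete_pairs": 340, "min_expression": 328},
  "pair_correlation": {"mean_spearman_rho": 0.75515, "n_positive": 317, "n_total": 328},
  "soft_threshold": {"chosen_power": 9.0, "fallback_used": true},
  "modules": {"n_modules": 5, "adjusted_rand_index": 0.994314,
              "module_sizes": {"1": 61, "2": 60, "3": 60, "4": 60, "5": 60}},
  "causal": {"n": 30, "n_directed": 0, "n_undirected": 3,
             "n_connected_subgraphs": 2, "shd_to_planted_cpdag": 2}
}
```

Reading this: 12 of the 340 simulated features were low-expression
background and fell to the `> 1 in ≥ 5 of 15 samples` filter; the retained
pairs correlate strongly across layers (mean Spearman ρ = 0.76); no power
reached the scale-free cut on block-structured data, so the configured
fallback β = 9 was used; all five planted modules were recovered almost
exactly (ARI 0.994); and the PC algorithm over the 5 module eigengenes
(n = 30 stacked observations) kept three module–module edges whose
directions are undetermined at this sample size, at structural Hamming
distance 2 from the planted equivalence class.

Every stage writes self-describing TSVs (`modules.tsv`,
`eigengenes_<layer>.tsv`, `preservation.tsv`, `cpdag_edges.tsv`, …) plus a
JSON manifest, and each stage is also available as a subcommand
(`simulate`, `filter`, `modules`, `networks`, `causal`, `summarize`) or as
library functions (`pgcausal.pc`, `pgcausal.consensus_modules`, …).

## Layout

```
src/pgcausal/
  containers.py     paired-omics containers + TSV dialect
  synthetic.py      DAGs, linear Gaussian SEM, planted-module generator
  preprocessing.py  filters and Spearman pair summaries
  wgcna.py          adjacency, TOM, consensus modules, eigengenes
  eigengenes.py     eigengene networks, preservation, z-score profiles
  causal.py         PC algorithm, Meek rules, CPDAG, oracles, metrics
  pipeline.py       configuration-driven end-to-end runner
  cli.py            click command-line interface
  plotting.py       optional heatmap/barplot/trend helpers
docs/methods.md     model assumptions, parameter choices, limitations
```
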