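"""Synthetic paired-omics generator with planted modules and a planted DAG.

Every downstream stage (filtering, consensus module detection, eigengene
networks, CPDAG estimation) is validated against data produced here, where
the ground truth — which feature belongs to which module, and which module
causes which — is known exactly.

The generative model:

1. A random DAG over module identifiers, with linear edge weights whose
   magnitude is bounded away from zero (|w| in [0.5, 1.5]) so effects stay
   detectable and near-unfaithful cancellations are avoided.
2. Module-level latent variables drawn from the linear Gaussian structural
   equation model (SEM) implied by the DAG: each node is the weighted sum of
   its parents plus independent Gaussian noise, evaluated in topological
   order.
3. Member features in each layer load linearly on their module's latent
   (loading drawn from a user-supplied range that must not straddle zero)
   plus feature-level Gaussian noise.  Cross-layer agreement is degraded by
   giving a fraction ``1 - layer_agreement`` of protein-layer features an
   independent latent profile instead of the module latent.
4. Values are mapped to a nonnegative abundance scale by a per-feature shift
   (``x - min(x) + 1``), which preserves all correlation structure; an
   exponential map is available via ``exponentiate=True`` for a more
   FPKM-like skewed marginal.
5. A fraction of background features is rescaled into (0, 1) so that they
   fail the "greater than 1 in at least a third of samples" expression
   filter, exercising the preprocessing step.

One global seed drives layered sub-seeds (DAG, latents, loadings, noises) via
``numpy.random.SeedSequence.spawn``, so each component is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import PROTEIN, TRANSCRIPT, OmicsMatrix, PairedOmics

__all__ = [
    "Dag",
    "SyntheticTruth",
    "random_dag",
    "simulate_sem",
    "generate_paired_omics",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class Dag:
    """A weighted directed acyclic graph.

    ``nodes`` fixes the variable order used by :func:`simulate_sem`;
    ``edges`` are (parent, child) pairs; ``weights`` maps each edge to its
    linear coefficient.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    weights: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        for parent, child in self.edges:
            if parent == child:
                raise ValueError(f"self-loop on {parent!r}")
            if parent not in node_set or child not in node_set:
                raise ValueError(f"edge ({parent}, {child}) uses unknown node")
        extra = set(self.weights) - set(self.edges)
        if extra:
            raise ValueError(f"weights for non-edges: {sorted(extra)}")
        self.topological_order()  # raises on cycles

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def parents(self, node: str) -> list[str]:
        return sorted(p for (p, c) in self.edges if c == node)

    def children(self, node: str) -> list[str]:
        return sorted(c for (p, c) in self.edges if p == node)

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; raises ValueError on a cycle."""
        indeg = {n: 0 for n in self.nodes}
        for _, child in self.edges:
            indeg[child] += 1
        frontier = [n for n in self.nodes if indeg[n] == 0]
        order: list[str] = []
        while frontier:
            node = frontier.pop()
            order.append(node)
            for child in self.children(node):
                indeg[child] -= 1
                if indeg[child] == 0:
                    frontier.append(child)
        if len(order) != len(self.nodes):
            raise ValueError("graph contains a cycle")
        return order

    def weight_matrix(self) -> np.ndarray:
        """W with W[i, j] = weight of edge nodes[i] -> nodes[j] (0 if absent)."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        W = np.zeros((self.n_nodes, self.n_nodes))
        for (parent, child) in self.edges:
            W[idx[parent], idx[child]] = self.weights.get((parent, child), 0.0)
        return W

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (p, c) in sorted(self.edges):
            g.add_edge(p, c, weight=self.weights.get((p, c), 1.0))
        return g


@dataclass
class SyntheticTruth:
    """Planted ground truth: module labels per feature and the module DAG."""

    module_labels: pd.Series  # feature id -> int label, 0 = background
    dag: Dag
    generation_params: dict

    def __post_init__(self) -> None:
        nonzero = set(int(v) for v in self.module_labels.unique() if v != 0)
        dag_modules = {_module_index(n) for n in self.dag.nodes}
        if not nonzero <= dag_modules:
            raise ValueError("module label without a DAG node")


def _module_index(node: str) -> int:
    """'M3' -> 3 (module node naming convention)."""
    return int(str(node).lstrip("M"))


def _as_generator(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dag(
    n_nodes: int,
    edge_prob: float,
    seed: int | np.random.Generator,
    weight_range: tuple[float, float] = (0.5, 1.5),
) -> Dag:
    """Sample a random weighted DAG.

    A uniformly random node order is drawn and each forward pair is included
    independently with probability ``edge_prob``.  Weight magnitudes are
    uniform on ``weight_range`` (default [0.5, 1.5], bounded away from zero)
    with a random sign.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    if not 0.0 < weight_range[0] < weight_range[1]:
        raise ValueError("weight_range must be positive and increasing")
    rng = _as_generator(seed)
    nodes = tuple(f"M{i + 1}" for i in range(n_nodes))
    order = rng.permutation(n_nodes)
    edges: list[tuple[str, str]] = []
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((nodes[order[a]], nodes[order[b]]))
    magnitudes = rng.uniform(weight_range[0], weight_range[1], size=len(edges))
    signs = rng.choice([-1.0, 1.0], size=len(edges))
    weights = {e: float(m * s) for e, m, s in zip(edges, magnitudes, signs)}
    return Dag(nodes=nodes, edges=frozenset(edges), weights=weights)


def simulate_sem(
    dag: Dag,
    n_samples: int,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw samples from the linear Gaussian SEM defined by ``dag``.

    Each node equals the weighted sum of its parent values plus N(0, noise_sd)
    noise, evaluated in topological order.  Returns samples x nodes, columns
    in ``dag.nodes`` order.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = _as_generator(seed)
    idx = {n: i for i, n in enumerate(dag.nodes)}
    X = np.zeros((n_samples, dag.n_nodes))
    noise = rng.normal(0.0, noise_sd, size=(n_samples, dag.n_nodes))
    for node in dag.topological_order():
        j = idx[node]
        X[:, j] = noise[:, j]
        for parent in dag.parents(node):
            X[:, j] += dag.weights.get((parent, node), 0.0) * X[:, idx[parent]]
    return X


def sem_covariance(dag: Dag, noise_sd: float = 1.0) -> np.ndarray:
    """Analytic SEM covariance (I - W)^-T Sigma_noise (I - W)^-1."""
    W = dag.weight_matrix()
    inv = np.linalg.inv(np.eye(dag.n_nodes) - W)
    return noise_sd**2 * inv.T @ inv


def max_latent_correlation(dag: Dag) -> float:
    """Largest absolute off-diagonal correlation implied by the SEM."""
    cov = sem_covariance(dag)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    off = ~np.eye(dag.n_nodes, dtype=bool)
    return float(np.abs(corr[off]).max()) if dag.n_nodes > 1 else 0.0


def identifiable_module_dag(
    n_nodes: int,
    edge_prob: float,
    seed: int,
    weight_range: tuple[float, float] = (0.5, 1.0),
    max_abs_corr: float = 0.6,
    max_tries: int = 1000,
) -> Dag:
    """Random DAG whose implied latent correlations stay identifiably modular.

    Module eigengenes inherit the latent correlations, and the merge step
    collapses modules whose eigengene correlation exceeds
    ``1 - merge_cut_height`` (0.75 at the default cut of 0.25).  A planted
    partition is therefore only a coherent ground truth when every pairwise
    latent |correlation| stays below that threshold; this helper rejects
    DAG draws (deterministically, given the seed) until the analytic SEM
    correlation satisfies the bound.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        dag = random_dag(n_nodes, edge_prob, rng, weight_range=weight_range)
        if max_latent_correlation(dag) <= max_abs_corr:
            return dag
    raise RuntimeError(
        f"no identifiable DAG found in {max_tries} draws; "
        "lower edge_prob or the weight range"
    )


def generate_paired_omics(
    module_sizes: Sequence[int],
    n_background: int,
    dag: Dag,
    n_samples: int,
    loading_range: tuple[float, float] = (0.8, 1.2),
    feature_noise_sd: float = 0.3,
    layer_agreement: float = 1.0,
    low_expression_fraction: float = 0.3,
    seed: int = 0,
    latent_noise_sd: float = 1.0,
    exponentiate: bool = False,
    missing_fraction: float = 0.0,
) -> tuple[PairedOmics, SyntheticTruth]:
    """Generate matched transcript/protein matrices with planted modules.

    Parameters
    ----------
    module_sizes
        Features per planted module; must match the number of DAG nodes.
    n_background
        Unstructured i.i.d.-noise features appended after the modules
        (the planted analogue of unassigned "module 0" features).
    loading_range
        Interval the per-feature loadings are drawn from; rejected if it
        contains 0 in its interior (the within-module correlation sign would
        be ambiguous).
    layer_agreement
        Fraction of protein-layer module features that share the transcript
        layer's module latent; the rest get an independent latent profile.
    low_expression_fraction
        Fraction of background features rescaled into (0, 1) so the
        minimum-expression filter removes them.
    missing_fraction
        Fraction of features that receive one missing cell in one layer
        (exercises the complete-pairs filter); default 0 = fully observed.
    """
    if len(module_sizes) != dag.n_nodes:
        raise ValueError("one module size per DAG node is required")
    if any(s <= 0 for s in module_sizes):
        raise ValueError("module sizes must be positive")
    if n_background < 0:
        raise ValueError("n_background must be nonnegative")
    if n_samples < 4:
        raise ValueError("n_samples must be at least 4")
    lo, hi = loading_range
    if lo >= hi:
        raise ValueError("loading_range must be an increasing interval")
    if lo < 0.0 < hi:
        raise ValueError(
            "loading_range must not contain 0 in its interior "
            "(within-module correlation sign would be ambiguous)"
        )
    if not 0.0 <= layer_agreement <= 1.0:
        raise ValueError("layer_agreement must lie in [0, 1]")
    if not 0.0 <= low_expression_fraction <= 1.0:
        raise ValueError("low_expression_fraction must lie in [0, 1]")

    ss = np.random.SeedSequence(seed)
    (
        ss_latent,
        ss_load,
        ss_noise_t,
        ss_noise_p,
        ss_disagree,
        ss_background,
        ss_missing,
    ) = (np.random.default_rng(child) for child in ss.spawn(7))

    latents = simulate_sem(dag, n_samples, latent_noise_sd, seed=ss_latent)

    n_module_features = int(sum(module_sizes))
    n_features = n_module_features + n_background
    labels = np.zeros(n_features, dtype=int)
    transcript = np.empty((n_features, n_samples))
    protein = np.empty((n_features, n_samples))

    row = 0
    for j, size in enumerate(module_sizes):
        latent = latents[:, j]
        labels[row : row + size] = j + 1
        load_t = ss_load.uniform(lo, hi, size=size)
        load_p = ss_load.uniform(lo, hi, size=size)
        noise_t = ss_noise_t.normal(0.0, feature_noise_sd, size=(size, n_samples))
        noise_p = ss_noise_p.normal(0.0, feature_noise_sd, size=(size, n_samples))
        transcript[row : row + size] = load_t[:, None] * latent[None, :] + noise_t
        # a subset of protein features tracks an independent latent instead
        n_disagree = int(round((1.0 - layer_agreement) * size))
        protein_latent = np.tile(latent, (size, 1))
        if n_disagree > 0:
            which = ss_disagree.choice(size, size=n_disagree, replace=False)
            protein_latent[which] = ss_disagree.normal(
                0.0, latent_noise_sd, size=(n_disagree, n_samples)
            )
        protein[row : row + size] = load_p[:, None] * protein_latent + noise_p
        row += size

    if n_background:
        transcript[row:] = ss_background.normal(0.0, 1.0, size=(n_background, n_samples))
        protein[row:] = ss_background.normal(0.0, 1.0, size=(n_background, n_samples))

    if exponentiate:
        transcript = np.exp(transcript)
        protein = np.exp(protein)
    else:
        # per-feature shift to a positive abundance scale; preserves
        # correlation structure exactly
        transcript = transcript - transcript.min(axis=1, keepdims=True) + 1.0
        protein = protein - protein.min(axis=1, keepdims=True) + 1.0

    # push a subset of background features below the expression-filter
    # threshold (values in (0, 1) in every sample)
    n_low = int(round(low_expression_fraction * n_background))
    if n_low > 0:
        low_rows = n_module_features + ss_background.choice(
            n_background, size=n_low, replace=False
        )
        for mat in (transcript, protein):
            block = mat[low_rows]
            span = block.max(axis=1, keepdims=True) - block.min(axis=1, keepdims=True)
            span[span == 0.0] = 1.0
            mat[low_rows] = 0.1 + 0.8 * (
                block - block.min(axis=1, keepdims=True)
            ) / span

    if missing_fraction > 0.0:
        n_miss = int(round(missing_fraction * n_features))
        rows = ss_missing.choice(n_features, size=n_miss, replace=False)
        for r in rows:
            layer = transcript if ss_missing.random() < 0.5 else protein
            layer[r, ss_missing.integers(n_samples)] = np.nan

    feature_ids = [f"F{i + 1:05d}" for i in range(n_features)]
    sample_ids = [f"T{i + 1:02d}" for i in range(n_samples)]
    data = PairedOmics(
        OmicsMatrix(TRANSCRIPT, pd.DataFrame(transcript, feature_ids, sample_ids)),
        OmicsMatrix(PROTEIN, pd.DataFrame(protein, feature_ids, sample_ids)),
    )
    truth = SyntheticTruth(
        module_labels=pd.Series(labels, index=feature_ids, name="module"),
        dag=dag,
        generation_params={
            "module_sizes": list(module_sizes),
            "n_background": n_background,
            "n_samples": n_samples,
            "loading_range": [lo, hi],
            "feature_noise_sd": feature_noise_sd,
            "layer_agreement": layer_agreement,
            "low_expression_fraction": low_expression_fraction,
            "latent_noise_sd": latent_noise_sd,
            "exponentiate": exponentiate,
            "missing_fraction": missing_fraction,
            "seed": seed,
        },
    )
    return data, truth


def write_truth(truth: SyntheticTruth, directory: str | Path) -> dict[str, Path]:
    """Write module labels and the DAG edge list as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels_path = directory / "true_modules.tsv"
    dag_path = directory / "true_dag.tsv"
    out = truth.module_labels.rename("module").to_frame()
    out.index.name = "feature"
    out.to_csv(labels_path, sep="\t")
    rows = [
        {"parent": p, "child": c, "weight": truth.dag.weights.get((p, c), 1.0)}
        for (p, c) in sorted(truth.dag.edges)
    ]
    pd.DataFrame(rows, columns=["parent", "child", "weight"]).to_csv(
        dag_path, sep="\t", index=False
    )
    return {"labels": labels_path, "dag": dag_path}


def read_truth(labels_path: str | Path, dag_path: str | Path) -> SyntheticTruth:
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["module"]
    labels.index = labels.index.astype(str)
    edges_df = pd.read_csv(dag_path, sep="\t")
    edges = [(str(r.parent), str(r.child)) for r in edges_df.itertuples()]
    weights = {
        (str(r.parent), str(r.child)): float(r.weight) for r in edges_df.itertuples()
    }
    max_label = int(labels.max()) if len(labels) else 0
    nodes = tuple(f"M{i + 1}" for i in range(max_label))
    dag = Dag(nodes=nodes, edges=frozenset(edges), weights=weights)
    return SyntheticTruth(labels, dag, {})
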