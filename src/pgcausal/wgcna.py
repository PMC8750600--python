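"""Consensus weighted co-expression network construction and module detection.

The pipeline per layer: Pearson correlation across samples -> soft-thresholded
adjacency a_ij (unsigned |r|^beta or signed ((1+r)/2)^beta) -> topological
overlap TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).  Layer TOMs are
quantile-calibrated against the first (transcript) layer and combined by the
element-wise minimum into a consensus TOM; modules are cut out of the
average-linkage dendrogram of 1 - consensusTOM, small clusters dissolved into
label 0, and modules with strongly correlated eigengenes in every layer are
merged.

Module detection uses a quantile-anchored static cut of the dendrogram in
place of the full hybrid dynamic tree cut: the cut height is
``q + f(deep_split) * (max_height - q)`` with q the 0.05 quantile of merge
heights and f mapping sensitivity 0..4 to {0.95, 0.90, 0.80, 0.70, 0.55}
(higher sensitivity => lower cut => more, smaller clusters).  This keeps the
user-facing knobs (minimum module size, sensitivity, merge cut height) while
staying transparent and testable on planted data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

UNSIGNED = "unsigned"
SIGNED = "signed"

DEFAULT_POWERS: tuple[int, ...] = tuple(range(1, 11)) + (12, 14, 16, 18, 20)

_DEEP_SPLIT_FACTOR = {0: 0.95, 1: 0.90, 2: 0.80, 3: 0.70, 4: 0.55}


@dataclass
class Network:
    """Weighted network on a fixed feature order."""

    feature_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray | None = None

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum of adjacency to all other nodes."""
        return self.adjacency.sum(axis=0) - np.diag(self.adjacency)


@dataclass
class SoftThresholdReport:
    powers: list[float]
    signed_r2: pd.DataFrame  # powers x layers
    mean_connectivity: pd.DataFrame  # powers x layers
    chosen_power: float | None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"power": self.powers})
        for layer in self.signed_r2.columns:
            out[f"signed_r2_{layer}"] = self.signed_r2[layer].to_numpy()
            out[f"mean_connectivity_{layer}"] = self.mean_connectivity[
                layer
            ].to_numpy()
        return out

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ModulePartition:
    """Per-feature module labels; 0 marks unassigned features."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(int)
        if (self.labels < 0).any():
            raise ValueError("module labels must be nonnegative")

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    @property
    def sizes(self) -> dict[int, int]:
        counts = self.labels.value_counts()
        return {int(m): int(counts[m]) for m in self.module_ids}

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def write(self, path: str | Path) -> None:
        out = self.labels.rename("module").to_frame()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "ModulePartition":
        labels = pd.read_csv(path, sep="\t", index_col=0)["module"]
        labels.index = labels.index.astype(str)
        return cls(labels)


def _correlation(expr: OmicsMatrix) -> np.ndarray:
    vals = expr.values.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("missing values present; filter before networking")
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = [f for f, s in zip(expr.feature_ids, sd) if s == 0]
        raise ValueError(f"zero-variance features: {bad[:5]}")
    r = np.corrcoef(vals)
    return np.clip(r, -1.0, 1.0)


def adjacency_from_expression(
    expr: OmicsMatrix, power: float, network_type: str = UNSIGNED
) -> Network:
    """Soft-thresholded adjacency from Pearson correlations across samples."""
    if power < 1:
        raise ValueError("power must be >= 1")
    if expr.n_samples < 3:
        raise ValueError("at least 3 samples are required")
    r = _correlation(expr)
    if network_type == UNSIGNED:
        a = np.abs(r) ** power
    elif network_type == SIGNED:
        a = ((1.0 + r) / 2.0) ** power
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return Network(expr.feature_ids, a)


def scale_free_fit(connectivities: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Bins connectivity into ``n_bins`` equal-width bins, regresses
    log10(mean frequency) on log10(mean k) over non-empty bins, and returns
    sign(-slope) * R^2 — positive when the degree distribution decays.
    """
    k = np.asarray(connectivities, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.allclose(k, k[0]):
        warnings.warn("connectivities are constant; scale-free fit undefined")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 2:
        warnings.warn("fewer than 2 non-empty connectivity bins")
        return 0.0
    if np.allclose(ys, ys[0]):
        return 0.0  # flat degree distribution: zero slope, zero fit
    slope, _, r_value, _, _ = stats.linregress(xs, ys)
    if not np.isfinite(r_value):
        return 0.0
    return float(np.sign(-slope) * r_value**2)


def pick_soft_threshold(
    expr_layers: Sequence[OmicsMatrix],
    powers: Sequence[float] = DEFAULT_POWERS,
    r2_cut: float = 0.85,
    network_type: str = UNSIGNED,
) -> SoftThresholdReport:
    """Scan candidate powers and choose the smallest whose cross-layer
    minimum signed scale-free fit reaches ``r2_cut`` (None if no power
    qualifies; the pipeline then falls back to a configured default)."""
    if not powers:
        raise ValueError("empty candidate power list")
    feature_sets = {tuple(l.feature_ids) for l in expr_layers}
    if len(feature_sets) != 1:
        raise ValueError("layers must share an identical feature set")
    corrs = [_correlation(l) for l in expr_layers]
    layer_names = [l.layer for l in expr_layers]
    r2 = np.zeros((len(powers), len(expr_layers)))
    mean_k = np.zeros_like(r2)
    for pi, power in enumerate(powers):
        for li, r in enumerate(corrs):
            if network_type == UNSIGNED:
                a = np.abs(r) ** power
            else:
                a = ((1.0 + r) / 2.0) ** power
            np.fill_diagonal(a, 1.0)
            k = a.sum(axis=0) - 1.0
            r2[pi, li] = scale_free_fit(k)
            mean_k[pi, li] = k.mean()
    chosen: float | None = None
    for pi, power in enumerate(powers):
        if r2[pi].min() >= r2_cut:
            chosen = float(power)
            break
    return SoftThresholdReport(
        powers=[float(p) for p in powers],
        signed_r2=pd.DataFrame(r2, index=list(powers), columns=layer_names),
        mean_connectivity=pd.DataFrame(
            mean_k, index=list(powers), columns=layer_names
        ),
        chosen_power=chosen,
    )


def tom_from_adjacency(net: Network) -> Network:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)."""
    a = net.adjacency
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=0) - np.diag(a)
    # l_ij = sum_{u != i,j} a_iu a_uj ; with unit diagonal (A@A)_ij counts
    # u=i and u=j as a_ij each
    l = a @ a - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return Network(net.feature_ids, a, tom)


def consensus_tom(
    toms: Sequence[np.ndarray], calibration_quantile: float = 0.95
) -> np.ndarray:
    """Quantile-calibrate layer TOMs to the first layer and take the
    element-wise minimum."""
    if not toms:
        raise ValueError("no TOM matrices given")
    shapes = {t.shape for t in toms}
    if len(shapes) != 1:
        raise ValueError("TOM matrices differ in shape")
    off = ~np.eye(toms[0].shape[0], dtype=bool)
    ref_q = float(np.quantile(toms[0][off], calibration_quantile))
    calibrated = [np.asarray(toms[0], dtype=float)]
    for t in toms[1:]:
        q = float(np.quantile(t[off], calibration_quantile))
        if ref_q <= 0.0 or q <= 0.0:
            warnings.warn("calibration quantile is zero; skipping calibration")
            calibrated.append(np.asarray(t, dtype=float))
        else:
            calibrated.append(np.minimum(t * (ref_q / q), 1.0))
    cons = np.minimum.reduce(calibrated)
    np.fill_diagonal(cons, 1.0)
    return cons


def detect_modules(
    consensus_dissimilarity: np.ndarray,
    feature_ids: Sequence[str],
    min_module_size: int = 30,
    deep_split: int = 2,
) -> ModulePartition:
    """Cut the average-linkage dendrogram of the consensus dissimilarity.

    Clusters smaller than ``min_module_size`` are dissolved into label 0;
    surviving clusters are relabeled 1..m by decreasing size.
    """
    if deep_split not in _DEEP_SPLIT_FACTOR:
        raise ValueError("deep_split must be in 0..4")
    d = np.asarray(consensus_dissimilarity, dtype=float)
    n = d.shape[0]
    if n != len(feature_ids):
        raise ValueError("dissimilarity size does not match feature_ids")
    if n < min_module_size:
        return ModulePartition(pd.Series(0, index=list(feature_ids)))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = link[:, 2]
    q = float(np.quantile(heights, 0.05))
    h_max = float(heights.max())
    cut = q + _DEEP_SPLIT_FACTOR[deep_split] * (h_max - q)
    raw = hierarchy.fcluster(link, t=cut, criterion="distance")
    return _relabel_by_size(raw, feature_ids, min_module_size)


def _relabel_by_size(
    raw_labels: np.ndarray, feature_ids: Sequence[str], min_module_size: int
) -> ModulePartition:
    labels = np.zeros(len(raw_labels), dtype=int)
    sizes: list[tuple[int, int]] = []
    for cluster in np.unique(raw_labels):
        size = int((raw_labels == cluster).sum())
        if size >= min_module_size:
            sizes.append((int(cluster), size))
    # decreasing size; stable tie-break on the original cluster id
    sizes.sort(key=lambda cs: (-cs[1], cs[0]))
    for new_label, (cluster, _) in enumerate(sizes, start=1):
        labels[raw_labels == cluster] = new_label
    return ModulePartition(pd.Series(labels, index=list(feature_ids)))


def module_eigengene(expr: OmicsMatrix, member_ids: Sequence[str]) -> np.ndarray:
    """First principal component of the standardized module submatrix.

    Returned as a unit-norm per-sample vector, sign-aligned so that its
    correlation with the mean standardized member profile is nonnegative.
    """
    members = list(member_ids)
    if not members:
        raise ValueError("empty module")
    if expr.n_samples < 3:
        raise ValueError("at least 3 samples are required")
    X = expr.values.loc[members].to_numpy()
    sd = X.std(axis=1)
    if (sd == 0).any():
        raise ValueError("zero-variance member feature")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector = PC1 scores over samples
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    eig = eig / np.linalg.norm(eig)
    mean_profile = Z.mean(axis=0)
    if float(eig @ mean_profile) < 0:
        eig = -eig
    return eig


def merge_close_modules(
    expr_layers: Sequence[OmicsMatrix],
    partition: ModulePartition,
    cut_height: float = 0.25,
) -> ModulePartition:
    """Iteratively merge modules whose eigengenes are close in every layer.

    Module-module dissimilarity = max over layers of (1 - cor(eig_p, eig_q));
    average-linkage clusters joined below ``cut_height`` are merged.  Repeats
    until no merge occurs, then relabels modules 1..m by decreasing size.
    """
    labels = partition.labels.copy()
    while True:
        modules = sorted(int(m) for m in labels.unique() if m != 0)
        if len(modules) < 2:
            break
        diss = np.zeros((len(modules), len(modules)))
        for layer in expr_layers:
            eigs = np.array(
                [
                    module_eigengene(layer, list(labels.index[labels == m]))
                    for m in modules
                ]
            )
            cors = np.clip(np.corrcoef(eigs), -1.0, 1.0)
            diss = np.maximum(diss, 1.0 - cors)
        np.fill_diagonal(diss, 0.0)
        link = hierarchy.linkage(squareform(diss, checks=False), method="average")
        groups = hierarchy.fcluster(link, t=cut_height, criterion="distance")
        if len(np.unique(groups)) == len(modules):
            break
        remap = {}
        for module, group in zip(modules, groups):
            target = min(m for m, g in zip(modules, groups) if g == group)
            remap[module] = target
        labels = labels.map(lambda m: remap.get(int(m), 0) if m != 0 else 0)
        logger.info("merged modules: %d -> %d", len(modules), len(set(remap.values())))
    # final relabel by decreasing size
    counts = labels[labels != 0].value_counts()
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    final_map = {int(m): i + 1 for i, m in enumerate(order)}
    labels = labels.map(lambda m: final_map.get(int(m), 0))
    return ModulePartition(labels)


def consensus_modules(
    expr_layers: Sequence[OmicsMatrix],
    power: float,
    network_type: str = UNSIGNED,
    calibration_quantile: float = 0.95,
    min_module_size: int = 30,
    deep_split: int = 2,
    merge_cut_height: float = 0.25,
) -> ModulePartition:
    """Full consensus module detection across layers (adjacency -> TOM ->
    calibrated consensus -> dendrogram cut -> eigengene-based merging)."""
    toms = []
    for layer in expr_layers:
        net = adjacency_from_expression(layer, power, network_type)
        toms.append(tom_from_adjacency(net).tom)
    cons = consensus_tom(toms, calibration_quantile)
    partition = detect_modules(
        1.0 - cons,
        expr_layers[0].feature_ids,
        min_module_size=min_module_size,
        deep_split=deep_split,
    )
    if partition.n_modules >= 2:
        partition = merge_close_modules(expr_layers, partition, merge_cut_height)
    return partition
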