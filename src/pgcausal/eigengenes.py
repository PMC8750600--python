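"""Eigengene networks, cross-layer preservation, and module summary profiles.

An eigengene network is the module-by-module adjacency
``A_pq = (1 + cor(E_p, E_q)) / 2`` computed within one omics layer; the
preservation between two layers' networks is ``P = 1 - |A - B|`` element-wise.
Mean preservation per module (column means excluding the diagonal) quantifies
how consistently a module relates to all others across layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import OmicsMatrix
from .wgcna import ModulePartition, module_eigengene

__all__ = [
    "EigengeneMatrix",
    "EigengeneNetwork",
    "consensus_eigengenes",
    "eigengene_adjacency",
    "preservation_network",
    "mean_preservation",
    "module_zscore_profiles",
    "eigengene_tissue_clustering",
]


@dataclass
class EigengeneMatrix:
    """Per-layer module eigengenes: modules x samples, unit-norm rows."""

    layer: str
    values: pd.DataFrame  # index = module ids (int), columns = sample ids

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.values.to_numpy(), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("eigengene rows must have unit Euclidean norm")

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.values.index]

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "module"
        out.to_csv(path, sep="\t")


@dataclass
class EigengeneNetwork:
    layer: str
    adjacency: pd.DataFrame  # modules x modules in [0, 1]

    def __post_init__(self) -> None:
        a = self.adjacency.to_numpy()
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("eigengene adjacency must be symmetric")

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.adjacency.index]


def consensus_eigengenes(
    expr: OmicsMatrix, partition: ModulePartition
) -> EigengeneMatrix:
    """Eigengene of every nonzero module of ``partition`` in one layer."""
    modules = partition.module_ids
    if not modules:
        raise ValueError("partition has no modules")
    rows = [module_eigengene(expr, partition.members(m)) for m in modules]
    return EigengeneMatrix(
        expr.layer,
        pd.DataFrame(np.array(rows), index=modules, columns=expr.sample_ids),
    )


def eigengene_adjacency(eig: EigengeneMatrix) -> EigengeneNetwork:
    """A_pq = (1 + cor(E_p, E_q)) / 2."""
    vals = eig.values.to_numpy()
    if vals.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    if (vals.std(axis=1) == 0).any():
        raise ValueError("zero-variance eigengene")
    cor = np.clip(np.corrcoef(vals), -1.0, 1.0)
    adj = (1.0 + cor) / 2.0
    np.fill_diagonal(adj, 1.0)
    return EigengeneNetwork(
        eig.layer, pd.DataFrame(adj, index=eig.values.index, columns=eig.values.index)
    )


def preservation_network(
    net_a: EigengeneNetwork, net_b: EigengeneNetwork
) -> pd.DataFrame:
    """P_pq = 1 - |A_pq - B_pq| (one minus the absolute adjacency difference)."""
    if net_a.module_ids != net_b.module_ids:
        raise ValueError("networks are defined on different module sets")
    return 1.0 - (net_a.adjacency - net_b.adjacency).abs()


def mean_preservation(pres: pd.DataFrame) -> pd.Series:
    """Column means of the preservation matrix, excluding the diagonal."""
    p = pres.to_numpy()
    if p.shape[0] != p.shape[1]:
        raise ValueError("preservation matrix must be square")
    if p.shape[0] < 2:
        raise ValueError("mean preservation needs at least 2 modules")
    mask = ~np.eye(p.shape[0], dtype=bool)
    means = (p * mask).sum(axis=0) / (p.shape[0] - 1)
    return pd.Series(means, index=pres.columns, name="mean_preservation")


def module_zscore_profiles(
    expr: OmicsMatrix, partition: ModulePartition
) -> pd.DataFrame:
    """Per-module mean z-score trend across samples.

    Each feature is z-scored across samples (zero-variance features
    contribute all-zero rows); a module profile is the per-sample mean over
    member features.
    """
    vals = expr.values.to_numpy()
    if np.isnan(vals).any():
        raise ValueError("missing values present")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, 0.0)
    zdf = pd.DataFrame(z, index=expr.feature_ids, columns=expr.sample_ids)
    profiles = {}
    for m in partition.module_ids:
        members = partition.members(m)
        if not members:
            raise ValueError(f"module {m} is empty")
        profiles[m] = zdf.loc[members].mean(axis=0)
    return pd.DataFrame(profiles).T.rename_axis("module")


def eigengene_tissue_clustering(
    eig: EigengeneMatrix,
) -> tuple[list[int], np.ndarray]:
    """Complete-linkage hierarchical clustering of modules (rows) under
    Euclidean distance.  Samples (columns) are never reordered.

    Returns (leaf order as module ids, scipy linkage matrix).
    """
    if len(eig.module_ids) < 2:
        raise ValueError("clustering needs at least 2 modules")
    link = hierarchy.linkage(pdist(eig.values.to_numpy()), method="complete")
    order = hierarchy.leaves_list(link)
    return [eig.module_ids[i] for i in order], link
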