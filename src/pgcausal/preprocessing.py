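"""Filtering of paired omics data and per-pair RNA-protein correlation.

The filtering chain keeps only transcript-protein pairs that are (a) fully
observed in every sample in both layers and (b) expressed above a threshold
(strictly greater than 1 by default) in at least a third of samples in both
layers.  Both filters act on the pair: a feature failing in either layer is
removed from both, so the layers always stay aligned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PairedOmics

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelationSummary",
    "filter_complete_pairs",
    "filter_min_expression",
    "default_min_samples",
    "good_features",
    "pair_spearman_summary",
    "FilterReport",
]


@dataclass
class PairCorrelationSummary:
    """Per-pair Spearman correlations between transcript and protein profiles."""

    per_pair_rho: pd.Series
    mean_rho: float
    n_positive: int
    n_total: int


@dataclass
class FilterReport:
    """Feature counts before/after each filtering step."""

    steps: list[tuple[str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_features"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_complete_pairs(data: PairedOmics) -> PairedOmics:
    """Keep features with no missing value in any sample in both layers."""
    complete = (
        data.transcript.values.notna().all(axis=1)
        & data.protein.values.notna().all(axis=1)
    )
    kept = [f for f, ok in zip(data.feature_ids, complete) if ok]
    if not kept:
        logger.warning("complete-pairs filter removed every feature")
    return data.subset(kept)


def default_min_samples(n_samples: int) -> int:
    """One out of three samples, rounded up (5 for 15 samples)."""
    return math.ceil(n_samples / 3)


def filter_min_expression(
    data: PairedOmics,
    threshold: float = 1.0,
    min_samples: int | None = None,
) -> PairedOmics:
    """Keep features exceeding ``threshold`` (strictly) in at least
    ``min_samples`` samples in *both* layers.

    ``min_samples`` defaults to ``ceil(n_samples / 3)``.
    """
    if min_samples is None:
        min_samples = default_min_samples(data.n_samples)
    if min_samples <= 0:
        raise ValueError("min_samples must be positive")
    if min_samples > data.n_samples:
        raise ValueError("min_samples exceeds the number of samples")
    passes = (
        ((data.transcript.values > threshold).sum(axis=1) >= min_samples)
        & ((data.protein.values > threshold).sum(axis=1) >= min_samples)
    )
    kept = [f for f, ok in zip(data.feature_ids, passes) if ok]
    if not kept:
        logger.warning("minimum-expression filter removed every feature")
    return data.subset(kept)


def good_features(data: PairedOmics) -> pd.Series:
    """Boolean mask: False for features with any missing value or zero
    variance across samples in either layer."""
    mask = pd.Series(True, index=data.feature_ids)
    for layer in data.layers:
        vals = layer.values
        mask &= vals.notna().all(axis=1)
        mask &= vals.std(axis=1, ddof=0) > 0
    return mask


def pair_spearman_summary(data: PairedOmics) -> PairCorrelationSummary:
    """Spearman rank correlation between each feature's transcript and
    protein profile across samples (average ranks for ties)."""
    if data.n_samples < 3:
        raise ValueError("Spearman summary requires at least 3 samples")
    t = data.transcript.values.to_numpy()
    p = data.protein.values.to_numpy()
    if np.isnan(t).any() or np.isnan(p).any():
        raise ValueError("missing values present; filter before correlating")
    rt = stats.rankdata(t, axis=1)
    rp = stats.rankdata(p, axis=1)
    rt = rt - rt.mean(axis=1, keepdims=True)
    rp = rp - rp.mean(axis=1, keepdims=True)
    denom = np.sqrt((rt**2).sum(axis=1) * (rp**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (rt * rp).sum(axis=1) / denom, np.nan)
    per_pair = pd.Series(rho, index=data.feature_ids, name="spearman_rho")
    return PairCorrelationSummary(
        per_pair_rho=per_pair,
        mean_rho=float(np.nanmean(rho)) if len(rho) else float("nan"),
        n_positive=int(np.nansum(rho > 0)),
        n_total=int(len(rho)),
    )


def apply_standard_filters(
    data: PairedOmics,
    threshold: float = 1.0,
    min_samples: int | None = None,
) -> tuple[PairedOmics, FilterReport]:
    """Complete-pairs filter then minimum-expression filter, with a report."""
    steps = [("input", data.n_features)]
    data = filter_complete_pairs(data)
    steps.append(("complete_pairs", data.n_features))
    data = filter_min_expression(data, threshold=threshold, min_samples=min_samples)
    steps.append(("min_expression", data.n_features))
    report = FilterReport(steps)
    for step, count in steps:
        logger.info("filter step %-16s -> %d features", step, count)
    return data, report
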