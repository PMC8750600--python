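"""Configuration-driven end-to-end runner.

Stage order: (optional) simulation -> filtering -> soft-threshold selection ->
consensus module detection -> eigengene networks / preservation -> PC causal
graph over module eigengenes -> summary manifest.  Every stage's output is
written as TSV before the next stage runs, so any stage can be re-loaded and
resumed; the manifest records feature counts, the chosen power, module sizes,
the CPDAG summary and, for simulated input with known truth, the adjusted
Rand index of module recovery and the structural Hamming distance to the
planted CPDAG.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import causal, eigengenes, preprocessing, synthetic, wgcna
from .containers import PairedOmics, read_paired_omics, write_paired_omics

logger = logging.getLogger(__name__)

STACK_MODES = ("stacked", "transcript", "protein")


@dataclass
class PipelineConfig:
    """All pipeline knobs; every analysis parameter is explicit."""

    output_dir: str = "pgcausal_run"
    seed: int = 0

    # input: either simulate=True, or both TSV paths set
    simulate: bool = True
    transcript_tsv: str | None = None
    protein_tsv: str | None = None
    truth_labels_tsv: str | None = None
    truth_dag_tsv: str | None = None

    # simulation parameters
    module_sizes: list[int] = field(default_factory=lambda: [60, 60, 60, 60, 60])
    n_background: int = 40
    edge_prob: float = 0.4
    n_samples: int = 15
    loading_range: tuple[float, float] = (0.8, 1.2)
    feature_noise_sd: float = 0.5
    layer_agreement: float = 1.0
    low_expression_fraction: float = 0.3
    missing_fraction: float = 0.0

    # filtering
    expression_threshold: float = 1.0
    min_samples: int | None = None  # None = ceil(n_samples / 3)

    # network construction
    network_type: str = wgcna.UNSIGNED
    powers: list[float] = field(default_factory=lambda: list(wgcna.DEFAULT_POWERS))
    r2_cut: float = 0.85
    fallback_power: float = 9.0
    calibration_quantile: float = 0.95
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25

    # causal stage
    alpha: float = 0.05
    eigengene_stacking: str = "stacked"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.merge_cut_height < 1.0:
            raise ValueError("merge_cut_height must lie in (0, 1)")
        if self.eigengene_stacking not in STACK_MODES:
            raise ValueError(f"eigengene_stacking must be one of {STACK_MODES}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "loading_range" in raw:
            raw["loading_range"] = tuple(raw["loading_range"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _echo_parameters(config: PipelineConfig) -> None:
    for f in dataclasses.fields(config):
        logger.info("config %-24s = %r", f.name, getattr(config, f.name))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full stage sequence; returns the run manifest."""
    _echo_parameters(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "artifacts": {}, "stages": {}}

    data, truth = _stage_input(config, out, manifest)
    data, report = _stage_filter(config, out, manifest, data)
    power = _stage_soft_threshold(config, out, manifest, data)
    partition = _stage_modules(config, out, manifest, data, power, truth)
    eig_layers = _stage_networks(config, out, manifest, data, partition)
    _stage_causal(config, out, manifest, partition, eig_layers, truth)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["artifacts"]["manifest"] = "manifest.json"
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["loading_range"] = list(d["loading_range"])
    # paths are machine-local; keep the manifest comparable across runs
    d.pop("output_dir")
    return d


def _stage_input(config, out, manifest):
    truth = None
    if config.simulate:
        # bounded weights + analytic correlation cap keep the planted
        # partition identifiable under the eigengene merge rule
        dag = synthetic.identifiable_module_dag(
            len(config.module_sizes),
            config.edge_prob,
            seed=config.seed,
            max_abs_corr=min(0.6, 1.0 - config.merge_cut_height - 0.05),
        )
        data, truth = synthetic.generate_paired_omics(
            module_sizes=config.module_sizes,
            n_background=config.n_background,
            dag=dag,
            n_samples=config.n_samples,
            loading_range=config.loading_range,
            feature_noise_sd=config.feature_noise_sd,
            layer_agreement=config.layer_agreement,
            low_expression_fraction=config.low_expression_fraction,
            missing_fraction=config.missing_fraction,
            seed=config.seed,
        )
        write_paired_omics(data, out / "data")
        synthetic.write_truth(truth, out / "data")
        manifest["artifacts"]["transcript"] = "data/transcript.tsv"
        manifest["artifacts"]["protein"] = "data/protein.tsv"
        manifest["artifacts"]["true_modules"] = "data/true_modules.tsv"
        manifest["artifacts"]["true_dag"] = "data/true_dag.tsv"
        manifest["stages"]["simulate"] = {
            "n_features": data.n_features,
            "n_samples": data.n_samples,
            "n_dag_edges": len(dag.edges),
        }
    else:
        if not (config.transcript_tsv and config.protein_tsv):
            raise StageError("input", "missing_paths", "both layer TSVs required")
        data = read_paired_omics(config.transcript_tsv, config.protein_tsv)
        if config.truth_labels_tsv and config.truth_dag_tsv:
            truth = synthetic.read_truth(
                config.truth_labels_tsv, config.truth_dag_tsv
            )
        manifest["stages"]["load"] = {
            "n_features": data.n_features,
            "n_samples": data.n_samples,
        }
    return data, truth


def _stage_filter(config, out, manifest, data):
    try:
        filtered, report = preprocessing.apply_standard_filters(
            data,
            threshold=config.expression_threshold,
            min_samples=config.min_samples,
        )
    except ValueError as err:
        raise StageError("filter", "invalid_parameters", str(err)) from err
    report.write(out / "filter_report.tsv")
    write_paired_omics(filtered, out / "filtered")
    manifest["artifacts"]["filter_report"] = "filter_report.tsv"
    manifest["artifacts"]["filtered_transcript"] = "filtered/transcript.tsv"
    manifest["artifacts"]["filtered_protein"] = "filtered/protein.tsv"
    manifest["stages"]["filter"] = {step: n for step, n in report.steps}
    if filtered.n_features == 0:
        raise StageError("filter", "empty_result", "all features filtered out")
    summary = preprocessing.pair_spearman_summary(filtered)
    manifest["stages"]["pair_correlation"] = {
        "mean_spearman_rho": round(summary.mean_rho, 6),
        "n_positive": summary.n_positive,
        "n_total": summary.n_total,
    }
    return filtered, report


def _stage_soft_threshold(config, out, manifest, data):
    report = wgcna.pick_soft_threshold(
        list(data.layers),
        powers=config.powers,
        r2_cut=config.r2_cut,
        network_type=config.network_type,
    )
    report.write(out / "soft_threshold.tsv")
    manifest["artifacts"]["soft_threshold"] = "soft_threshold.tsv"
    power = report.chosen_power
    fallback_used = power is None
    if fallback_used:
        power = config.fallback_power
        logger.warning(
            "no power reached r2_cut=%.2f; falling back to %.0f",
            config.r2_cut,
            power,
        )
    manifest["stages"]["soft_threshold"] = {
        "chosen_power": power,
        "fallback_used": fallback_used,
    }
    return power


def _stage_modules(config, out, manifest, data, power, truth):
    partition = wgcna.consensus_modules(
        list(data.layers),
        power=power,
        network_type=config.network_type,
        calibration_quantile=config.calibration_quantile,
        min_module_size=config.min_module_size,
        deep_split=config.deep_split,
        merge_cut_height=config.merge_cut_height,
    )
    partition.write(out / "modules.tsv")
    manifest["artifacts"]["modules"] = "modules.tsv"
    stage = {
        "n_modules": partition.n_modules,
        "module_sizes": partition.sizes,
        "n_unassigned": int((partition.labels == 0).sum()),
    }
    if truth is not None:
        true_labels = truth.module_labels.loc[partition.labels.index]
        stage["adjusted_rand_index"] = round(
            float(adjusted_rand_score(true_labels, partition.labels)), 6
        )
    manifest["stages"]["modules"] = stage
    return partition


def _stage_networks(config, out, manifest, data, partition):
    if partition.n_modules < 2:
        logger.warning("fewer than 2 modules; eigengene networks skipped")
        manifest["stages"]["networks"] = {"skipped": "fewer than 2 modules"}
        return None
    eig_layers = [
        eigengenes.consensus_eigengenes(layer, partition) for layer in data.layers
    ]
    nets = []
    for eig in eig_layers:
        eig.write(out / f"eigengenes_{eig.layer}.tsv")
        manifest["artifacts"][f"eigengenes_{eig.layer}"] = (
            f"eigengenes_{eig.layer}.tsv"
        )
        net = eigengenes.eigengene_adjacency(eig)
        net.adjacency.rename_axis("module").to_csv(
            out / f"eigengene_network_{eig.layer}.tsv", sep="\t"
        )
        manifest["artifacts"][f"eigengene_network_{eig.layer}"] = (
            f"eigengene_network_{eig.layer}.tsv"
        )
        nets.append(net)
    pres = eigengenes.preservation_network(nets[0], nets[1])
    pres.rename_axis("module").to_csv(out / "preservation.tsv", sep="\t")
    mean_pres = eigengenes.mean_preservation(pres)
    mean_pres.rename_axis("module").to_csv(out / "mean_preservation.tsv", sep="\t")
    manifest["artifacts"]["preservation"] = "preservation.tsv"
    manifest["artifacts"]["mean_preservation"] = "mean_preservation.tsv"
    for layer in data.layers:
        profiles = eigengenes.module_zscore_profiles(layer, partition)
        profiles.to_csv(out / f"zscore_profiles_{layer.layer}.tsv", sep="\t")
        manifest["artifacts"][f"zscore_profiles_{layer.layer}"] = (
            f"zscore_profiles_{layer.layer}.tsv"
        )
    manifest["stages"]["networks"] = {
        "mean_preservation": {
            str(m): round(float(v), 6) for m, v in mean_pres.items()
        }
    }
    return eig_layers


def _stage_causal(config, out, manifest, partition, eig_layers, truth):
    if eig_layers is None or partition.n_modules < 2:
        logger.warning("causal stage skipped: fewer than 2 modules")
        manifest["stages"]["causal"] = {"skipped": "fewer than 2 modules"}
        return
    suff = eigengene_suff_stat(eig_layers, config.eigengene_stacking)
    cpdag = causal.pc(suff, alpha=config.alpha)
    causal.write_cpdag_tsv(cpdag, out / "cpdag_edges.tsv")
    (out / "cpdag.dot").write_text(causal.cpdag_to_dot(cpdag) + "\n")
    manifest["artifacts"]["cpdag_edges"] = "cpdag_edges.tsv"
    manifest["artifacts"]["cpdag_dot"] = "cpdag.dot"
    summary = causal.summarize_cpdag(cpdag)
    stage = {
        "n": suff.n,
        "n_directed": summary.n_directed,
        "n_undirected": summary.n_undirected,
        "n_connected_subgraphs": summary.n_connected_subgraphs,
        "effect_only_modules": list(summary.effect_only_nodes),
    }
    if truth is not None:
        shd = _shd_to_truth(cpdag, partition, truth)
        stage["shd_to_planted_cpdag"] = shd
    manifest["stages"]["causal"] = stage


def eigengene_suff_stat(
    eig_layers: list[eigengenes.EigengeneMatrix], mode: str = "stacked"
) -> causal.CiSuffStat:
    """Observation matrix for the CI tests over module eigengenes.

    ``stacked`` concatenates the transcript- and protein-layer eigengene
    sample vectors (n = 2 x samples); ``transcript``/``protein`` use a single
    layer (n = samples).
    """
    by_layer = {e.layer: e for e in eig_layers}
    if mode == "stacked":
        mats = [e.values.to_numpy() for e in eig_layers]
        obs = np.hstack(mats).T  # (layers * samples) x modules
    elif mode in by_layer:
        obs = by_layer[mode].values.to_numpy().T
    else:
        raise ValueError(f"unknown stacking mode {mode!r}")
    labels = tuple(f"M{m}" for m in eig_layers[0].module_ids)
    return causal.suff_stat_from_observations(obs, labels)


def match_modules(
    partition: wgcna.ModulePartition, true_labels: pd.Series
) -> dict[str, str] | None:
    """Majority-overlap matching of detected modules to planted modules.

    Returns a detected->planted node-name map when the matching is a
    bijection onto the planted modules, else None.
    """
    true_labels = true_labels.loc[partition.labels.index]
    mapping: dict[str, str] = {}
    used: set[int] = set()
    for m in partition.module_ids:
        members = partition.labels == m
        overlap = true_labels[members]
        overlap = overlap[overlap != 0]
        if overlap.empty:
            return None
        counts = overlap.value_counts()
        best = int(counts.idxmax())
        if best in used:
            return None
        used.add(best)
        mapping[f"M{m}"] = f"M{best}"
    planted = {int(v) for v in true_labels.unique() if v != 0}
    if used != planted:
        return None
    return mapping


def _shd_to_truth(cpdag, partition, truth) -> int | None:
    mapping = match_modules(partition, truth.module_labels)
    if mapping is None:
        logger.warning("no bijective module match to truth; SHD unavailable")
        return None
    renamed = causal.Cpdag(
        tuple(mapping[n] for n in cpdag.nodes),
        frozenset((mapping[a], mapping[b]) for a, b in cpdag.directed_edges),
        frozenset(
            frozenset(mapping[v] for v in pair) for pair in cpdag.undirected_edges
        ),
    )
    return causal.structural_hamming_distance(
        renamed, causal.dag_to_cpdag(truth.dag)
    )
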