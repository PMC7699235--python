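"""End-to-end orchestration: simulate/load -> screen -> network -> modules.

A run is described by a :class:`RunConfig` (usually loaded from JSON):
either file paths to OTU/metabolite/trait tables or a synthetic-cohort
block, plus per-stage parameter blocks and one global seed. The global
seed fans out deterministically to stage-specific child seeds, so a stage
can be rerun in isolation and reproduce the full run's output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import corrnet, preprocess, simulate, topology, wgcna
from .io import (
    MergedDataset,
    TraitTable,
    merge_tables,
    read_feature_table,
    read_trait_table,
    write_network,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_network_pipeline", "run_wgcna_pipeline", "load_dataset"]


def _child_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from one global seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


@dataclasses.dataclass
class RunConfig:
    """Inputs + per-stage parameters for a pipeline run.

    Exactly one of ``inputs`` (paths to otus/metabolites/traits TSVs) and
    ``synth`` (a :class:`~gutnet.simulate.SynthConfig` block) must be set.
    """

    outdir: str | Path = "gutnet_out"
    seed: int = 0
    inputs: dict[str, str] | None = None
    synth: dict[str, Any] | None = None
    thresholds: dict[str, Any] = dataclasses.field(default_factory=dict)
    network: dict[str, Any] = dataclasses.field(default_factory=dict)
    topology: dict[str, Any] = dataclasses.field(default_factory=dict)
    wgcna: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synth is None):
            raise ValueError("exactly one of 'inputs' and 'synth' must be given")
        if self.inputs is not None:
            missing = {"otus", "metabolites", "traits"} - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing keys: {sorted(missing)}")
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"{key} table not found: {path}")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload.update(overrides)
        return cls(**payload)


def load_dataset(config: RunConfig) -> MergedDataset:
    """Materialize the dataset a config points at (files or simulation)."""
    if config.synth is not None:
        synth = dict(config.synth)
        if synth.pop("fixture_44", False):
            return simulate.fixture_44(seed=synth.get("seed", config.seed))
        synth.setdefault("seed", config.seed)
        if "module_sizes" in synth:
            synth["module_sizes"] = tuple(synth["module_sizes"])
        dataset, _ = simulate.generate_study(simulate.SynthConfig(**synth))
        return dataset
    otus = read_feature_table(config.inputs["otus"], kind="OTU")
    mets = read_feature_table(config.inputs["metabolites"], kind="metabolite")
    table = merge_tables(otus, mets)
    traits = read_trait_table(config.inputs["traits"])
    traits = TraitTable(
        traits.condition.reindex(table.sample_ids),
        traits.treatment.reindex(table.sample_ids),
    )
    return MergedDataset(table, traits)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf"
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_summary(summary: dict, outdir: Path, name: str = "summary.json") -> None:
    with open(outdir / name, "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_network_pipeline(config: RunConfig) -> dict:
    """Screen features, build the FDR-thresholded correlation network,
    compute topology metrics and communities, and write the report bundle.

    Writes filter_report.tsv, correlation_{r,p,q}.tsv, network.graphml,
    network.edgelist, node_metrics.tsv, communities.tsv,
    participation.tsv and network_summary.json into ``config.outdir``. Returns
    the summary dict. An empty survivor set or edgeless network is a
    clean status in the summary, not an error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)

    dataset = load_dataset(config)
    logger.info(
        "dataset: %d features x %d samples (%d patients, %d controls)",
        dataset.features.n_features,
        dataset.n_samples,
        dataset.n_patients,
        dataset.n_controls,
    )
    th = preprocess.Thresholds(**config.thresholds)
    z, report = preprocess.select_features(dataset, th, seed=seeds[0])
    report.to_tsv(outdir / "filter_report.tsv")
    kinds = dataset.features.kind
    summary: dict[str, Any] = {
        "n_features_in": dataset.features.n_features,
        "n_samples": dataset.n_samples,
        "n_survivors": report.n_survivors,
        "survivor_kind_counts": {
            str(k): int(v)
            for k, v in kinds.loc[report.survivors].value_counts().items()
        },
    }
    logger.info("screening: %d features survived", report.n_survivors)
    if report.n_survivors < 2:
        summary["status"] = "too few surviving features for a network"
        _write_summary(summary, outdir, "network_summary.json")
        return summary

    corr = corrnet.correlate(z)
    corr.r.to_csv(outdir / "correlation_r.tsv", sep="\t")
    corr.p.to_csv(outdir / "correlation_p.tsv", sep="\t")
    corr.q.to_csv(outdir / "correlation_q.tsv", sep="\t")
    alpha = config.network.get("alpha", 0.05)
    net = corrnet.threshold_network(corr, kinds=kinds, alpha=alpha)
    summary["n_nodes"] = net.n_nodes
    summary["n_edges"] = net.n_edges
    if net.n_nodes == 0:
        summary["status"] = "no significant correlations; empty network"
        _write_summary(summary, outdir, "network_summary.json")
        return summary
    write_network(net, outdir / "network.graphml", format="graphml")
    write_network(net, outdir / "network.edgelist", format="edgelist")

    comps = corrnet.components(net)
    summary["component_sizes"] = [len(c) for c in comps]
    metrics = topology.node_metrics(net)
    part = topology.louvain(
        net,
        seed=config.topology.get("seed", seeds[1]),
        resolution=config.topology.get("resolution", 1.0),
    )
    node_table = metrics.table.copy()
    node_table["community"] = part.membership
    node_table["kind"] = net.kinds()
    node_table["label"] = [net.graph.nodes[n]["label"] for n in node_table.index]
    node_table.to_csv(outdir / "node_metrics.tsv", sep="\t", index_label="feature_id")
    part.membership.to_frame("community").to_csv(
        outdir / "communities.tsv", sep="\t", index_label="feature_id"
    )
    ratios = topology.participation_ratio(part, net.kinds())
    ratios.to_frame("otu_over_metabolite").to_csv(
        outdir / "participation.tsv", sep="\t", index_label="community"
    )
    kind_counts = {
        int(c): {
            str(k): int(v)
            for k, v in net.kinds().loc[list(nodes)].value_counts().items()
        }
        for c, nodes in part.communities().items()
    }
    summary.update(
        {
            "n_communities": part.n_communities,
            "modularity": part.q,
            "community_kind_counts": kind_counts,
            "participation_ratio": {
                int(c): (v if math.isfinite(v) else "inf")
                for c, v in ratios.items()
            },
            "status": "ok",
        }
    )
    _write_summary(summary, outdir, "network_summary.json")
    return summary


def run_wgcna_pipeline(config: RunConfig) -> dict:
    """Weighted co-expression analysis of the merged dataset.

    Writes power_sweep.tsv, modules.tsv (feature, kind, color, MM, MM-p,
    BS, BS-p), eigengenes.tsv, module_trait_{r,p}.tsv and wgcna_summary.json.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = load_dataset(config)
    z = preprocess.zscore(preprocess.log2_stabilized(dataset.features))
    usable = z.values.loc[~z.degenerate]
    params = dict(config.wgcna)
    model = wgcna.fit_wgcna(
        usable,
        dataset.traits,
        powers=range(1, params.pop("max_power", 20) + 1),
        r2_target=params.pop("r2_target", 0.8),
        beta=params.pop("beta", None),
        min_module_size=params.pop("min_module_size", 20),
        cut_height=params.pop("cut_height", None),
        outlier_cut=params.pop("outlier_cut", None),
    )
    model.power_sweep.to_csv(outdir / "power_sweep.tsv", sep="\t")
    module_table = pd.DataFrame(
        {"kind": dataset.features.kind.loc[model.colors.index], "color": model.colors}
    )
    for color in model.mes.index:
        module_table[f"MM_{color}"] = model.mm[color]
        module_table[f"MMp_{color}"] = model.mm_p[color]
    for trait in model.bs.columns:
        module_table[f"BS_{trait}"] = model.bs[trait]
        module_table[f"BSp_{trait}"] = model.bs_p[trait]
    module_table.to_csv(outdir / "modules.tsv", sep="\t", index_label="feature_id")
    model.mes.to_csv(outdir / "eigengenes.tsv", sep="\t", index_label="module")
    model.module_trait_r.to_csv(outdir / "module_trait_r.tsv", sep="\t")
    model.module_trait_p.to_csv(outdir / "module_trait_p.tsv", sep="\t")

    sizes = model.module_sizes
    top_modules = {}
    for trait in model.module_trait_r.columns:
        col = model.module_trait_r[trait].abs().dropna()
        if len(col):
            top_modules[trait] = str(col.idxmax())
    summary = {
        "n_features_in": int(usable.shape[0]),
        "n_samples_kept": len(model.kept_samples),
        "soft_power": model.beta,
        "n_modules": int(len(sizes)),
        "module_sizes": {str(k): int(v) for k, v in sizes.items()},
        "top_module_per_trait": top_modules,
        "status": "ok" if len(sizes) else "no modules detected (all gray)",
    }
    _write_summary(summary, outdir, "wgcna_summary.json")
    return summary
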