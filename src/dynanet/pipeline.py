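"""End-to-end orchestration: simulate/load → DyNA + DyBN + stats → report.

A :class:`RunConfig` fully determines a run; the report bundle written to
disk echoes the config (and its hash) so every number is traceable to a
stage, a configuration and a seed.  Stochastic stages (the generator and
the DyBN sampler) are keyed by the config seed, so rerunning an identical
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .dataset import MediatorDataset, load_long_csv
from .dybn import DynamicBayesianNetwork
from .dyna import DynamicNetworkAnalysis
from .exceptions import ConfigError, PanelLookupError
from .simulate import generate, hepatocyte_preset, palf_preset
from .stats import roc_auc, spearman_vs_covariate, volcano

log = logging.getLogger("dynanet.pipeline")


@dataclass
class RunConfig:
    """Serializable configuration of a full analysis run.

    ``input_path`` points at a long CSV, or ``preset`` names a synthetic
    study design (``"palf"`` or ``"hepatocyte"``).  ``volcano_groups`` is
    the (reference, comparison) pair for the volcano and ROC stages.
    """

    preset: str | None = "palf"
    input_path: str | None = None
    subgroups: list[str] | None = None  # None = all in the dataset
    volcano_groups: tuple[str, str] | None = None
    dyna: dict = field(default_factory=lambda: {"threshold": 0.85, "mode": "levels", "min_pairs": 4})
    dybn: dict = field(
        default_factory=lambda: {
            "iterations": 20000,
            "burn_in": 5000,
            "thinning": 10,
            "fan_in": 3,
            "k_max": 1,
            "edge_threshold": 0.5,
        }
    )
    stats: dict = field(default_factory=lambda: {"fc_threshold": 2.0, "alpha": 0.05})
    roc_mediators: list[str] = field(default_factory=lambda: ["GDF-15", "HMGB1"])
    run_dybn: bool = True
    out_dir: str = "dynanet_run"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.volcano_groups is not None:
            d["volcano_groups"] = list(self.volcano_groups)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "volcano_groups" in raw and raw["volcano_groups"] is not None:
            raw["volcano_groups"] = tuple(raw["volcano_groups"])
        return cls(**raw)


@dataclass
class RunReport:
    """In-memory results of a run; heavyweight tables stay as DataFrames."""

    config: RunConfig
    dataset: MediatorDataset
    complexity: dict  # subgroup -> ComplexityProfile
    connectivity: dict  # subgroup -> DataFrame
    networks: dict  # subgroup -> DynamicNetworkSet
    consensus: dict  # subgroup -> ConsensusGraph (empty if run_dybn=False)
    volcano: object | None
    roc: dict  # mediator -> RocResult
    spearman: pd.DataFrame | None
    warnings: list
    version: str = __version__

    @property
    def total_connections(self) -> dict:
        return {g: prof.total_connections for g, prof in self.complexity.items()}


def _resolve_dataset(config: RunConfig):
    if config.input_path:
        return load_long_csv(config.input_path), None
    if config.preset == "palf":
        spec = palf_preset(seed=config.seed)
    elif config.preset == "hepatocyte":
        spec = hepatocyte_preset(seed=config.seed)
    else:
        raise ConfigError(
            f"unknown preset {config.preset!r} and no input_path given"
        )
    spec = dataclasses.replace(spec, seed=config.seed)
    ds, truth = generate(spec)
    return ds, truth


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage in dependency order and write the bundle to
    ``config.out_dir``.  Per-stage failures are isolated and logged; any
    failure is re-raised at the end."""
    t0 = time.time()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds, truth = _resolve_dataset(config)
    groups = config.subgroups or ds.subgroups
    unknown = [g for g in groups if g not in ds.subgroups]
    if unknown:
        raise ConfigError(
            f"unknown subgroup(s) {unknown}; available: {ds.subgroups}"
        )

    ds.to_long_csv(out / "dataset.csv")
    ds.summary_json(out / "dataset_summary.json")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")

    report_warnings: list[str] = []
    failures: list[tuple[str, Exception]] = []
    complexity, connectivity, networks, consensus_graphs = {}, {}, {}, {}

    for g in groups:
        stage_dir = out / g / "dyna"
        try:
            tic = time.time()
            dyna = DynamicNetworkAnalysis(**config.dyna).fit(ds, subgroup=g)
            dyna.write_outputs(stage_dir)
            complexity[g] = dyna.complexity_
            connectivity[g] = dyna.connectivity_table()
            networks[g] = dyna.networks_
            for k, undef in enumerate(dyna.networks_.excluded):
                for m, reason in undef.items():
                    report_warnings.append(f"dyna/{g} interval {k}: {m}: {reason}")
            log.info("dyna[%s] done in %.1fs", g, time.time() - tic)
        except Exception as exc:  # stage isolation
            log.error("dyna[%s] failed: %s", g, exc)
            failures.append((f"dyna/{g}", exc))

    if config.run_dybn:
        import warnings as _w

        for g in groups:
            stage_dir = out / g / "dybn"
            try:
                tic = time.time()
                with _w.catch_warnings(record=True) as caught:
                    _w.simplefilter("always")
                    dybn = DynamicBayesianNetwork(
                        **config.dybn, random_state=config.seed
                    ).fit(ds, subgroup=g)
                for w in caught:
                    report_warnings.append(f"dybn/{g}: {w.message}")
                dybn.write_outputs(stage_dir)
                consensus_graphs[g] = dybn.consensus_
                log.info("dybn[%s] done in %.1fs", g, time.time() - tic)
            except Exception as exc:
                log.error("dybn[%s] failed: %s", g, exc)
                failures.append((f"dybn/{g}", exc))

    volcano_res = None
    roc_res = {}
    spearman_table = None
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    try:
        ga, gb = config.volcano_groups or (
            (groups[0], groups[1]) if len(groups) >= 2 else (None, None)
        )
        if ga is not None:
            volcano_res = volcano(ds, ga, gb, **config.stats)
            volcano_res.table.round(6).to_csv(stats_dir / "volcano.csv", index=False)
            roc_rows = []
            frame = ds.frame
            for m in config.roc_mediators:
                if m not in ds.mediators:
                    continue
                sub = frame[
                    (frame["mediator"] == m) & frame["subgroup"].isin([ga, gb])
                ].dropna(subset=["value"])
                res = roc_auc(sub["value"].to_numpy(), sub["subgroup"].to_numpy())
                roc_res[m] = res
                roc_rows.append(
                    {
                        "mediator": m,
                        "auc": res.auc,
                        "optimal_cutoff": res.optimal_cutoff,
                        "positive_group": res.positive_group,
                        "note": "all time points pooled (pseudo-replication)",
                    }
                )
            pd.DataFrame(roc_rows).round(6).to_csv(stats_dir / "roc.csv", index=False)
    except Exception as exc:
        log.error("stats failed: %s", exc)
        failures.append(("stats", exc))
    try:
        if ds.subject_meta is not None and "age" in getattr(ds.subject_meta, "columns", []):
            spearman_table = spearman_vs_covariate(ds, "age")
            spearman_table.round(6).to_csv(stats_dir / "spearman_age.csv", index=False)
    except Exception as exc:
        log.error("spearman stage failed: %s", exc)
        failures.append(("spearman", exc))

    report = RunReport(
        config=config,
        dataset=ds,
        complexity=complexity,
        connectivity=connectivity,
        networks=networks,
        consensus=consensus_graphs,
        volcano=volcano_res,
        roc=roc_res,
        spearman=spearman_table,
        warnings=report_warnings,
    )

    index = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "subgroups": list(groups),
        "total_connections": report.total_connections,
        "warnings": report_warnings,
        "failures": [f"{stage}: {exc}" for stage, exc in failures],
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "index.json", "w") as fh:
        json.dump(index, fh, indent=2)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    if failures:
        stage, exc = failures[0]
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    return report


def compare_subgroups(report: RunReport, a: str, b: str) -> dict:
    """Side-by-side complexity, connectivity deltas and consensus edge-set
    differences between two analyzed subgroups."""
    for g in (a, b):
        if g not in report.complexity:
            raise PanelLookupError(
                f"subgroup {g!r} not in report; available: {list(report.complexity)}"
            )
    ca, cb = report.complexity[a], report.complexity[b]
    complexity_tab = pd.DataFrame(
        {
            "interval": [f"{x:g}-{y:g}" for x, y in ca.intervals],
            f"complexity_{a}": ca.complexity,
            f"complexity_{b}": cb.complexity,
            f"edges_{a}": ca.edge_counts,
            f"edges_{b}": cb.edge_counts,
        }
    )
    conn = pd.DataFrame(
        {
            f"total_{a}": report.connectivity[a]["total"],
            f"total_{b}": report.connectivity[b]["total"],
        }
    )
    conn["delta"] = conn[f"total_{a}"] - conn[f"total_{b}"]

    edge_rows = []
    if a in report.consensus and b in report.consensus:
        ea = set(report.consensus[a].graph.edges)
        eb = set(report.consensus[b].graph.edges)
        for p, c in sorted(ea - eb):
            edge_rows.append({"parent": p, "child": c, "present_in": f"{a} only"})
        for p, c in sorted(eb - ea):
            edge_rows.append({"parent": p, "child": c, "present_in": f"{b} only"})
    return {
        "complexity": complexity_tab,
        "connectivity_delta": conn,
        "consensus_edge_diff": pd.DataFrame(
            edge_rows, columns=["parent", "child", "present_in"]
        ),
        "total_connections": {
            a: ca.total_connections,
            b: cb.total_connections,
        },
    }
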