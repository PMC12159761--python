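"""End-to-end pipeline: simulate/load -> diversity -> networks -> stability -> PLS-PM.

A structured YAML config drives the run; every stage's parameters, seeds and
output files are recorded in a JSON manifest so any stage can be replayed.
Reruns with the same config and seeds reproduce numerically identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conet, diversity, plspm, stability, synthetic_data, tabio


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Normalized pipeline configuration with the study defaults
    (rarefaction depth 34,234; edge rule |rho| > 0.8, BH-adjusted p < 0.05)."""

    out_dir: str = "micronetstab_out"
    table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    plspm_spec: str | None = None
    orientation: str = "taxa-rows"
    group_col: str = "group"
    rarefy_depth: int | str = 34_234
    rho_min: float = 0.8
    alpha: float = 0.05
    min_prevalence: float = 0.0
    min_mean_relabund: float = 0.0
    pooled_network: bool = False
    permutations: int = 999
    n_null: int = 200
    robustness_reps: int = 100
    n_boot: int = 200
    seed: int = 7
    stages: list[str] = field(
        default_factory=lambda: ["diversity", "network", "stability", "plspm"]
    )
    simulate: dict | None = None

    KNOWN_STAGES = ("simulate", "diversity", "network", "stability", "plspm")

    def validate(self) -> "PipelineConfig":
        for stage in self.stages:
            if stage not in self.KNOWN_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
        if self.simulate is None and "simulate" not in self.stages:
            if self.table is None:
                raise ConfigError("config field 'table' is required without simulation")
            for fieldname in ("table", "metadata", "tree", "plspm_spec"):
                value = getattr(self, fieldname)
                if value is not None and not Path(value).exists():
                    raise ConfigError(f"config field {fieldname!r}: no such file {value}")
        if isinstance(self.rarefy_depth, str) and self.rarefy_depth != "min":
            raise ConfigError("rarefy_depth must be an integer or 'min'")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default-fill and validate a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    return cfg.validate()


def _resolve_depth(cfg: PipelineConfig, table: tabio.AsvTable) -> int:
    if cfg.rarefy_depth == "min":
        return int(table.sample_sums().min())
    return int(cfg.rarefy_depth)


def run_pipeline(cfg: PipelineConfig, log=print) -> dict:
    """Execute the configured stages; returns the run manifest (also written
    to ``out_dir/manifest.json``). A stage failure raises ``StageError``
    naming the stage; earlier outputs are retained."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "stages": []}

    table: tabio.AsvTable | None = None
    meta: tabio.SampleMetadata | None = None
    tree = None
    stages = list(cfg.stages)
    if cfg.simulate is not None and "simulate" not in stages:
        stages.insert(0, "simulate")

    def record(stage: str, t0: float, outputs: list[str], **params) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": outputs,
                "params": params,
            }
        )

    for stage in stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                sim_kwargs = dict(cfg.simulate or {})
                sim_kwargs.setdefault("seed", cfg.seed)
                if "groups" in sim_kwargs:
                    sim_kwargs["groups"] = tuple(sim_kwargs["groups"])
                sc = synthetic_data.SynthConfig(**sim_kwargs)
                table, truth = synthetic_data.generate_community(sc)
                meta = synthetic_data.generate_metadata(sc, truth)
                newick = synthetic_data.generate_tree(table.taxon_ids, seed=sc.seed)
                tabio.write_asv_table(table, out / "asv_table.tsv")
                tabio.write_metadata(meta, out / "metadata.tsv")
                (out / "tree.nwk").write_text(newick + "\n")
                truth_obj = {
                    "module_assignment": truth.module_assignment.to_dict(),
                    "true_effect_taxa": truth.true_effect_taxa,
                    "true_paths": truth.true_paths.to_dict(),
                }
                (out / "ground_truth.json").write_text(
                    json.dumps(truth_obj, indent=2) + "\n"
                )
                import io as _io

                tree = tabio.read_tree(_io.StringIO(newick))
                record(stage, t0,
                       ["asv_table.tsv", "metadata.tsv", "tree.nwk", "ground_truth.json"],
                       seed=sc.seed, n_taxa=sc.n_taxa, n_samples=sc.n_samples)
                continue

            if table is None:
                table = tabio.read_asv_table(cfg.table, orientation=cfg.orientation)
                if cfg.metadata:
                    meta = tabio.read_metadata(cfg.metadata, group_col=cfg.group_col).align_to(table)
                if cfg.tree:
                    tree = tabio.read_tree(cfg.tree)

            if stage == "diversity":
                depth = _resolve_depth(cfg, table)
                rare = diversity.rarefy(table, depth, seed=cfg.seed)
                alpha = diversity.alpha_diversity(rare, tree=tree)
                alpha.to_csv(out / "alpha_diversity.tsv", sep="\t",
                             index_label="sample_id", float_format="%.6g")
                dm = diversity.bray_curtis(rare)
                ord_res = diversity.pcoa(dm)
                coords = ord_res.coordinates.copy()
                coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t",
                              index_label="sample_id", float_format="%.6g")
                outputs = ["alpha_diversity.tsv", "pcoa_coordinates.tsv"]
                perma = None
                if meta is not None:
                    groups = meta.align_to(rare if set(rare.sample_ids) == set(table.sample_ids) else table).groups
                    groups = groups.loc[rare.sample_ids]
                    res = diversity.permanova(dm, groups,
                                              n_permutations=cfg.permutations, seed=cfg.seed)
                    pairwise = diversity.pairwise_permanova(
                        dm, groups, n_permutations=cfg.permutations, seed=cfg.seed)
                    perma = {
                        "pseudo_F": res.pseudo_F,
                        "R2": res.r2,
                        "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                        "seed": res.seed,
                        "pairwise": pairwise.to_dict(orient="records"),
                    }
                    (out / "permanova.json").write_text(
                        json.dumps(perma, indent=2) + "\n")
                    outputs.append("permanova.json")
                record(stage, t0, outputs, rarefy_depth=depth, seed=cfg.seed,
                       proportion_explained=[round(float(p), 4) for p in
                                             ord_res.proportion_explained[:2]])

            elif stage == "network":
                kwargs = dict(
                    min_prevalence=cfg.min_prevalence,
                    min_mean_relabund=cfg.min_mean_relabund,
                    rho_min=cfg.rho_min,
                    alpha=cfg.alpha,
                )
                if cfg.pooled_network or meta is None:
                    nets = {"pooled": conet.network_from_table(table, **kwargs)}
                else:
                    nets = conet.per_group_networks(table, meta.align_to(table).groups, **kwargs)
                metrics_rows = []
                outputs = []
                for name, net in nets.items():
                    tabio.write_network(net.graph, out / f"network_{name}.graphml",
                                        format="graphml")
                    tabio.write_network(net.graph, out / f"network_{name}.tsv",
                                        format="edgelist")
                    outputs += [f"network_{name}.graphml", f"network_{name}.tsv"]
                    if net.n_nodes:
                        row = conet.topology(net, community_seed=cfg.seed).to_dict()
                    else:
                        row = {"n_nodes": 0, "n_edges": 0}
                    row["network"] = name
                    metrics_rows.append(row)
                pd.DataFrame(metrics_rows).to_csv(
                    out / "topology_metrics.tsv", sep="\t", index=False,
                    float_format="%.6g")
                outputs.append("topology_metrics.tsv")
                manifest["networks"] = {k: {"n_nodes": v.n_nodes, "n_edges": v.n_edges}
                                        for k, v in nets.items()}
                record(stage, t0, outputs, rho_min=cfg.rho_min, alpha=cfg.alpha,
                       seed=cfg.seed)
                manifest["_nets"] = nets  # in-memory handoff to the stability stage

            elif stage == "stability":
                coh = stability.cohesion(table, null_model="taxa_shuffle",
                                         n_null=cfg.n_null, seed=cfg.seed)
                groups = meta.align_to(table).groups if meta is not None else None
                per_sample = stability.stability_ratio(coh, groups=groups)
                coh.cohesion.join(per_sample).to_csv(
                    out / "cohesion.tsv", sep="\t", index_label="sample_id",
                    float_format="%.6g")
                summary = stability.summarize_stability(per_sample)
                report: dict = {
                    "null_model": coh.null_model,
                    "n_null": coh.n_null,
                    "seed": cfg.seed,
                    "stability_ratio": {
                        str(g): {"mean": row["mean"], "se": row["se"], "n": row["n"]}
                        for g, row in summary.iterrows()
                    },
                    "networks": {},
                }
                outputs = ["cohesion.tsv"]
                nets = manifest.pop("_nets", {})
                for name, net in nets.items():
                    if net.n_nodes < 3:
                        report["networks"][name] = {"n_nodes": net.n_nodes,
                                                    "note": "too small for stability metrics"}
                        continue
                    rnd = stability.robustness(net, strategy="random",
                                               n_repetitions=cfg.robustness_reps,
                                               seed=cfg.seed)
                    tgt = stability.robustness(net, strategy="degree",
                                               n_repetitions=cfg.robustness_reps,
                                               seed=cfg.seed)
                    rnd.frame.assign(strategy="random").to_csv(
                        out / f"robustness_{name}_random.tsv", sep="\t",
                        index=False, float_format="%.6g")
                    tgt.frame.assign(strategy="degree").to_csv(
                        out / f"robustness_{name}_degree.tsv", sep="\t",
                        index=False, float_format="%.6g")
                    outputs += [f"robustness_{name}_random.tsv",
                                f"robustness_{name}_degree.tsv"]
                    report["networks"][name] = {
                        "n_nodes": net.n_nodes,
                        "n_edges": net.n_edges,
                        "complexity_avg_degree": stability.complexity(net),
                        "robustness_random_f50": rnd.at(0.5),
                        "robustness_degree_f50": tgt.at(0.5),
                        "vulnerability": stability.vulnerability(net),
                    }
                (out / "stability_report.json").write_text(
                    json.dumps(report, indent=2, default=tabio._json_default) + "\n")
                outputs.append("stability_report.json")
                record(stage, t0, outputs, n_null=cfg.n_null,
                       reps=cfg.robustness_reps, seed=cfg.seed)

            elif stage == "plspm":
                if cfg.plspm_spec is None or meta is None:
                    record(stage, t0, [], skipped="no plspm_spec or metadata")
                    continue
                spec = plspm.PlsPmSpec.from_yaml(cfg.plspm_spec)
                data = meta.align_to(table).frame
                results = plspm.fit_plspm(data, spec)
                if cfg.n_boot > 0:
                    results.bootstrap(n_boot=cfg.n_boot, seed=cfg.seed)
                results.path_table().to_csv(out / "plspm_paths.tsv", sep="\t",
                                            index=False, float_format="%.6g")
                model_obj = {
                    "gof": results.gof,
                    "r2": results.r2,
                    "n_iterations": results.n_iterations,
                    "outer_weights": results.outer_weights.to_dict(),
                    "loadings": results.loadings.to_dict(),
                    "paths": results.path_table().to_dict(orient="records"),
                }
                (out / "plspm_model.json").write_text(
                    json.dumps(model_obj, indent=2, default=tabio._json_default) + "\n")
                (out / "plspm_summary.txt").write_text(results.summary() + "\n")
                record(stage, t0,
                       ["plspm_paths.tsv", "plspm_model.json", "plspm_summary.txt"],
                       n_boot=cfg.n_boot, seed=cfg.seed, gof=results.gof)
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        log(f"[micronetstab] stage {stage} done "
            f"({manifest['stages'][-1]['seconds']:.2f}s)")

    manifest.pop("_nets", None)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=tabio._json_default) + "\n")
    return manifest


__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "ConfigError", "StageError"]
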