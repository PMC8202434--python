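"""End-to-end orchestration from a single declarative YAML config.

Stages: input (or synthetic generation) -> normalization -> three-way
consensus DE -> wave segmentation -> per-wave DE and kinetic classes ->
perturbation scoring and validated edges -> wave networks with ranking,
hierarchy and bridging -> wave gene sets and module scores. Every artifact
is written as plain text and listed in a JSON manifest along with the
config hash and the per-stage seeds, so a rerun at the same seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import SCRAMBLE_LABEL, CountMatrix
from .de import (
    estimate_size_factors,
    normalize_log_expression,
    run_consensus_de,
)
from .io import (
    read_gmt,
    write_gmt,
    write_json,
    write_network_graphml,
    write_network_sif,
    write_table,
)
from .network import (
    backbone_hierarchy,
    bridging_tfs,
    build_wave_network,
    integrate_validated_edges,
    load_prior_edges,
    rank_tfs,
)
from .perturbation import (
    effect_score_matrix,
    infer_validated_edges,
    measure_knockdown_efficiencies,
    perturbation_de,
    perturbation_pca,
)
from .synthetic import (
    SimulationParams,
    demo_ground_truth,
    simulate_perturbation_panel,
    simulate_time_course,
)
from .waves import (
    Wave,
    assign_kinetic_classes,
    log2fc_profile,
    segment_waves,
    timepoint_correlation_matrix,
    wave_gene_sets,
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """Validated run configuration. Exactly one of ``inputs`` (paths to
    counts / sample sheet / prior / panel files) or ``synthetic`` (generator
    options) must be present."""

    outdir: str = "pipeline_out"
    seed: int = 0
    inputs: dict | None = None
    synthetic: dict | None = None
    de_rule: str = "agree_by_two"
    fdr_threshold: float = 0.05
    n_waves: int = 3
    lfc_threshold: float = 1.0
    efficiency_gate: float = 0.6
    centrality_variant: str = "closeness"
    n_gois: int = 30
    goi_gene_set: str | None = None
    module_score_bins: int = 24
    module_score_controls: int = 100

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError(
                "config must provide exactly one of 'inputs' or 'synthetic'"
            )
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")
        if not (0 <= self.efficiency_gate <= 1):
            raise ValueError("efficiency_gate must lie in [0, 1]")
        if self.de_rule not in ("agree_by_two", "any"):
            raise ValueError(f"unknown DE rule {self.de_rule!r}")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "outdir seed inputs synthetic de_rule fdr_threshold n_waves "
                "lfc_threshold efficiency_gate centrality_variant n_gois "
                "goi_gene_set module_score_bins module_score_controls"
            ).split()
        }

    def analysis_dict(self) -> dict:
        """Config without the output location: what the analysis depends on."""
        return {k: v for k, v in self.to_dict().items() if k != "outdir"}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.analysis_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


#: Generator settings of the bundled synthetic fixture. The analysis grid
#: omits the 24 h transition point, which by design falls between the
#: intermediate and late windows (eight post-baseline points in three
#: clean blocks).
DEFAULT_SYNTHETIC = {
    "n_tfs_per_wave": 8,
    "n_flat_tfs": 4,
    "n_targets": 1200,
    "hub_out_degree": 60,
    "tf_out_degree": 12,
    "time_grid": [0, 1, 2, 4, 8, 16, 48, 72, 96],
    "n_replicates": 3,
    "dispersion": 0.1,
    "knockdown_efficiency": 0.9,
    "n_perturbations": 21,
}


def validate_inputs(paths: dict) -> dict:
    """Cross-check user-supplied input files; returns {'errors': [...],
    'warnings': [...]} without raising."""
    errors: list[str] = []
    warnings_list: list[str] = []
    for key in ("counts", "sample_sheet", "prior"):
        if key not in paths:
            errors.append(f"missing input path: {key}")
    if errors:
        return {"errors": errors, "warnings": warnings_list}
    try:
        cm = CountMatrix.from_files(paths["counts"], paths["sample_sheet"])
    except Exception as exc:  # unreadable or inconsistent
        return {"errors": [f"counts/sample sheet: {exc}"], "warnings": warnings_list}
    try:
        prior = load_prior_edges(paths["prior"])
    except Exception as exc:
        return {"errors": [f"prior: {exc}"], "warnings": warnings_list}
    genes = set(cm.gene_ids)
    orphan = {g for e in prior.edges for g in e} - genes
    if orphan:
        warnings_list.append(
            f"prior references {len(orphan)} gene(s) absent from the counts"
        )
    counts_cells = cm.design.replicate_counts()
    thin = counts_cells[counts_cells < 2]
    if len(thin):
        warnings_list.append(
            f"{len(thin)} design cell(s) have a single replicate"
        )
    return {"errors": errors, "warnings": warnings_list}


def _load_or_generate(config: PipelineConfig, outdir: Path, manifest: dict):
    if config.inputs is not None:
        inp = config.inputs
        counts = CountMatrix.from_files(inp["counts"], inp["sample_sheet"])
        prior = load_prior_edges(inp["prior"])
        panel = None
        if inp.get("panel_counts"):
            panel = CountMatrix.from_files(inp["panel_counts"], inp["panel_sheet"])
        tf_list = set(pd.read_csv(inp["tf_list"], header=None)[0]) if inp.get(
            "tf_list"
        ) else prior.tf_universe
        return counts, panel, prior, tf_list, None

    opts = dict(DEFAULT_SYNTHETIC)
    opts.update(config.synthetic or {})
    gen_seed = stage_seed(config.seed, "generate")
    truth = demo_ground_truth(
        seed=gen_seed,
        n_tfs_per_wave=opts["n_tfs_per_wave"],
        n_flat_tfs=opts["n_flat_tfs"],
        n_targets=opts["n_targets"],
        hub_out_degree=opts["hub_out_degree"],
        tf_out_degree=opts["tf_out_degree"],
    )
    params = SimulationParams(
        time_grid=tuple(float(t) for t in opts["time_grid"]),
        n_replicates=opts["n_replicates"],
        dispersion=opts["dispersion"],
        knockdown_efficiency=opts["knockdown_efficiency"],
        seed=stage_seed(config.seed, "timecourse"),
    )
    counts, _ = simulate_time_course(truth, params)
    out_deg = pd.Series(
        {tf: sum(1 for e in truth.edges if e[0] == tf) for tf in truth.tfs}
    )
    perturbed = list(
        out_deg.sort_values(ascending=False, kind="mergesort")
        .head(opts["n_perturbations"])
        .index
    )
    panel_params = SimulationParams(
        time_grid=params.time_grid,
        n_replicates=params.n_replicates,
        dispersion=params.dispersion,
        knockdown_efficiency=params.knockdown_efficiency,
        seed=stage_seed(config.seed, "panel"),
    )
    panel = simulate_perturbation_panel(truth, perturbed, panel_params)
    prior_path = outdir / "prior_edges.tsv"
    truth.to_tsv(prior_path)
    counts.to_files(outdir / "counts.tsv", outdir / "sample_sheet.csv")
    panel.to_files(outdir / "panel_counts.tsv", outdir / "panel_sheet.csv")
    manifest["artifacts"] += [
        "prior_edges.tsv",
        "counts.tsv",
        "sample_sheet.csv",
        "panel_counts.tsv",
        "panel_sheet.csv",
    ]
    prior = load_prior_edges(prior_path)
    return counts, panel, prior, set(truth.tfs), truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.analysis_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {},
        "artifacts": [],
        "summary": {},
    }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- inputs ----------------------------------------------------------
    try:
        counts, panel, prior, tf_list, truth = _load_or_generate(
            config, outdir, manifest
        )
    except Exception as exc:
        fail("input", exc)

    # ---- normalization and global consensus DE ---------------------------
    try:
        sf = estimate_size_factors(counts)
        expr = normalize_log_expression(counts, sf)
        results, consensus = run_consensus_de(
            counts, rule=config.de_rule, fdr_threshold=config.fdr_threshold
        )
        write_table(sf.to_frame(), outdir / "size_factors.tsv", "sample")
        for m, r in results.items():
            write_table(r.table, outdir / f"de_{m}.tsv", "gene")
        write_table(consensus.table, outdir / "de_consensus.tsv", "gene")
        manifest["artifacts"] += [
            "size_factors.tsv",
            *[f"de_{m}.tsv" for m in results],
            "de_consensus.tsv",
        ]
        manifest["summary"]["n_de_genes"] = int(consensus.table["consensus"].sum())
    except Exception as exc:
        fail("de_consensus", exc)

    # ---- wave segmentation ----------------------------------------------
    try:
        corr = timepoint_correlation_matrix(expr, counts.design.table)
        waves = segment_waves(corr, n_waves=config.n_waves)
        write_table(corr, outdir / "correlation_matrix.tsv", "time_h")
        write_json(
            {w.label: list(w.time_points) for w in waves}, outdir / "waves.json"
        )
        manifest["artifacts"] += ["correlation_matrix.tsv", "waves.json"]
    except Exception as exc:
        fail("waves", exc)

    # ---- per-wave DE, kinetic classes, wave gene sets --------------------
    try:
        design = counts.design.table
        wave_calls = pd.DataFrame(False, index=counts.gene_ids, columns=[w.label for w in waves])
        per_wave_consensus = {}
        for w in waves:
            ids = list(design.index[design["time_h"].isin(w.time_points)])
            sub = counts.subset_samples(ids)
            n_times = sub.design.table["time_h"].nunique()
            _, cons_w = run_consensus_de(
                sub,
                rule=config.de_rule,
                fdr_threshold=config.fdr_threshold,
                with_timecourse=n_times >= 2,
            )
            per_wave_consensus[w.label] = cons_w
            wave_calls[w.label] = cons_w.table["consensus"].reindex(
                counts.gene_ids
            ).fillna(False)
            w.gene_set = set(cons_w.table.index[cons_w.table["consensus"]])
            write_table(cons_w.table, outdir / f"de_consensus_{w.label}.tsv", "gene")
            manifest["artifacts"].append(f"de_consensus_{w.label}.tsv")
        lfc = log2fc_profile(expr, design)
        classes = assign_kinetic_classes(
            lfc, wave_calls, waves, consensus.de_genes, config.lfc_threshold
        )
        sets = wave_gene_sets(classes, waves)
        write_table(classes.to_frame(), outdir / "kinetic_classes.tsv", "gene")
        write_gmt(sets, outdir / "wave_gene_sets.gmt")
        manifest["artifacts"] += ["kinetic_classes.tsv", "wave_gene_sets.gmt"]
        manifest["summary"]["wave_windows"] = {
            w.label: list(w.time_points) for w in waves
        }
        manifest["summary"]["kinetic_class_counts"] = (
            classes.value_counts().sort_index().to_dict()
        )
    except Exception as exc:
        fail("kinetic_classes", exc)

    # ---- perturbation ----------------------------------------------------
    validated_by_tf: dict[str, list] = {}
    try:
        if panel is not None:
            pert_labels = sorted(
                {
                    str(v)
                    for v in panel.design.table["perturbation"]
                    if v is not None and not pd.isna(v)
                }
                - {SCRAMBLE_LABEL}
            )
            eff = measure_knockdown_efficiencies(panel, pert_labels)
            write_table(eff.to_frame(), outdir / "knockdown_efficiency.tsv", "tf")
            passing = sorted(eff.index[eff >= config.efficiency_gate])
            panel_sf = estimate_size_factors(panel)
            panel_disp = None
            if passing:
                from .de import estimate_dispersion

                panel_disp = estimate_dispersion(panel, size_factors=panel_sf)
            for tf in passing:
                de_tf = perturbation_de(
                    panel,
                    tf,
                    config.fdr_threshold,
                    size_factors=panel_sf,
                    dispersion=panel_disp,
                )
                validated_by_tf[tf] = infer_validated_edges(
                    de_tf, tf, config.fdr_threshold
                )
            all_edges = [
                (e.tf, e.target, e.sign, e.fdr)
                for tf in passing
                for e in validated_by_tf[tf]
            ]
            write_table(
                pd.DataFrame(all_edges, columns=["tf", "target", "sign", "fdr"]),
                outdir / "validated_edges.tsv",
            )
            gois = _pick_gois(config, consensus, tf_list, lfc)
            effects = effect_score_matrix(panel, pert_labels, gois)
            write_table(effects, outdir / "effect_scores.tsv", "tf")
            manifest["artifacts"] += [
                "knockdown_efficiency.tsv",
                "validated_edges.tsv",
                "effect_scores.tsv",
            ]
            if effects.shape[0] >= 2 and effects.shape[1] >= 2:
                pca = perturbation_pca(effects)
                write_table(pca.scores, outdir / "pca_scores.tsv", "tf")
                write_table(pca.loadings, outdir / "pca_loadings.tsv", "gene")
                write_table(pca.modules.to_frame(), outdir / "pca_modules.tsv", "tf")
                manifest["artifacts"] += [
                    "pca_scores.tsv",
                    "pca_loadings.tsv",
                    "pca_modules.tsv",
                ]
            manifest["summary"]["n_perturbations_passing_gate"] = len(passing)
            manifest["summary"]["n_validated_edges"] = len(all_edges)
    except Exception as exc:
        fail("perturbation", exc)

    # ---- wave networks, ranking, hierarchy, bridging ---------------------
    try:
        universe = (prior.target_universe | prior.tf_universe) & set(counts.gene_ids)
        wave_nets = {}
        rankings = {}
        for w in waves:
            net = build_wave_network(w, consensus, tf_list, prior)
            flat = [e for edges in validated_by_tf.values() for e in edges]
            net = integrate_validated_edges(net, flat, w, consensus, tf_list)
            wave_nets[w.label] = net
            write_network_graphml(net, outdir / f"network_{w.label}.graphml")
            write_network_sif(net, outdir / f"network_{w.label}.sif")
            manifest["artifacts"] += [
                f"network_{w.label}.graphml",
                f"network_{w.label}.sif",
            ]
            if any(d.get("is_tf") for _, d in net.nodes(data=True)):
                rank = rank_tfs(
                    net,
                    prior,
                    universe,
                    set(w.gene_set),
                    config.centrality_variant,
                )
                rankings[w.label] = rank
                write_table(rank.table, outdir / f"tf_ranking_{w.label}.tsv", "tf")
                manifest["artifacts"].append(f"tf_ranking_{w.label}.tsv")
            hier = backbone_hierarchy(net, tf_list)
            write_json(
                {tf: int(layer) for tf, layer in sorted(hier.layers.items())},
                outdir / f"hierarchy_{w.label}.json",
            )
            manifest["artifacts"].append(f"hierarchy_{w.label}.json")
        de_tfs_per_wave = {
            w.label: set(w.gene_set) & tf_list for w in waves
        }
        bridging = bridging_tfs(wave_nets, de_tfs_per_wave)
        write_json(
            {
                "bridging_tfs": bridging.bridging_tfs,
                "waves_of_tf": {
                    tf: sorted(ws) for tf, ws in sorted(bridging.waves_of_tf.items())
                },
            },
            outdir / "bridging_tfs.json",
        )
        write_network_graphml(bridging.combined, outdir / "bridging_network.graphml")
        manifest["artifacts"] += ["bridging_tfs.json", "bridging_network.graphml"]
        manifest["summary"]["n_tfs_per_wave_network"] = {
            lb: sum(1 for _, d in net.nodes(data=True) if d.get("is_tf"))
            for lb, net in wave_nets.items()
        }
        manifest["summary"]["top_tf_per_wave"] = {
            lb: (rk.table.index[0] if len(rk.table) else None)
            for lb, rk in rankings.items()
        }
        manifest["summary"]["n_bridging_tfs"] = len(bridging.bridging_tfs)
    except Exception as exc:
        fail("network", exc)

    # ---- wave module scores ----------------------------------------------
    try:
        from .signatures import wave_scores

        nonempty = {lb: g for lb, g in sets.items() if g}
        if nonempty:
            scores = wave_scores(
                expr,
                nonempty,
                n_bins=config.module_score_bins,
                n_control=config.module_score_controls,
                seed=stage_seed(config.seed, "module_score"),
            )
            table = pd.DataFrame({lb: ms.scores for lb, ms in scores.items()})
            write_table(table, outdir / "wave_module_scores.tsv", "sample")
            manifest["artifacts"].append("wave_module_scores.tsv")
    except Exception as exc:
        fail("module_scores", exc)

    manifest["stage_seeds"] = {
        s: stage_seed(config.seed, s)
        for s in ("generate", "timecourse", "panel", "module_score")
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest


def _pick_gois(config, consensus, tf_list, lfc) -> list[str]:
    """Genes of interest for the effect heatmap/PCA: from the configured
    gene set if given, else the strongest-responding DE non-TF genes."""
    if config.goi_gene_set:
        sets = read_gmt(config.goi_gene_set)
        return sorted({g for genes in sets.values() for g in genes})
    de = [g for g in consensus.de_genes if g not in tf_list]
    strength = lfc.abs().max(axis=1)
    ranked = sorted(de, key=lambda g: (-float(strength.get(g, 0.0)), g))
    return ranked[: config.n_gois]
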