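"""End-to-end orchestration: simulate/load → preprocess → modules → DGE →
GSEA → hubs → SVM-RFE → evaluation, with file-mediated stage boundaries.

Every stage writes its outputs (TSV/JSON) into the run directory so real
and synthetic runs share code paths and any stage can be re-run from
files. A single global seed fans out to per-stage sub-seeds, so changing
one stage's stochastic behavior never perturbs another's.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coexmark import dge, evaluate, gsea, hubs, preprocess, simulate, wgcna
from coexmark.io import (
    GeneSetCollection,
    read_edge_list,
    read_expression_tsv,
    read_gmt,
    read_phenotypes_csv,
    write_expression_tsv,
    write_phenotypes_csv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "stage_seed"]

_STAGE_IDS = {
    "simulate": 1,
    "severity": 2,
    "wgcna": 3,
    "gsea": 4,
    "ppi": 5,
    "rfe": 6,
    "epc": 7,
    "gene_sets": 8,
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the global seed."""
    return int(np.random.SeedSequence([seed, _STAGE_IDS[stage]]).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters.

    Exactly one of ``synthetic`` or ``expression_path`` must be provided.
    Thresholds default to the conventional screening settings: soft
    threshold scan over powers 1–20 with signed R² cut 0.9, minimum module
    size 30, module–trait |r| cutoff 0.3, DE cuts adjusted P < 0.01 and
    |log2FC| > 1, GSEA nominal P < 0.05, hub rule top 25% in > 4 of the 12
    centrality rankings, 5 CV folds, ROC alpha 0.05.
    """

    # inputs: either synthetic or file-based
    synthetic: bool = True
    synthetic_config: simulate.SyntheticConfig = field(
        default_factory=simulate.SyntheticConfig
    )
    expression_path: str | None = None
    phenotypes_path: str | None = None
    gmt_path: str | None = None
    edge_list_path: str | None = None
    edge_score_threshold: float = 0.0
    # preprocess
    knn_k: int = 10
    variance_top: float = 0.25
    adjust_batches: bool = True
    # wgcna
    powers: tuple[int, ...] = tuple(range(1, 21))
    r2_cut: float = 0.9
    network_mode: str = "unsigned"
    min_module_size: int = 30
    cut_height: float = 0.995
    merge_cut: float = 0.25
    module_trait_cutoff: float = 0.3
    # dge
    de_p_cut: float = 0.01
    de_lfc_cut: float = 1.0
    # gsea
    gsea_n_perm: int = 200
    gsea_alpha: float = 0.05
    gsea_mode: str = "gene_set"
    # hubs
    hub_fraction: float = 0.25
    hub_min_count: int = 5
    epc_trials: int = 500
    # rfe
    rfe_folds: int = 5
    rfe_kernel: str = "linear"
    svm_C: float = 1.0
    # evaluate
    roc_alpha: float = 0.05
    # synthetic ppi parameters (used when no edge list is supplied)
    ppi_edge_prob: float = 0.05
    ppi_n_hubs: int = 5
    ppi_hub_boost: int = 12
    # severity generator (synthetic runs)
    severity_coupling: float = 1.0
    severity_noise_sd: float = 0.5
    n_severity_drivers: int = 5
    # global
    seed: int = 0
    outdir: str = "coexmark_run"

    def __post_init__(self) -> None:
        if not self.synthetic and self.expression_path is None:
            raise ValueError("provide either synthetic=True or an expression_path")
        if self.synthetic and self.expression_path is not None:
            raise ValueError("synthetic and expression_path are mutually exclusive")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic_config", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if syn:
            syn = dict(syn)
            if "module_sizes" in syn:
                syn["module_sizes"] = tuple(syn["module_sizes"])
            if "trait_linked_modules" in syn:
                syn["trait_linked_modules"] = tuple(syn["trait_linked_modules"])
            cfg = dataclasses.replace(cfg, synthetic_config=simulate.SyntheticConfig(**syn))
        return cfg


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    stages_skipped: list = field(default_factory=list)
    recovery: dict = field(default_factory=dict)
    seed: int = 0
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": self.counts,
            "stages_skipped": self.stages_skipped,
            "recovery": self.recovery,
            "seed": self.seed,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all intermediates to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    report.config = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if not isinstance(v, dict)
    }

    # ------------------------------------------------------------------ input
    truth = None
    if config.synthetic:
        syn = dataclasses.replace(
            config.synthetic_config, seed=stage_seed(config.seed, "simulate")
        )
        matrix, phenotypes, truth = simulate.generate_expression(syn)
        drivers = sorted(truth.discriminative_genes)[: config.n_severity_drivers]
        phenotypes["severity"] = simulate.generate_severity(
            phenotypes,
            matrix,
            drivers,
            coupling=config.severity_coupling,
            noise_sd=config.severity_noise_sd,
            seed=stage_seed(config.seed, "severity"),
        )
    else:
        matrix = read_expression_tsv(config.expression_path)
        phenotypes = read_phenotypes_csv(config.phenotypes_path)
    write_expression_tsv(matrix, outdir / "expression.tsv")
    write_phenotypes_csv(phenotypes, outdir / "phenotypes.csv")
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
    report.counts["n_genes_input"] = int(matrix.shape[0])
    report.counts["n_samples"] = int(matrix.shape[1])

    # ------------------------------------------------------------- preprocess
    full_matrix, prep = preprocess.run(
        matrix,
        phenotypes,
        k=config.knn_k,
        top_fraction=1.0,  # keep all genes for DE; variance filter applies to WGCNA below
        batch_adjust=config.adjust_batches,
    )
    filtered = preprocess.variance_filter(full_matrix, top_fraction=config.variance_top)
    write_expression_tsv(filtered, outdir / "expression_filtered.tsv")
    report.counts["n_imputed_cells"] = prep.n_imputed_cells
    report.counts["n_genes_filtered"] = int(filtered.shape[0])

    # ------------------------------------------------------------------ wgcna
    scan = wgcna.pick_soft_threshold(
        filtered, powers=list(config.powers), r2_cut=config.r2_cut, mode=config.network_mode
    )
    scan.to_frame().to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
    cor = np.corrcoef(filtered.to_numpy(dtype=float))
    adj = wgcna.adjacency(cor, scan.chosen_beta, mode=config.network_mode)
    tom = wgcna.tom_similarity(adj)
    assignment, eigengenes = wgcna.detect_modules(
        tom,
        list(filtered.index),
        matrix=filtered,
        min_size=config.min_module_size,
        cut_height=config.cut_height,
        merge_cut=config.merge_cut,
    )
    assignment.colors.rename("module").to_csv(outdir / "modules.tsv", sep="\t")
    report.counts["beta"] = scan.chosen_beta
    report.counts["module_sizes"] = {
        str(k): int(v) for k, v in assignment.sizes().items()
    }

    selected_modules: list[str] = []
    if eigengenes is not None and not eigengenes.empty:
        eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
        trait_table = wgcna.module_trait_correlation(
            eigengenes, phenotypes, cutoff=config.module_trait_cutoff
        )
        trait_table.to_csv(outdir / "module_trait.tsv", sep="\t")
        selected_modules = list(trait_table.index[trait_table["selected"]])
        gs, mm, mm_gs = wgcna.gene_trait_stats(filtered, eigengenes, phenotypes, assignment)
        pd.concat([gs, mm], axis=1).to_csv(outdir / "gene_trait_stats.tsv", sep="\t")
        if not mm_gs.empty:
            mm_gs.to_csv(outdir / "mm_vs_gs.tsv", sep="\t")
    else:
        report.stages_skipped.append("module_trait (no modules detected)")
    report.counts["n_selected_modules"] = len(selected_modules)
    report.counts["selected_modules"] = selected_modules
    module_genes: set[str] = set()
    for color in selected_modules:
        module_genes |= set(assignment.genes_in(color))
    report.counts["n_selected_module_genes"] = len(module_genes)

    # ------------------------------------------------------------------- gsea
    gene_sets = _load_gene_sets(config, truth)
    if gene_sets is not None and selected_modules:
        for color in selected_modules:
            genes = [g for g in assignment.genes_in(color)]
            result = gsea.permutation_pvalues(
                filtered.loc[genes],
                phenotypes,
                gene_sets,
                n_perm=config.gsea_n_perm,
                mode=config.gsea_mode,
                seed=stage_seed(config.seed, "gsea"),
                alpha=config.gsea_alpha,
            )
            if not result.table.empty:
                out = result.table.sort_values("p").head(10)
                out.to_csv(outdir / f"gsea_{color}.tsv", sep="\t")
                report.counts.setdefault("gsea_significant_sets", {})[color] = int(
                    result.table["significant"].sum()
                )
    elif gene_sets is None:
        report.stages_skipped.append("gsea (no gene sets)")

    # -------------------------------------------------------------------- dge
    de_table = dge.moderated_t_test(full_matrix, phenotypes)
    de_table.to_csv(outdir / "dge.tsv", sep="\t")
    up, down = dge.filter_de(de_table, p_cut=config.de_p_cut, lfc_cut=config.de_lfc_cut)
    report.counts["n_de_up"] = len(up)
    report.counts["n_de_down"] = len(down)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        feature_genes = dge.intersect_with_modules(up | down, assignment, selected_modules)
    report.counts["n_feature_genes"] = len(feature_genes)

    # ------------------------------------------------------------------- hubs
    hub_genes: list[str] = []
    if len(feature_genes) >= 2:
        graph = _load_graph(config, sorted(feature_genes), truth)
        if graph.number_of_nodes() >= 2 and graph.number_of_edges() >= 1:
            centralities = hubs.compute_centralities(
                graph,
                epc_trials=config.epc_trials,
                seed=stage_seed(config.seed, "epc"),
            )
            centralities.to_csv(outdir / "centrality.tsv", sep="\t")
            selection = hubs.consensus_hubs(
                centralities, fraction=config.hub_fraction, min_count=config.hub_min_count
            )
            hub_genes = list(selection.hubs)
            pd.DataFrame(
                {"occurrence": selection.occurrence, "hub": selection.occurrence >= config.hub_min_count}
            ).to_csv(outdir / "hubs.tsv", sep="\t")
        else:
            report.stages_skipped.append("hubs (empty interaction graph)")
    else:
        report.stages_skipped.append("hubs (no feature genes)")
    report.counts["n_hubs"] = len(hub_genes)

    # -------------------------------------------------------------------- rfe
    key_genes: list[str] = []
    rfe_summary: dict = {}
    if len(hub_genes) >= 1:
        from coexmark import rfe as rfe_mod

        X = full_matrix.loc[hub_genes].T
        y = (phenotypes.loc[X.index, "group"] == "AS").astype(int).to_numpy()
        rfe_seed = stage_seed(config.seed, "rfe")
        ranking = rfe_mod.rfe_rank(X, y, C=config.svm_C, seed=rfe_seed)
        curve = rfe_mod.cv_error_curve(
            X,
            y,
            ranking,
            n_folds=config.rfe_folds,
            kernel=config.rfe_kernel,
            C=config.svm_C,
            seed=rfe_seed,
        )
        key_genes, rfe_summary = rfe_mod.select_key_features(
            X, y, curve, ranking, kernel=config.rfe_kernel, C=config.svm_C, seed=rfe_seed
        )
        ranking.rank.rename("rank").to_csv(outdir / "rfe_ranking.tsv", sep="\t")
        curve.to_frame().to_csv(outdir / "cv_curve.tsv", sep="\t", index=False)
        report.counts["k_star"] = rfe_summary["k_star"]
        report.counts["cv_accuracy"] = rfe_summary["cv_accuracy"]
        report.counts["train_accuracy"] = rfe_summary["train_accuracy"]
    else:
        report.stages_skipped.append("rfe (no hub genes)")
    report.counts["n_key_genes"] = len(key_genes)

    # --------------------------------------------------------------- evaluate
    screened: list[str] = []
    if key_genes:
        roc = evaluate.roc_table(full_matrix, phenotypes, key_genes, alpha=config.roc_alpha)
        roc.to_csv(outdir / "roc.tsv", sep="\t")
        screened, discarded = evaluate.screen_significant(roc, alpha=config.roc_alpha)
        report.counts["n_roc_significant"] = len(screened)
        report.counts["roc_discarded"] = discarded
        anova = evaluate.group_difference_test(full_matrix, phenotypes, screened or key_genes)
        anova.to_csv(outdir / "anova.tsv", sep="\t")
        if "severity" in phenotypes.columns and phenotypes["severity"].notna().sum() >= 3:
            sev = evaluate.severity_correlation(full_matrix, phenotypes, screened or key_genes)
            sev.to_csv(outdir / "severity_correlation.tsv", sep="\t")
            report.counts["n_severity_correlated"] = int(sev["significant"].sum())
    else:
        report.stages_skipped.append("evaluate (no key genes)")

    if truth is not None:
        report.recovery = evaluate.recovery_metrics(
            truth,
            assignment=assignment,
            de_genes=up | down,
            hub_genes=set(hub_genes),
            key_genes=set(key_genes),
            key_candidates=set(hub_genes),
        )
        Path(outdir / "recovery.json").write_text(json.dumps(report.recovery, indent=2))

    report.to_json(outdir / "report.json")
    return report


def _load_gene_sets(config: RunConfig, truth) -> GeneSetCollection | None:
    if config.gmt_path:
        return read_gmt(config.gmt_path)
    if config.synthetic and truth is not None:
        return simulate.generate_gene_sets(
            truth, n_enriched=5, n_null=20, set_size=30, seed=stage_seed(config.seed, "gene_sets")
        )
    return None


def _load_graph(config: RunConfig, feature_genes: list[str], truth):
    """Interaction graph over the feature genes: file-based or planted."""
    if config.edge_list_path:
        edges = read_edge_list(config.edge_list_path, score_threshold=config.edge_score_threshold)
        graph = hubs.graph_from_edges(edges, nodes=feature_genes)
        return graph.subgraph(feature_genes).copy()
    n = len(feature_genes)
    n_hubs = min(config.ppi_n_hubs, max(1, n // 10))
    boost = min(config.ppi_hub_boost, max(1, n - n_hubs - 1))
    graph, ppi_truth = simulate.generate_ppi_graph(
        n,
        n_hubs,
        boost,
        config.ppi_edge_prob,
        seed=stage_seed(config.seed, "ppi"),
        node_ids=feature_genes,
    )
    if truth is not None:
        truth.planted_hubs = set(ppi_truth.planted_hubs)
        truth.graph_params = ppi_truth.graph_params
    return graph
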