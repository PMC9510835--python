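"""Synthetic data with planted structure for every pipeline stage.

The expression generator follows a single-latent-factor-per-module model:

    x[g, s] = mu_g + lambda * f_m(s) + delta * 1[g discriminative] * 1[s case]
              + b(batch(s)) + eps,   eps ~ N(0, noise_sd^2)

where each module m has one latent factor f_m ~ N(0, 1) per sample and
trait-linked modules receive a group-dependent factor mean shift. Module
labels, discriminative genes, planted hubs and the generating parameters
are recorded as ground truth so module recovery, differential-expression
filtering, hub ranking and key-gene selection can each be scored.

The default configuration mirrors a whole-blood case/control microarray
cohort of 52 cases and 20 controls on ~2000 genes with four planted
modules of 100 genes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from coexmark.io import GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_expression",
    "generate_ppi_graph",
    "generate_gene_sets",
    "generate_severity",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure expression generator.

    ``factor_loading`` is the loading of module genes on their latent
    factor; ``trait_effect`` the log2-scale case/control mean shift of
    discriminative genes; ``factor_trait_shift`` the case-group mean shift
    of trait-linked module factors (module-level trait signal, distinct
    from the gene-level shift).
    """

    n_genes: int = 2000
    n_samples_case: int = 52
    n_samples_control: int = 20
    n_modules: int = 4
    module_sizes: tuple[int, ...] = (100, 100, 100, 100)
    factor_loading: float = 0.8
    trait_effect: float = 1.5
    n_discriminative: int = 60
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    n_batches: int = 1
    batch_sd: float = 0.0
    trait_linked_modules: tuple[int, ...] = (0,)
    factor_trait_shift: float = 1.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if any(m >= self.n_modules or m < 0 for m in self.trait_linked_modules):
            raise ValueError("trait_linked_modules indices out of range")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_discriminative > self.n_genes:
            raise ValueError("n_discriminative exceeds n_genes")


@dataclass
class GroundTruth:
    """Planted structure recorded by the generators.

    ``module_label_per_gene`` maps gene id → module index (int) or ``-1``
    for background; every other field is the generator's record of what a
    perfect analysis should recover.
    """

    module_label_per_gene: dict[str, int] = field(default_factory=dict)
    discriminative_genes: set[str] = field(default_factory=set)
    trait_linked_modules: tuple[int, ...] = ()
    planted_hubs: set[str] = field(default_factory=set)
    generating_config: SyntheticConfig | None = None
    graph_params: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_label_per_gene": self.module_label_per_gene,
            "discriminative_genes": sorted(self.discriminative_genes),
            "trait_linked_modules": list(self.trait_linked_modules),
            "planted_hubs": sorted(self.planted_hubs),
            "generating_config": (
                dataclasses.asdict(self.generating_config) if self.generating_config else None
            ),
            "graph_params": self.graph_params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cfg = payload.get("generating_config")
        if cfg is not None:
            cfg["module_sizes"] = tuple(cfg["module_sizes"])
            cfg["trait_linked_modules"] = tuple(cfg["trait_linked_modules"])
            cfg = SyntheticConfig(**cfg)
        return cls(
            module_label_per_gene=dict(payload["module_label_per_gene"]),
            discriminative_genes=set(payload["discriminative_genes"]),
            trait_linked_modules=tuple(payload["trait_linked_modules"]),
            planted_hubs=set(payload["planted_hubs"]),
            generating_config=cfg,
            graph_params=payload.get("graph_params"),
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression matrix, phenotype table, ground truth).

    Deterministic for a fixed config (including seed). Cases come first in
    the sample order; batches are assigned round-robin so each batch mixes
    cases and controls.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_samples_case + config.n_samples_control
    genes = _gene_ids(config.n_genes)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    is_case = np.array([1] * config.n_samples_case + [0] * config.n_samples_control)

    labels = np.full(config.n_genes, -1, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes):
        labels[start : start + size] = m
        start += size

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    X = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    for m in range(config.n_modules):
        f = rng.normal(0.0, 1.0, size=n_samples)
        if m in config.trait_linked_modules:
            f = f + config.factor_trait_shift * is_case
        X[labels == m] += config.factor_loading * f[None, :]

    # discriminative genes: alternate between trait-linked-module genes and
    # background so both the module-level and gene-level signals carry DE truth
    linked = [g for g in range(config.n_genes) if labels[g] in config.trait_linked_modules]
    background = [g for g in range(config.n_genes) if labels[g] == -1]
    pool = [g for pair in zip(linked, background) for g in pair]
    pool += linked[len(background):] + background[len(linked):]
    if config.n_discriminative > config.n_genes:
        raise ValueError("n_discriminative exceeds n_genes")
    disc_idx = np.array(pool[: config.n_discriminative], dtype=int)
    if len(disc_idx) < config.n_discriminative:
        extra = [g for g in range(config.n_genes) if g not in set(disc_idx)]
        disc_idx = np.concatenate([disc_idx, extra[: config.n_discriminative - len(disc_idx)]])
    X[np.ix_(disc_idx, np.flatnonzero(is_case))] += config.trait_effect

    batches = np.array([f"B{i % config.n_batches}" for i in range(n_samples)])
    if config.n_batches > 1 and config.batch_sd > 0:
        offsets = rng.normal(0.0, config.batch_sd, size=config.n_batches)
        for b in range(config.n_batches):
            X[:, batches == f"B{b}"] += offsets[b]

    if config.missing_rate > 0:
        mask = rng.random(size=X.shape) < config.missing_rate
        X = X.copy()
        X[mask] = np.nan

    matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    phenotypes = pd.DataFrame(
        {
            "group": np.where(is_case == 1, "AS", "HC"),
            "batch": batches,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = GroundTruth(
        module_label_per_gene={g: int(l) for g, l in zip(genes, labels)},
        discriminative_genes={genes[i] for i in disc_idx},
        trait_linked_modules=tuple(config.trait_linked_modules),
        generating_config=config,
    )
    return matrix, phenotypes, truth


def generate_ppi_graph(
    n_nodes: int,
    n_hubs: int,
    hub_degree_boost: int,
    edge_prob: float,
    seed: int = 0,
    node_ids: list[str] | None = None,
) -> tuple[nx.Graph, GroundTruth]:
    """Erdős–Rényi background plus planted high-degree hubs.

    Each of the ``n_hubs`` planted hubs receives ``hub_degree_boost`` extra
    edges to uniformly chosen current non-neighbors.
    """
    if n_hubs >= n_nodes:
        raise ValueError("n_hubs must be < n_nodes")
    rng = np.random.default_rng(seed)
    nodes = node_ids if node_ids is not None else _gene_ids(n_nodes)
    if len(nodes) != n_nodes:
        raise ValueError("node_ids length must equal n_nodes")
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    if edge_prob > 0:
        upper = np.triu_indices(n_nodes, k=1)
        draw = rng.random(len(upper[0])) < edge_prob
        graph.add_edges_from(
            (nodes[i], nodes[j]) for i, j, keep in zip(*upper, draw) if keep
        )
    if hub_degree_boost > n_nodes - 1:
        raise ValueError(
            f"hub_degree_boost {hub_degree_boost} exceeds the {n_nodes - 1} "
            "non-neighbors any node can have"
        )
    hub_idx = rng.choice(n_nodes, size=n_hubs, replace=False)
    hubs = [nodes[i] for i in sorted(hub_idx)]
    for hub in hubs:
        # boost capped by the current non-neighbors (a dense background
        # already provides part of the intended degree)
        candidates = sorted(set(nodes) - set(graph.neighbors(hub)) - {hub})
        n_extra = min(hub_degree_boost, len(candidates))
        if n_extra > 0:
            chosen = rng.choice(len(candidates), size=n_extra, replace=False)
            graph.add_edges_from((hub, candidates[c]) for c in chosen)
    truth = GroundTruth(
        planted_hubs=set(hubs),
        graph_params={
            "n_nodes": n_nodes,
            "n_hubs": n_hubs,
            "hub_degree_boost": hub_degree_boost,
            "edge_prob": edge_prob,
            "seed": seed,
        },
    )
    return graph, truth


def generate_gene_sets(
    truth: GroundTruth,
    n_enriched: int,
    n_null: int,
    set_size: int,
    seed: int = 0,
    enriched_fraction: float = 0.8,
) -> GeneSetCollection:
    """Gene sets enriched for planted signal genes plus uniform null sets.

    Enriched sets draw at least ``enriched_fraction`` of their members from
    the union of discriminative genes and trait-linked-module genes; null
    sets are uniform draws from the whole gene universe.
    """
    universe = sorted(truth.module_label_per_gene)
    if not universe:
        raise ValueError("empty gene universe in ground truth")
    if set_size > len(universe):
        raise ValueError("set_size exceeds gene universe size")
    signal = sorted(
        truth.discriminative_genes
        | {
            g
            for g, m in truth.module_label_per_gene.items()
            if m in set(truth.trait_linked_modules)
        }
    )
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    for i in range(n_enriched):
        n_signal = min(int(np.ceil(enriched_fraction * set_size)), len(signal), set_size)
        members = list(rng.choice(signal, size=n_signal, replace=False))
        rest = sorted(set(universe) - set(members))
        if set_size - n_signal > 0:
            members += list(rng.choice(rest, size=set_size - n_signal, replace=False))
        collection.add(f"ENRICHED_{i}", members, description="planted-signal set")
    for i in range(n_null):
        members = list(rng.choice(universe, size=set_size, replace=False))
        collection.add(f"NULL_{i}", members, description="uniform background set")
    return collection


def generate_severity(
    phenotypes: pd.DataFrame,
    expression: pd.DataFrame,
    driver_genes: set[str] | list[str],
    coupling: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """BASDAI-like 0–10 severity score for case samples.

    severity(s) = coupling * mean(standardized driver expression in s) + noise,
    affinely rescaled into [0, 10]; controls get missing severity.
    """
    drivers = sorted(driver_genes)
    missing = [g for g in drivers if g not in expression.index]
    if missing:
        raise ValueError(f"driver genes not in matrix: {missing}")
    cases = phenotypes.index[phenotypes["group"] == "AS"]
    if len(cases) == 0:
        raise ValueError("no case samples to assign severity to")
    rng = np.random.default_rng(seed)
    sub = expression.loc[drivers, cases].to_numpy(dtype=float)
    mu = np.nanmean(sub, axis=1, keepdims=True)
    sd = np.nanstd(sub, axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    standardized = (sub - mu) / sd
    raw = coupling * np.nanmean(standardized, axis=0) + rng.normal(0, noise_sd, len(cases))
    lo, hi = raw.min(), raw.max()
    scaled = np.full_like(raw, 5.0) if hi == lo else (raw - lo) / (hi - lo) * 10.0
    severity = pd.Series(np.nan, index=phenotypes.index, name="severity")
    severity.loc[cases] = np.clip(scaled, 0.0, 10.0)
    return severity
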