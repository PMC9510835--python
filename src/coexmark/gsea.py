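"""Pre-ranked gene-set enrichment with permutation p-values.

Genes are ranked by a signal-to-noise metric between the two phenotype
groups; a weighted Kolmogorov–Smirnov running sum over the ranked list
yields the enrichment score (ES) per gene set, and significance comes
from either phenotype permutations (re-ranking under shuffled labels) or
gene-set permutations (random member sets on the fixed ranking). Nominal
p-values use the add-one rule, p ≥ 1/(n_perm + 1). Reporting keeps sets
with p < 0.05, the conventional nominal cut.

When run per co-expression module, the ranked universe is restricted to
that module's genes so enrichment is assessed within the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexmark.io import GeneSetCollection

__all__ = [
    "GseaResult",
    "rank_genes",
    "enrichment_score",
    "permutation_pvalues",
]


@dataclass
class GseaResult:
    """Per-set enrichment statistics."""

    table: pd.DataFrame  # index: set name; columns ES, p, n_members, n_leading_edge, significant
    leading_edges: dict[str, list[str]]
    mode: str
    n_perm: int


def _signal_to_noise(
    x1: np.ndarray, x2: np.ndarray, sd_floor_frac: float = 0.2, sd_floor_abs: float = 0.2
) -> np.ndarray:
    """Classic GSEA signal-to-noise with the standard-deviation floor.

    Each group's sd is floored at ``sd_floor_frac``·|mean| and, if still
    zero, at ``sd_floor_abs``, which keeps near-constant genes from
    dominating the ranking.
    """
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s1, s2 = x1.std(axis=1, ddof=1), x2.std(axis=1, ddof=1)

    def floor(s: np.ndarray, m: np.ndarray) -> np.ndarray:
        s = np.maximum(s, sd_floor_frac * np.abs(m))
        s = np.where(s == 0, sd_floor_abs, s)
        return s

    return (m1 - m2) / (floor(s1, m1) + floor(s2, m2))


def rank_genes(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    metric: str = "signal_to_noise",
) -> pd.Series:
    """Rank genes by a case-vs-control metric, descending.

    Ties break by gene id (ascending) for determinism. With fewer than 3
    samples in a group the signal-to-noise metric falls back to the
    moderated t metric with a warning.
    """
    groups = phenotypes.loc[matrix.columns, "group"]
    case_cols = matrix.columns[groups == "AS"]
    ctrl_cols = matrix.columns[groups == "HC"]
    x1 = matrix[case_cols].to_numpy(dtype=float)
    x2 = matrix[ctrl_cols].to_numpy(dtype=float)
    if metric == "signal_to_noise" and (x1.shape[1] < 3 or x2.shape[1] < 3):
        warnings.warn(
            "group too small for signal-to-noise; falling back to moderated t", stacklevel=2
        )
        metric = "moderated_t"
    if metric == "signal_to_noise":
        scores = _signal_to_noise(x1, x2)
    elif metric == "moderated_t":
        from coexmark.dge import moderated_t_test

        scores = moderated_t_test(matrix, phenotypes)["t"].to_numpy()
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    ranking = pd.Series(scores, index=matrix.index.rename("gene"), name="score")
    frame = ranking.reset_index()
    frame = frame.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(frame["score"].to_numpy(), index=frame["gene"].to_numpy(), name="score")


def enrichment_score(
    ranking: pd.Series, gene_set: list[str] | set[str], weight: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score of a gene set on a ranked list.

    The running sum gains |score_i|^weight / Σ_hits |score|^weight at set
    members and loses 1/(N − N_hits) elsewhere; ES is the extremum of
    largest magnitude. The leading edge contains the members at or before
    a positive extremum (after, for a negative one). A set covering the
    whole universe has a degenerate walk and is scored ES = 1 with a
    warning; a set with no members in the universe raises.
    """
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n_hits = int(hit.sum())
    n = len(genes)
    if n_hits == 0:
        raise ValueError("gene set has no members in the ranked universe")
    if n_hits == n:
        warnings.warn("gene set covers the whole ranked universe; ES = 1", stacklevel=2)
        return 1.0, np.ones(n), list(genes)
    w = np.abs(scores) ** weight
    hit_total = w[hit].sum()
    if hit_total == 0:  # all member scores zero: fall back to unweighted hits
        increments = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        increments = np.where(hit, w / hit_total, 0.0)
    decrement = 1.0 / (n - n_hits)
    walk = np.cumsum(np.where(hit, increments, -decrement))
    i_max = int(np.argmax(walk))
    i_min = int(np.argmin(walk))
    es = walk[i_max] if abs(walk[i_max]) >= abs(walk[i_min]) else walk[i_min]
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_min + 1 :], hit[i_min + 1 :]) if h]
    return float(es), walk, leading


def permutation_pvalues(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    mode: str = "phenotype",
    weight: float = 1.0,
    metric: str = "signal_to_noise",
    seed: int = 0,
    alpha: float = 0.05,
) -> GseaResult:
    """Permutation p-values for every gene set.

    ``phenotype`` mode permutes group labels and re-ranks per permutation
    (requires ≥ 7 samples per group, else it auto-switches to ``gene_set``
    mode with a warning); ``gene_set`` mode draws random member sets of the
    same size on the fixed observed ranking. p = (1 + #{|ES_perm| ≥
    |ES_obs|}) / (n_perm + 1); a set is significant at nominal p < alpha.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-values are coarse", stacklevel=2)
    groups = phenotypes.loc[matrix.columns, "group"]
    n_case = int((groups == "AS").sum())
    n_ctrl = int((groups == "HC").sum())
    if mode == "phenotype" and min(n_case, n_ctrl) < 7:
        warnings.warn(
            "fewer than 7 samples per group; switching to gene_set permutation", stacklevel=2
        )
        mode = "gene_set"
    if mode not in ("phenotype", "gene_set"):
        raise ValueError(f"unknown permutation mode {mode!r}")

    rng = np.random.default_rng(seed)
    ranking = rank_genes(matrix, phenotypes, metric=metric)
    universe = set(ranking.index)

    observed: dict[str, tuple[float, list[str], int]] = {}
    skipped: list[str] = []
    for name in sets:
        members = [g for g in sets[name] if g in universe]
        if not members:
            skipped.append(name)
            continue
        es, _, leading = enrichment_score(ranking, members, weight=weight)
        observed[name] = (es, leading, len(members))
    if skipped:
        warnings.warn(f"sets with no members in universe skipped: {skipped}", stacklevel=2)

    exceed = {name: 0 for name in observed}
    if mode == "phenotype":
        labels = groups.to_numpy().copy()
        for _ in range(n_perm):
            rng.shuffle(labels)
            perm_pheno = pd.DataFrame({"group": labels}, index=matrix.columns)
            perm_ranking = rank_genes(matrix, perm_pheno, metric=metric)
            for name, (es_obs, _, _) in observed.items():
                members = [g for g in sets[name] if g in universe]
                es_perm, _, _ = enrichment_score(perm_ranking, members, weight=weight)
                if abs(es_perm) >= abs(es_obs):
                    exceed[name] += 1
    else:
        gene_array = ranking.index.to_numpy()
        for name, (es_obs, _, n_members) in observed.items():
            for _ in range(n_perm):
                random_set = rng.choice(gene_array, size=n_members, replace=False)
                es_perm, _, _ = enrichment_score(ranking, random_set, weight=weight)
                if abs(es_perm) >= abs(es_obs):
                    exceed[name] += 1

    rows = []
    leading_edges = {}
    for name, (es, leading, n_members) in observed.items():
        p = (1.0 + exceed[name]) / (n_perm + 1.0)
        rows.append(
            {
                "set": name,
                "ES": es,
                "p": p,
                "n_members": n_members,
                "n_leading_edge": len(leading),
                "significant": p < alpha,
            }
        )
        leading_edges[name] = leading
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame()
    return GseaResult(table=table, leading_edges=leading_edges, mode=mode, n_perm=n_perm)
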