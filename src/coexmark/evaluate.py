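"""ROC screening, group tests, severity correlation, recovery scoring.

The per-gene AUC is the Mann–Whitney U statistic divided by n1·n2 (ties
counted half); its significance uses the tie-corrected normal
approximation, two-sided. Group differences use one-way ANOVA (for two
groups, F = t²). Severity correlations are Pearson over case samples
with non-missing severity. Recovery metrics score a synthetic run
against its planted ground truth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from coexmark.simulate import GroundTruth
from coexmark.wgcna import GREY, ModuleAssignment

__all__ = [
    "roc_auc",
    "roc_table",
    "screen_significant",
    "group_difference_test",
    "severity_correlation",
    "recovery_metrics",
]


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC from the Mann–Whitney U statistic plus a two-sided p-value.

    AUC = U / (n1·n2) with tied score pairs counted 0.5. The p-value for
    AUC ≠ 0.5 uses the normal approximation with tie-corrected variance;
    fully tied data gives p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n2 = len(pos), len(neg)
    if n1 == 0 or n2 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n2)
    n = n1 + n2
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return float(auc), 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc), float(min(p, 1.0))


def roc_table(
    matrix: pd.DataFrame, phenotypes: pd.DataFrame, genes: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene AUC and significance of discrimination between groups."""
    labels = (phenotypes.loc[matrix.columns, "group"] == "AS").astype(int).to_numpy()
    rows = []
    for gene in genes:
        auc, p = roc_auc(matrix.loc[gene].to_numpy(dtype=float), labels)
        rows.append({"gene": gene, "auc": auc, "p": p, "significant": p < alpha})
    return pd.DataFrame(rows).set_index("gene")


def screen_significant(roc: pd.DataFrame, alpha: float = 0.05) -> tuple[list[str], list[str]]:
    """Split ROC-screened genes into (retained, discarded) at strict p < alpha."""
    retained = list(roc.index[roc["p"] < alpha])
    discarded = list(roc.index[roc["p"] >= alpha])
    return retained, discarded


def group_difference_test(
    matrix: pd.DataFrame, phenotypes: pd.DataFrame, genes: list[str], alpha: float = 0.01
) -> pd.DataFrame:
    """One-way ANOVA of each gene's expression across the two groups."""
    groups = phenotypes.loc[matrix.columns, "group"]
    case_cols = matrix.columns[groups == "AS"]
    ctrl_cols = matrix.columns[groups == "HC"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for gene in genes:
        x1 = matrix.loc[gene, case_cols].to_numpy(dtype=float)
        x2 = matrix.loc[gene, ctrl_cols].to_numpy(dtype=float)
        if np.ptp(np.concatenate([x1, x2])) == 0:
            warnings.warn(f"constant gene {gene}: F undefined, p = 1", stacklevel=2)
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(x1, x2)
        rows.append({"gene": gene, "F": float(f_stat), "p": float(p), "significant": p < alpha})
    return pd.DataFrame(rows).set_index("gene")


def severity_correlation(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    genes: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each gene with severity among scored cases."""
    if "severity" not in phenotypes.columns:
        raise ValueError("phenotype table has no 'severity' column")
    cases = phenotypes.index[
        (phenotypes["group"] == "AS") & phenotypes["severity"].notna()
    ]
    cases = [s for s in cases if s in matrix.columns]
    if len(cases) < 3:
        raise ValueError("need at least 3 cases with severity scores")
    severity = phenotypes.loc[cases, "severity"].to_numpy(dtype=float)
    rows = []
    for gene in genes:
        expr = matrix.loc[gene, cases].to_numpy(dtype=float)
        if np.ptp(expr) == 0 or np.ptp(severity) == 0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(expr, severity)
        rows.append(
            {
                "gene": gene,
                "r": float(r),
                "r_squared": float(r**2),
                "p": float(p),
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _precision_recall(selected: set, truth: set) -> tuple[float, float]:
    if not selected:
        return 0.0, 0.0 if truth else 1.0
    tp = len(selected & truth)
    precision = tp / len(selected)
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


def recovery_metrics(
    truth: GroundTruth,
    assignment: ModuleAssignment | None = None,
    de_genes: set[str] | None = None,
    hub_genes: set[str] | None = None,
    key_genes: set[str] | None = None,
    key_candidates: set[str] | None = None,
) -> dict:
    """Score pipeline outputs against planted ground truth.

    Module recovery is the adjusted Rand index between detected colors and
    planted module indices, restricted to genes planted in a module (the
    background genes have no true module, so the unassigned bin is not
    penalized on the truth side). Set-valued outputs are scored by
    precision and recall against the planted sets.
    """
    if truth is None:
        raise ValueError("ground truth required for recovery scoring")
    report: dict = {}
    if assignment is not None:
        planted = {
            g: m for g, m in truth.module_label_per_gene.items() if m != -1
        }
        genes = [g for g in planted if g in assignment.colors.index]
        if genes:
            true_labels = [planted[g] for g in genes]
            found_labels = [assignment.colors[g] for g in genes]
            report["module_ari"] = float(adjusted_rand_score(true_labels, found_labels))
            grey_frac = float(np.mean([c == GREY for c in found_labels]))
            report["planted_genes_unassigned_fraction"] = grey_frac
    if de_genes is not None:
        p, r = _precision_recall(set(de_genes), set(truth.discriminative_genes))
        report["de_precision"], report["de_recall"] = p, r
    if hub_genes is not None:
        p, r = _precision_recall(set(hub_genes), set(truth.planted_hubs))
        report["hub_precision"], report["hub_recall"] = p, r
    if key_genes is not None:
        p, r = _precision_recall(set(key_genes), set(truth.discriminative_genes))
        report["key_gene_precision"], report["key_gene_recall"] = p, r
        if key_candidates is not None:
            # recall among the planted genes that actually reached the
            # feature-selection stage (the upstream funnel bounds what
            # selection can recover)
            reachable = set(key_candidates) & set(truth.discriminative_genes)
            if reachable:
                report["key_gene_recall_candidates"] = len(
                    set(key_genes) & reachable
                ) / len(reachable)
    return report
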