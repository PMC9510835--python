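"""Moderated-t differential expression between cases and controls.

Gene-wise residual variances are shrunk toward a prior estimated from all
genes by moment matching on log variances (the empirical-Bayes scheme of
the moderated t-statistic): with prior degrees of freedom d0 and prior
variance s0², the posterior variance is

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g)

and t̃_g = log2FC_g / (s̃_g·sqrt(1/n1 + 1/n2)) follows a Student t with
d0 + d_g degrees of freedom under the null. Benjamini–Hochberg adjustment
and the reporting filters (adjusted P < 0.01, |log2FC| > 1, both strict)
follow the screening convention for two-group microarray comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "VariancePrior",
    "fit_variance_prior",
    "moderated_t_test",
    "bh_adjust",
    "filter_de",
    "intersect_with_modules",
]


@dataclass(frozen=True)
class VariancePrior:
    """Empirical-Bayes variance prior: d0 may be ``inf`` (complete shrinkage)."""

    d0: float
    s0_sq: float


def fit_variance_prior(s2: np.ndarray, df: float) -> VariancePrior:
    """Estimate (d0, s0²) by moment matching on e_g = log s²_g.

    Under the hierarchical model, var(e_g) = trigamma(d_g/2) + trigamma(d0/2),
    so d0 solves trigamma(d0/2) = var(e_g) − trigamma(d_g/2) (monotone in d0,
    solved by bracketed root finding). When the observed spread does not
    exceed the sampling spread the prior is degenerate: d0 = +inf and s0² is
    the mean variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 10:
        raise ValueError("need at least 10 genes to estimate the variance prior")
    if np.any(s2 <= 0):
        raise ValueError("residual variances must be positive")
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    e = np.log(s2)
    target = np.var(e, ddof=1) - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        return VariancePrior(np.inf, float(np.mean(s2)))

    def f(d0: float) -> float:
        return float(special.polygamma(1, d0 / 2.0)) - target

    lo, hi = 1e-8, 1e12
    if f(hi) > 0:  # even huge d0 leaves too much spread unexplained -> d0 ~ inf
        return VariancePrior(np.inf, float(np.mean(s2)))
    d0 = float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
    log_s0 = (
        float(np.mean(e))
        - float(special.digamma(df / 2.0))
        + np.log(df / 2.0)
        + float(special.digamma(d0 / 2.0))
        - np.log(d0 / 2.0)
    )
    return VariancePrior(d0, float(np.exp(log_s0)))


def moderated_t_test(
    matrix: pd.DataFrame,
    phenotypes: pd.DataFrame,
    prior: VariancePrior | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test per gene (cases = ``AS`` vs controls).

    Returns a DataFrame indexed by gene with columns log2FC (case −
    control), t, p, adj_p (BH), direction and passes_filter at the default
    cuts. Supplying ``prior`` overrides the data-estimated variance prior
    (``VariancePrior(0, 1)`` recovers the ordinary two-sample t-test).
    """
    groups = phenotypes.loc[matrix.columns, "group"]
    case_cols = matrix.columns[groups == "AS"]
    ctrl_cols = matrix.columns[groups == "HC"]
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    x1 = matrix[case_cols].to_numpy(dtype=float)
    x2 = matrix[ctrl_cols].to_numpy(dtype=float)
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = float(n1 + n2 - 2)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    if prior is None:
        positive = s2[s2 > 0]
        prior = fit_variance_prior(positive, df_resid)
    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df_resid * s2) / (prior.d0 + df_resid)
        df_total = prior.d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2FC": lfc,
            "t": t,
            "p": p,
            "adj_p": adj,
            "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        },
        index=matrix.index,
    )
    table["passes_filter"] = (table["adj_p"] < 0.01) & (table["log2FC"].abs() > 1.0)
    return table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def filter_de(
    table: pd.DataFrame, p_cut: float = 0.01, lfc_cut: float = 1.0
) -> tuple[set[str], set[str]]:
    """Split the DGE table into (up, down) gene sets at strict cutoffs."""
    sig = table["adj_p"] < p_cut
    up = set(table.index[sig & (table["log2FC"] > lfc_cut)])
    down = set(table.index[sig & (table["log2FC"] < -lfc_cut)])
    return up, down


def intersect_with_modules(
    de_genes: set[str],
    assignment,
    selected_modules: list[str],
) -> set[str]:
    """Intersect DE genes with the union of selected-module member genes."""
    module_genes: set[str] = set()
    for color in selected_modules:
        module_genes |= set(assignment.genes_in(color))
    feature = module_genes & set(de_genes)
    if not feature:
        warnings.warn("empty module × DE intersection; downstream stages will skip", stacklevel=2)
    return feature
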