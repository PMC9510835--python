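"""Weighted co-expression network analysis core.

Soft-threshold selection by the scale-free topology fit index, unsigned
(or signed) adjacency, topological overlap similarity, module detection by
average-linkage clustering of 1−TOM with a static cut and eigengene-based
merging, module eigengenes, module–trait statistics, gene significance /
module membership, and a permutation Z-score of module preservation.

Conventions: genes in rows, samples in columns; correlations are Pearson;
modules are named by the conventional color vocabulary in decreasing size
order, with ``grey`` reserved for unassigned genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "MODULE_COLORS",
    "SoftThresholdScan",
    "ModuleAssignment",
    "scale_free_fit",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "gene_trait_stats",
    "preservation_z",
]

#: conventional module color order; assigned by decreasing module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]
GREY = "grey"


@dataclass
class SoftThresholdScan:
    """Per-power scale-free fit indices and the chosen power."""

    powers: list[int]
    fit_r2: list[float]  # signed: R² × sign(slope)
    mean_connectivity: list[float]
    chosen_beta: int
    r2_cut: float
    met_cut: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "signed_r2": self.fit_r2,
                "mean_connectivity": self.mean_connectivity,
            }
        )


@dataclass
class ModuleAssignment:
    """Gene → module color map (``grey`` = unassigned)."""

    colors: pd.Series  # index: gene ids, values: color strings

    @property
    def modules(self) -> list[str]:
        sizes = self.colors[self.colors != GREY].value_counts()
        return list(sizes.index)

    def sizes(self) -> pd.Series:
        return self.colors.value_counts()

    def genes_in(self, color: str) -> list[str]:
        return list(self.colors.index[self.colors == color])


def _pearson_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Gene × gene Pearson correlation; constant genes yield NaN rows."""
    values = matrix.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(values)
    return cor


def scale_free_fit(connectivities: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit index of a connectivity distribution.

    Bins the connectivities into ``n_bins`` equal-width bins, regresses
    log10(frequency) on log10(mean connectivity) over non-empty bins, and
    returns (−sign(slope) · R², slope): a decaying power-law degree
    distribution (negative slope) scores near +1, an increasing one near
    −1.
    """
    k = np.asarray(connectivities, dtype=float)
    k = k[np.isfinite(k) & (k > 0)]
    if len(np.unique(k)) < 2:
        raise ValueError("scale-free fit undefined: all connectivities equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(len(members) / len(k)))
    if len(log_k) < 2:
        raise ValueError("scale-free fit undefined: fewer than 2 non-empty bins")
    slope, _, r, _, _ = stats.linregress(log_k, log_f)
    return float(-np.sign(slope) * r**2), float(slope)


def adjacency(cor_matrix: np.ndarray, beta: float, mode: str = "unsigned") -> np.ndarray:
    """Soft-threshold a correlation matrix into an adjacency matrix.

    unsigned: a_ij = |cor_ij|^beta; signed: a_ij = ((1 + cor_ij)/2)^beta.
    The diagonal is set to 0 so connectivity sums exclude self-adjacency.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    cor = np.asarray(cor_matrix, dtype=float)
    if mode == "unsigned":
        adj = np.abs(cor) ** beta
    elif mode == "signed":
        adj = ((1.0 + cor) / 2.0) ** beta
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(adj, 0.0)
    return adj


def pick_soft_threshold(
    matrix: pd.DataFrame,
    powers: list[int] | None = None,
    r2_cut: float = 0.9,
    mode: str = "unsigned",
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers and choose the smallest meeting the R² cut.

    If no power reaches ``r2_cut`` the power maximizing the signed R² is
    chosen with a warning. Degenerate inputs where every gene pair is
    perfectly correlated (constant connectivity) raise at every power and
    therefore an error overall.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    powers = list(powers) if powers is not None else list(range(1, 21))
    cor = _pearson_matrix(matrix)
    fit_r2, mean_k = [], []
    any_ok = False
    for beta in powers:
        adj = adjacency(cor, beta, mode=mode)
        k = np.nansum(adj, axis=1)
        mean_k.append(float(np.mean(k)))
        try:
            r2, _ = scale_free_fit(k, n_bins=n_bins)
            if not np.isfinite(r2):
                raise ValueError("fit index undefined (degenerate bins)")
            any_ok = True
        except ValueError as exc:
            warnings.warn(f"power {beta}: {exc}", stacklevel=2)
            r2 = np.nan
        fit_r2.append(r2)
    if not any_ok:
        raise ValueError("scale-free fit failed at every candidate power (degenerate input)")
    chosen = None
    for beta, r2 in zip(powers, fit_r2):
        if np.isfinite(r2) and r2 >= r2_cut:
            chosen = beta
            break
    met = chosen is not None
    if chosen is None:
        finite = [(r2, b) for b, r2 in zip(powers, fit_r2) if np.isfinite(r2)]
        chosen = max(finite)[1]
        warnings.warn(
            f"no power reached signed R² ≥ {r2_cut}; using power {chosen} "
            f"with max R² = {max(finite)[0]:.3f}",
            stacklevel=2,
        )
    return SoftThresholdScan(powers, fit_r2, mean_k, int(chosen), r2_cut, met)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an adjacency matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) for i ≠ j with
    l_ij = Σ_u a_iu a_uj (u ≠ i, j) and k_i = Σ_u a_iu; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # diagonal of a is 0, so u = i and u = j terms vanish
    k_min = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (k_min + 1.0 - a)
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(matrix_subset: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of a module's standardized expression.

    Genes are standardized (mean 0, sd 1); the eigengene is the unit-norm
    first right-singular vector over samples, sign-flipped so it correlates
    non-negatively with the module's mean standardized profile. Returns
    (eigengene, proportion of variance explained). Zero-variance genes are
    dropped with a warning.
    """
    if matrix_subset.shape[0] < 2:
        raise ValueError("module eigengene needs at least 2 genes")
    if matrix_subset.shape[1] < 3:
        raise ValueError("module eigengene needs at least 3 samples")
    values = matrix_subset.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    if (sd == 0).any():
        dropped = list(matrix_subset.index[sd == 0])
        warnings.warn(f"dropping zero-variance genes from module: {dropped}", stacklevel=2)
        values = values[sd > 0]
        if values.shape[0] < 2:
            raise ValueError("fewer than 2 non-constant genes in module")
        sd = sd[sd > 0]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return pd.Series(eig, index=matrix_subset.columns, name="ME"), var_explained


def _eigengene_table(matrix: pd.DataFrame, colors: pd.Series) -> pd.DataFrame:
    mes = {}
    for color in colors[colors != GREY].unique():
        genes = colors.index[colors == color]
        me, _ = module_eigengene(matrix.loc[genes])
        mes[color] = me
    return pd.DataFrame(mes, index=matrix.columns)


def _order_colors(labels: pd.Series) -> pd.Series:
    """Map arbitrary cluster labels to size-ordered conventional colors."""
    counts = labels[labels != -1].value_counts()
    # decreasing size; ties by smallest member gene id for determinism
    firsts = {
        lab: min(labels.index[labels == lab]) for lab in counts.index
    }
    ordered = sorted(counts.index, key=lambda lab: (-counts[lab], firsts[lab]))
    if len(ordered) > len(MODULE_COLORS):
        raise ValueError(f"more than {len(MODULE_COLORS)} modules detected")
    mapping = {lab: MODULE_COLORS[i] for i, lab in enumerate(ordered)}
    mapping[-1] = GREY
    return labels.map(mapping)


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    matrix: pd.DataFrame | None = None,
    min_size: int = 30,
    cut_height: float = 0.995,
    merge_cut: float = 0.25,
) -> tuple[ModuleAssignment, pd.DataFrame | None]:
    """Detect modules by average-linkage clustering of the TOM dissimilarity.

    The dendrogram of 1−TOM is cut statically at ``cut_height``; clusters
    smaller than ``min_size`` become grey. When the expression ``matrix`` is
    provided, module eigengenes are computed and modules whose eigengene
    dissimilarity (1 − correlation) falls below ``merge_cut`` are merged
    iteratively until stable. Returns the color assignment and the final
    eigengene table (samples × modules), or None when no matrix was given.
    """
    gene_index = pd.Index(gene_ids, name="gene")
    n = len(gene_index)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match gene list")
    if n < min_size:
        warnings.warn("fewer genes than min module size: all genes grey", stacklevel=2)
        colors = pd.Series(GREY, index=gene_index)
        return ModuleAssignment(colors), None
    diss = 1.0 - np.asarray(tom, dtype=float)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    link = average(squareform(diss, checks=False))

    def _cut(height: float) -> pd.Series:
        raw = fcluster(link, t=height, criterion="distance")
        out = pd.Series(raw, index=gene_index)
        out[out.map(out.value_counts()) < min_size] = -1
        return out

    labels = _cut(cut_height)
    if (labels == -1).all() and link.shape[0] >= 2:
        # high soft-threshold powers compress TOM toward 0, pushing every
        # merge above the static cut; fall back to cutting at the largest
        # gap in the upper merge heights, which separates planted blocks
        # from the background regardless of the overall scale
        heights = np.sort(link[:, 2])
        upper = heights[heights >= np.median(heights)]
        if len(upper) >= 2:
            gaps = np.diff(upper)
            idx = int(np.argmax(gaps))
            if gaps[idx] > 0:
                adaptive = float((upper[idx] + upper[idx + 1]) / 2.0)
                warnings.warn(
                    f"static cut at {cut_height} produced no modules; "
                    f"re-cutting at the largest height gap ({adaptive:.6f})",
                    stacklevel=2,
                )
                labels = _cut(adaptive)

    if matrix is not None and (labels != -1).any():
        labels = _merge_close_modules(matrix, labels, merge_cut)

    colors = _order_colors(labels)
    assignment = ModuleAssignment(colors)
    eigengenes = None
    if matrix is not None and (colors != GREY).any():
        eigengenes = _eigengene_table(matrix, colors)
    return assignment, eigengenes


def _merge_close_modules(
    matrix: pd.DataFrame, labels: pd.Series, merge_cut: float
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < merge_cut."""
    labels = labels.copy()
    while True:
        active = sorted(set(labels.unique()) - {-1})
        if len(active) < 2:
            return labels
        mes = {}
        for lab in active:
            genes = labels.index[labels == lab]
            me, _ = module_eigengene(matrix.loc[genes])
            mes[lab] = me.to_numpy()
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                d = 1.0 - np.corrcoef(mes[a], mes[b])[0, 1]
                if d < merge_cut and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            return labels
        _, a, b = best
        labels[labels == b] = a


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    cutoff: float = 0.3,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with the case indicator.

    Trait is encoded 1 = AS, 0 = HC; p-values are two-sided Student t with
    n−2 degrees of freedom. A module is selected when |r| ≥ cutoff. The
    grey (unassigned) bin is eligible for selection like any module, but a
    ``note`` column flags it.
    """
    trait = (phenotypes.loc[eigengenes.index, "group"] == "AS").astype(float)
    if trait.nunique() < 2:
        raise ValueError("trait indicator is constant; correlation undefined")
    rows = []
    for color in eigengenes.columns:
        me = eigengenes[color]
        if me.nunique() < 2:
            raise ValueError(f"constant eigengene for module {color!r}")
        r, p = stats.pearsonr(me, trait)
        rows.append(
            {
                "module": color,
                "r": float(r),
                "p": float(p),
                "selected": bool(abs(r) >= cutoff),
                "note": "unassigned-bin" if color == GREY else "",
            }
        )
    return pd.DataFrame(rows).set_index("module")


def gene_trait_stats(
    matrix: pd.DataFrame,
    eigengenes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    assignment: ModuleAssignment | None = None,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Gene significance, module membership, and per-module cor(MM, GS).

    GS_g = |cor(x_g, trait)|; MM_{g,m} = cor(x_g, ME_m). The third return
    value reports, for each module with an eigengene, the Pearson
    correlation (and p) between MM and GS over that module's genes
    (falling back to all genes when no assignment is given).
    """
    trait = (phenotypes.loc[matrix.columns, "group"] == "AS").astype(float).to_numpy()
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant genes from GS/MM: {list(matrix.index[~keep])}",
            stacklevel=2,
        )
    matrix = matrix.loc[matrix.index[keep]]
    values = values[keep]

    def _cor_with(vec: np.ndarray) -> np.ndarray:
        vz = (vec - vec.mean()) / vec.std(ddof=1)
        gz = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, ddof=1, keepdims=True
        )
        return gz @ vz / (len(vec) - 1)

    gs = pd.Series(np.abs(_cor_with(trait)), index=matrix.index, name="GS")
    mm = pd.DataFrame(
        {color: _cor_with(eigengenes[color].to_numpy()) for color in eigengenes.columns},
        index=matrix.index,
    )
    rows = []
    for color in eigengenes.columns:
        genes = (
            [g for g in assignment.genes_in(color) if g in matrix.index]
            if assignment is not None
            else list(matrix.index)
        )
        if len(genes) < 3:
            continue
        r, p = stats.pearsonr(mm.loc[genes, color].abs(), gs.loc[genes])
        rows.append({"module": color, "cor_mm_gs": float(r), "p": float(p), "n_genes": len(genes)})
    return gs, mm, pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()


def preservation_z(
    matrix: pd.DataFrame,
    assignment: ModuleAssignment,
    beta: float = 6,
    n_permutations: int = 100,
    seed: int = 0,
    mode: str = "unsigned",
) -> pd.Series:
    """Permutation Z-score of mean intramodular adjacency per module.

    obs_m is the mean off-diagonal adjacency within module m; the null
    redraws the module as a uniformly random gene subset of the same size,
    ``n_permutations`` times. Z_m = (obs_m − mean_null) / sd_null. A
    well-preserved (tight) module scores a large positive Z.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    modules = assignment.modules
    if not modules:
        raise ValueError("no non-grey modules to assess")
    rng = np.random.default_rng(seed)
    cor = _pearson_matrix(matrix)
    adj = adjacency(cor, beta, mode=mode)
    gene_pos = {g: i for i, g in enumerate(matrix.index)}

    def mean_intra(idx: np.ndarray) -> float:
        sub = adj[np.ix_(idx, idx)]
        n = len(idx)
        return float(sub.sum() / (n * (n - 1))) if n > 1 else 0.0

    out = {}
    n_genes = matrix.shape[0]
    for color in modules:
        idx = np.array([gene_pos[g] for g in assignment.genes_in(color) if g in gene_pos])
        obs = mean_intra(idx)
        null = np.array(
            [
                mean_intra(rng.choice(n_genes, size=len(idx), replace=False))
                for _ in range(n_permutations)
            ]
        )
        sd = null.std(ddof=1)
        if sd == 0:
            warnings.warn(f"degenerate permutation null for {color}; Z = +inf", stacklevel=2)
            out[color] = np.inf
        else:
            out[color] = (obs - null.mean()) / sd
    return pd.Series(out, name="preservation_z")
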