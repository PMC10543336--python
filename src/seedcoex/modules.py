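"""Weighted co-expression module detection.

The network model follows the classic weighted co-expression construction:
pairwise Spearman correlation, signed soft-threshold adjacency
a_ij = ((1 + rho_ij)/2)**beta, conversion to a topological overlap matrix
(TOM), average-linkage clustering of the TOM dissimilarity, a static height
cut with a minimum module size, and iterative merging of modules whose
eigengenes are closely correlated. Module eigengenes are the first principal
component of the per-gene standardized module expression; connectivity is
the adjacency row sum, whole-network (k) and intramodular (kWithin).

The adjacency diagonal is held at zero so connectivities and TOM exclude
self-edges; TOM_ii is reported as 1 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "NetworkModel",
    "filter_genes",
    "correlation_matrix",
    "adjacency",
    "pick_beta",
    "tom_similarity",
    "cut_modules",
    "module_eigengene",
    "connectivity",
    "detect_modules",
]


@dataclass
class NetworkModel:
    """Bundle of the fitted co-expression network."""

    gene_ids: list[str]
    correlation_method: str
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    module_labels: pd.Series  # gene -> module id, 0 = unassigned
    eigengenes: pd.DataFrame  # module x sample, unit-norm rows
    connectivity: pd.DataFrame  # gene -> k, kWithin
    variance_explained: dict[int, float] = field(default_factory=dict)

    def genes_in(self, module: int) -> list[str]:
        return list(self.module_labels.index[self.module_labels == module])

    @property
    def modules(self) -> list[int]:
        return sorted(m for m in self.module_labels.unique() if m != 0)


# ---------------------------------------------------------------------------
# filtering and correlation
# ---------------------------------------------------------------------------


def filter_genes(
    em: ExpressionMatrix, n_expressed: int = 50000, n_cv: int = 15000
) -> ExpressionMatrix:
    """Two-pass gene filter: top ``n_expressed`` by mean TPM, then among
    those the top ``n_cv`` by coefficient of variation (sd/mean).

    Ties break by gene id ascending; a constant gene (sd = 0) ranks last by
    CV. Either cutoff larger than the available gene count keeps everything.
    """
    if n_cv > n_expressed:
        raise ValueError(f"n_cv ({n_cv}) must not exceed n_expressed ({n_expressed})")
    v = em.values
    mean = v.mean(axis=1)
    step1 = (
        pd.DataFrame({"mean": mean})
        .sort_index(kind="stable")
        .sort_values(["mean"], ascending=False, kind="stable")
        .head(n_expressed)
        .index
    )
    sub = v.loc[step1]
    sd = sub.std(axis=1, ddof=1)
    m = sub.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (sd / m).to_numpy()
    cv = np.where(np.isfinite(cv), cv, 0.0)
    order = (
        pd.DataFrame({"cv": cv}, index=step1)
        .sort_index(kind="stable")
        .sort_values(["cv"], ascending=False, kind="stable")
        .head(n_cv)
        .index
    )
    keep = [g for g in em.gene_ids if g in set(order)]
    return em.subset_genes(keep)


def correlation_matrix(em: ExpressionMatrix, method: str = "spearman") -> np.ndarray:
    """Gene x gene correlation matrix (Spearman by default).

    Spearman uses average ranks for ties (rank transform then Pearson).
    Zero-variance genes get correlation 0 to every other gene, with a
    warning; the diagonal is 1 throughout.
    """
    if em.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation network")
    X = em.values.to_numpy()
    if method == "spearman":
        X = rankdata(X, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance genes; correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def adjacency(corr: np.ndarray, beta: int = 12) -> np.ndarray:
    """Signed soft-threshold adjacency ((1 + rho)/2)**beta, zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def pick_beta(
    corr: np.ndarray,
    grid: list[int] | None = None,
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate beta the connectivities k_i are binned into
    ``n_bins`` equal-occupancy bins; log10 p(k) is regressed on log10 of the
    per-bin mean k, and the fit index is R^2, signed negative when the slope
    is positive (a scale-free degree distribution has negative slope).
    Returns the smallest beta whose fit reaches ``r2_target``, else the
    argmax of the fit, along with the full fit table.
    """
    if grid is None:
        grid = [2, 4, 6, 8, 10, 12, 14, 16]
    if not grid:
        raise ValueError("empty beta grid")
    rows = []
    for b in sorted(grid):
        k = adjacency(corr, b).sum(axis=1)
        k = k[k > 0]
        if k.size == 0:
            raise ValueError("degenerate network: all connectivities zero")
        fit, slope, mean_k = _scale_free_fit(k, n_bins)
        rows.append({"beta": b, "fit": fit, "slope": slope, "mean_k": mean_k})
    table = pd.DataFrame(rows)
    ok = table[table["fit"] >= r2_target]
    best = int(ok["beta"].iloc[0]) if len(ok) else int(table.loc[table["fit"].idxmax(), "beta"])
    return best, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float, float]:
    """Signed R^2 of log10 p(k) on log10 k over equal-occupancy bins.

    Equal-occupancy bins hold (nearly) equal counts by construction, so the
    degree density at each bin is estimated as (count / total) / bin width;
    without the width normalization the regression response would be flat.
    """
    n_bins = min(n_bins, max(2, len(np.unique(k)) // 2), len(k))
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0, 0.0, float(k.mean())
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    for b in range(len(edges) - 1):
        sel = which == b
        width = edges[b + 1] - edges[b]
        if sel.sum() == 0 or width <= 0:
            continue
        mk = k[sel].mean()
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(sel.sum() / len(k) / width))
    xs, ys = np.asarray(xs), np.asarray(ys)
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0, 0.0, float(k.mean())
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    fit = -r2 if slope > 0 else r2
    return float(fit), float(slope), float(k.mean())


# ---------------------------------------------------------------------------
# TOM and module cutting
# ---------------------------------------------------------------------------


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    ``adj`` must be symmetric with zero diagonal and entries in [0, 1];
    l_ij = sum_u a_iu a_uj, k_i = sum_u a_iu. The diagonal is set to 1.
    """
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.diag(adj).any():
        raise ValueError("adjacency diagonal must be zero")
    L = adj @ adj
    k = adj.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - adj
    tom = (L + adj) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cut_modules(
    dissimilarity: np.ndarray,
    em: ExpressionMatrix,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_threshold: float = 0.25,
    kme_min: float = 0.5,
    method: str = "average",
) -> pd.Series:
    """Static-height tree cut of the TOM dissimilarity with membership
    pruning and eigengene merging.

    The dendrogram (average linkage) is cut at the absolute dissimilarity
    height ``cut_height``; clusters below ``min_module_size`` become
    unassigned (label 0). Genes whose module membership — the Pearson
    correlation of their profile with the module eigengene (kME) — falls
    below ``kme_min`` are unassigned, and modules shrinking below the size
    floor dissolve. Modules whose eigengene dissimilarity (1 - Pearson r)
    falls below ``merge_threshold`` are then merged iteratively, closest
    pair first. Labels are renumbered 1..M by decreasing module size.
    ``em`` supplies the expression used for eigengenes and must cover the
    same genes in the same order as ``dissimilarity``.
    """
    n = dissimilarity.shape[0]
    if em.shape[0] != n:
        raise ValueError("expression matrix and dissimilarity disagree on gene count")
    d = np.clip((dissimilarity + dissimilarity.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method=method)
    raw = fcluster(Z, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=em.gene_ids, name="module")
    labels = _drop_small(labels, min_module_size)
    if (labels == 0).all():
        warnings.warn("all genes unassigned; no module passed the size filter")
        return labels

    labels = _prune_by_kme(labels, em, kme_min)
    labels = _drop_small(labels, min_module_size)
    if (labels == 0).all():
        warnings.warn("all genes unassigned after membership pruning")
        return labels
    labels = _merge_close_modules(labels, em, merge_threshold)
    return _renumber_by_size(labels)


def _drop_small(labels: pd.Series, min_module_size: int) -> pd.Series:
    labels = labels.copy()
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = 0
    return labels


def _prune_by_kme(labels: pd.Series, em: ExpressionMatrix, kme_min: float) -> pd.Series:
    """Unassign genes with signed module membership kME below ``kme_min``."""
    labels = labels.copy()
    me, _ = module_eigengene(em, labels)
    X = em.values.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    norms[norms == 0] = np.inf
    Xc = Xc / norms
    for m in me.index:
        e = me.loc[m].to_numpy()
        e = e - e.mean()
        ne = np.linalg.norm(e)
        if ne == 0:
            continue
        e = e / ne
        sel = (labels == m).to_numpy()
        kme = Xc[sel] @ e
        genes = labels.index[sel]
        labels[genes[kme < kme_min]] = 0
    return labels


def _merge_close_modules(
    labels: pd.Series, em: ExpressionMatrix, merge_threshold: float
) -> pd.Series:
    labels = labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            return labels
        me, _ = module_eigengene(em, labels)
        E = me.loc[mods].to_numpy()
        corr = np.corrcoef(E)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_threshold:
            return labels
        keep, drop = sorted((mods[i], mods[j]))
        labels[labels == drop] = keep


def _renumber_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != 0].value_counts()
    order = sizes.sort_index().sort_values(ascending=False, kind="stable").index
    mapping = {old: new + 1 for new, old in enumerate(order)}
    mapping[0] = 0
    return labels.map(mapping).rename("module")


# ---------------------------------------------------------------------------
# eigengenes and connectivity
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def module_eigengene(
    em: ExpressionMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, dict[int, float]]:
    """First principal component of each module's standardized expression.

    Genes are standardized to zero mean / unit variance over samples; the
    eigengene is the leading right singular vector (a unit-norm sample
    profile), sign-aligned so its correlation with the module's mean
    standardized expression is positive. Also returns the fraction of
    module variance the eigengene explains. A single-gene module's eigengene
    is that gene's standardized profile (unit-normalized).
    """
    rows, varexp = [], {}
    mods = sorted(m for m in labels.unique() if m != 0)
    for m in mods:
        genes = list(labels.index[labels == m])
        X = _standardize(em.values.loc[genes].to_numpy())
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        v = vt[0]
        mean_profile = X.mean(axis=0)
        if mean_profile @ v < 0:
            v = -v
        rows.append(v)
        total = (s**2).sum()
        varexp[m] = float(s[0] ** 2 / total) if total > 0 else 0.0
    me = pd.DataFrame(rows, index=mods, columns=em.sample_ids)
    return me, varexp


def connectivity(adj: np.ndarray, labels: pd.Series) -> pd.DataFrame:
    """Whole-network (k) and intramodular (kWithin) adjacency row sums."""
    if np.diag(adj).any():
        raise ValueError("adjacency diagonal must be zero")
    genes = list(labels.index)
    k = adj.sum(axis=1)
    lab = labels.to_numpy()
    same = lab[:, None] == lab[None, :]
    k_within = (adj * same).sum(axis=1)
    return pd.DataFrame({"module": lab, "k": k, "kWithin": k_within}, index=genes)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


def detect_modules(
    em: ExpressionMatrix,
    n_expressed: int = 50000,
    n_cv: int = 15000,
    method: str = "spearman",
    beta: int | None = 12,
    beta_grid: list[int] | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    merge_threshold: float = 0.25,
    kme_min: float = 0.5,
) -> NetworkModel:
    """Full module-detection pipeline on a replicate-averaged TPM matrix.

    Filters genes, correlates on log2(TPM+1) (rank-based for Spearman the
    transform is immaterial, but eigengenes use the log scale), builds the
    signed adjacency at ``beta`` (or picks beta on ``beta_grid`` when
    ``beta`` is None), computes TOM, cuts modules and derives eigengenes
    and connectivity.
    """
    filtered = filter_genes(em, n_expressed=n_expressed, n_cv=n_cv)
    logem = ExpressionMatrix(np.log2(filtered.values + 1.0), filtered.sample_meta)
    corr = correlation_matrix(logem, method=method)
    if beta is None:
        beta, _ = pick_beta(corr, beta_grid)
    adj = adjacency(corr, beta)
    tom = tom_similarity(adj)
    labels = cut_modules(
        1.0 - tom,
        logem,
        min_module_size=min_module_size,
        cut_height=cut_height,
        merge_threshold=merge_threshold,
        kme_min=kme_min,
    )
    me, varexp = module_eigengene(logem, labels)
    conn = connectivity(adj, labels)
    return NetworkModel(
        gene_ids=logem.gene_ids,
        correlation_method=method,
        beta=int(beta),
        adjacency=adj,
        tom=tom,
        module_labels=labels,
        eigengenes=me,
        connectivity=conn,
        variance_explained=varexp,
    )
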