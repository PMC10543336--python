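"""Replicate QC, averaging, log transform, PCA, and stage assignment.

A seed development time course is staged by hierarchically clustering the
averaged, log2(TPM+1)-transformed time-point profiles under Pearson
correlation distance (1 - r) and cutting the tree into K clusters. Stages
are renumbered by ascending mean DAF so stage 1 is the earliest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "StageAssignment",
    "replicate_correlation",
    "average_replicates",
    "log_transform",
    "pca_project",
    "assign_stages",
]


@dataclass
class StageAssignment:
    """Stage labels (1..K) for each averaged time-point column."""

    stages: pd.Series  # index: time-point sample id, values 1..K
    K: int
    linkage_matrix: np.ndarray  # scipy linkage record of the merge heights

    def timepoints_in(self, stage: int) -> list[str]:
        return list(self.stages.index[self.stages == stage])

    @property
    def sizes(self) -> dict[int, int]:
        return self.stages.value_counts().sort_index().to_dict()


def _groups(em: ExpressionMatrix) -> pd.core.groupby.DataFrameGroupBy:
    meta = em.sample_meta.copy()
    meta["daf"] = meta["daf"].astype("Int64")
    return meta.groupby(["tissue", "daf"], dropna=False, sort=True)


def replicate_correlation(
    em: ExpressionMatrix, qc_threshold: float = 0.90
) -> pd.DataFrame:
    """Squared Pearson correlation (R^2) between replicate pairs per time point.

    Returns one row per within-time-point replicate pair with columns
    ``tissue, daf, sample_a, sample_b, r2, pass_qc``. A zero-variance
    replicate yields ``r2 = NaN`` and ``pass_qc = False`` rather than an
    exception.
    """
    rows = []
    logv = np.log2(em.values.to_numpy() + 1.0)
    cols = {s: i for i, s in enumerate(em.sample_ids)}
    any_pair = False
    for (tissue, daf), grp in _groups(em):
        samples = list(grp.index)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                any_pair = True
                a, b = logv[:, cols[samples[i]]], logv[:, cols[samples[j]]]
                if a.std() == 0 or b.std() == 0:
                    r2 = np.nan
                else:
                    r2 = float(np.corrcoef(a, b)[0, 1] ** 2)
                rows.append(
                    {
                        "tissue": tissue,
                        "daf": daf,
                        "sample_a": samples[i],
                        "sample_b": samples[j],
                        "r2": r2,
                        "pass_qc": bool(r2 >= qc_threshold) if np.isfinite(r2) else False,
                    }
                )
    if not any_pair:
        raise ValueError("no time point has >= 2 replicates")
    return pd.DataFrame(rows)


def average_replicates(em: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean TPM across replicates of each (tissue, DAF) group.

    Metadata collapses to one row per group; a group with a single
    replicate passes through unchanged. Averaged column ids are
    ``{tissue}_{daf}DAF`` (or the tissue label when DAF is absent).
    """
    means, ids, tissues, dafs = [], [], [], []
    for (tissue, daf), grp in _groups(em):
        cols = list(grp.index)
        means.append(em.values[cols].mean(axis=1))
        if pd.isna(daf):
            ids.append(str(tissue))
            dafs.append(pd.NA)
        else:
            ids.append(f"{tissue}_{int(daf)}DAF")
            dafs.append(int(daf))
        tissues.append(tissue)
    values = pd.concat(means, axis=1)
    values.columns = ids
    meta = pd.DataFrame(
        {
            "tissue": tissues,
            "daf": pd.array(dafs, dtype="Int64"),
            "replicate": pd.array([pd.NA] * len(ids), dtype="Int64"),
        },
        index=ids,
    )
    return ExpressionMatrix(values, meta)


def log_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1)."""
    return ExpressionMatrix(np.log2(em.values + 1.0), em.sample_meta)


def pca_project(em: ExpressionMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the first k principal components.

    Samples are observations, genes features; features are centered. Returns
    (scores: samples x k, explained variance fractions). A constant matrix
    yields all-zero scores and zero variance fractions.
    """
    X = em.values.to_numpy().T  # samples x genes
    n = X.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} exceeds n_samples-1={n - 1}")
    Xc = X - X.mean(axis=0, keepdims=True)
    total = float((Xc**2).sum())
    if total == 0.0:
        return (
            pd.DataFrame(np.zeros((n, k)), index=em.sample_ids,
                         columns=[f"PC{i+1}" for i in range(k)]),
            np.zeros(k),
        )
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, :k] * s[:k]
    evr = (s[:k] ** 2) / (s**2).sum()
    return (
        pd.DataFrame(scores, index=em.sample_ids,
                     columns=[f"PC{i+1}" for i in range(k)]),
        evr,
    )


def assign_stages(
    em: ExpressionMatrix, K: int = 5, method: str = "average"
) -> StageAssignment:
    """Cluster time points into K stages on Pearson correlation distance.

    ``em`` should already be replicate-averaged and log-transformed. The
    distance between two time points is 1 - r over their gene profiles;
    hierarchical clustering (average linkage by default) is cut into K
    clusters and stages renumbered 1..K by ascending mean DAF (column order
    when DAF is absent).
    """
    n = em.shape[1]
    if K > n:
        raise ValueError(f"K={K} exceeds number of time points ({n})")
    X = em.values.to_numpy().T  # timepoints x genes
    sd = X.std(axis=1)
    if (sd == 0).any():
        warnings.warn("zero-variance time-point profile; correlation set to 0")
        corr = np.zeros((n, n))
        ok = sd > 0
        if ok.sum() >= 2:
            corr[np.ix_(ok, ok)] = np.corrcoef(X[ok])
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)
    raw = fcluster(Z, t=K, criterion="maxclust")

    # renumber by ascending mean DAF
    daf = em.sample_meta["daf"]
    order_key = (
        daf.astype(float).to_numpy()
        if daf.notna().all()
        else np.arange(n, dtype=float)
    )
    cluster_ids = np.unique(raw)
    mean_daf = {c: order_key[raw == c].mean() for c in cluster_ids}
    rank = {c: i + 1 for i, c in enumerate(sorted(cluster_ids, key=lambda c: mean_daf[c]))}
    stages = pd.Series([rank[c] for c in raw], index=em.sample_ids, name="stage")
    return StageAssignment(stages=stages, K=len(cluster_ids), linkage_matrix=Z)
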