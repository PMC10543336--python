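"""Tissue-specificity scoring (tau index) and stage-marker screening.

Tau is the quantile-free specificity index computed on log2(TPM+1)
per-tissue means: with per-tissue values x_i and xhat_i = x_i / max(x),

    tau = sum_i (1 - xhat_i) / (N - 1)

for N tissues. Tau is 1 when a gene is expressed in a single tissue and 0
when expression is uniform. Genes whose maximum TPM never exceeds
``min_tpm`` in any tissue are excluded from scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .staging import StageAssignment

__all__ = ["compute_tau", "seed_specific_genes", "stage_markers"]


def _collapse_tissues(em: ExpressionMatrix) -> pd.DataFrame:
    """Mean TPM per tissue label (genes x tissues)."""
    tissue = em.sample_meta["tissue"]
    return em.values.T.groupby(tissue.to_numpy()).mean().T


def compute_tau(
    em: ExpressionMatrix,
    min_tpm: float = 1.0,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-gene tau over tissue-mean expression.

    Returns a DataFrame indexed by gene with columns ``tau`` (NaN when the
    gene is excluded), ``argmax_tissue``, ``specific`` (tau > threshold) and
    ``excluded`` (max TPM <= min_tpm in every tissue).
    """
    by_tissue = _collapse_tissues(em)
    if by_tissue.shape[1] < 2:
        raise ValueError("tau is undefined with a single tissue")
    max_tpm = by_tissue.max(axis=1)
    excluded = max_tpm <= min_tpm

    x = np.log2(by_tissue.to_numpy() + 1.0)
    xmax = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = x / xmax[:, None]
    n = x.shape[1]
    tau = (1.0 - xhat).sum(axis=1) / (n - 1)
    tau[xmax == 0] = np.nan
    tau[excluded.to_numpy()] = np.nan

    argmax = by_tissue.columns.to_numpy()[x.argmax(axis=1)]
    out = pd.DataFrame(
        {
            "tau": tau,
            "argmax_tissue": argmax,
            "specific": (tau > threshold) & ~excluded.to_numpy(),
            "excluded": excluded.to_numpy() | ~np.isfinite(tau),
        },
        index=by_tissue.index,
    )
    return out


def seed_specific_genes(
    atlas: ExpressionMatrix,
    seed_tissues: set[str] | None = None,
    threshold: float = 0.9,
    min_tpm: float = 1.0,
) -> set[str]:
    """Genes with tau > threshold whose top tissue is a seed tissue.

    ``seed_tissues`` defaults to tissue labels containing "seed"
    (case-insensitive). The atlas must contain at least one seed and one
    non-seed tissue.
    """
    tissues = set(atlas.sample_meta["tissue"])
    if seed_tissues is None:
        seed_tissues = {t for t in tissues if "seed" in str(t).lower()}
    if not seed_tissues or seed_tissues >= tissues:
        raise ValueError("atlas must contain both seed and non-seed tissues")
    res = compute_tau(atlas, min_tpm=min_tpm, threshold=threshold)
    hit = res["specific"] & res["argmax_tissue"].isin(seed_tissues)
    return set(res.index[hit])


def stage_markers(
    em: ExpressionMatrix,
    stages: StageAssignment,
    tau_stage: float = 0.8,
    min_tpm: float = 1.0,
) -> dict[int, set[str]]:
    """Stage-specific marker genes from per-stage mean profiles.

    For each gene the K per-stage means of log2(TPM+1) (over the time points
    in each stage) are scored with tau; the gene marks stage s when its
    stage-level tau exceeds ``tau_stage``, its maximal stage mean is s, and
    its maximum raw TPM exceeds ``min_tpm``. ``em`` must be the
    replicate-averaged time course whose columns carry the stage labels.
    """
    logv = np.log2(em.values + 1.0)
    stage_of = stages.stages
    cols_by_stage = {s: stages.timepoints_in(s) for s in sorted(stage_of.unique())}
    K = len(cols_by_stage)
    if K < 2:
        raise ValueError("stage markers need at least two stages")
    stage_means = np.column_stack(
        [logv[cols].mean(axis=1).to_numpy() for cols in cols_by_stage.values()]
    )
    stage_ids = list(cols_by_stage)

    xmax = stage_means.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = stage_means / xmax[:, None]
    tau = (1.0 - xhat).sum(axis=1) / (K - 1)
    expressed = em.values.max(axis=1).to_numpy() > min_tpm
    ok = (tau > tau_stage) & (xmax > 0) & expressed
    arg = stage_means.argmax(axis=1)

    out: dict[int, set[str]] = {s: set() for s in stage_ids}
    genes = em.values.index.to_numpy()
    for g, a in zip(genes[ok], arg[ok]):
        out[stage_ids[a]].add(g)
    return out
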