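"""Guide-gene network expansion, hub calling, and display filtering.

A pathway-annotated guide set (e.g. acyl-lipid genes) is expanded against a
candidate set (genes assigned to co-expression modules): a candidate becomes
a first-degree partner (P1) when the absolute Pearson correlation of its
averaged log2(TPM+1) profile with at least one guide exceeds ``r_retain``
(0.8). All guide-guide, guide-P1 and P1-P1 edges above the same threshold
are kept. Hub genes are the transcription factors in each module plus the
top 10% of genes by intramodular connectivity. A stricter ``r_view``
threshold (0.9) selects the subnetwork typically exported for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .modules import NetworkModel

__all__ = ["GuideNetwork", "expand_guides", "hub_genes", "display_subnetwork"]


@dataclass
class GuideNetwork:
    """Guide/partner nodes with correlation-weighted edges."""

    nodes: pd.DataFrame  # index gene, column role in {guide, partner}
    edges: pd.DataFrame  # columns source, target, r
    r_retain: float

    @property
    def guides(self) -> set[str]:
        return set(self.nodes.index[self.nodes["role"] == "guide"])

    @property
    def partners(self) -> set[str]:
        return set(self.nodes.index[self.nodes["role"] == "partner"])

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [
            (r.source, r.target, float(r.r)) for r in self.edges.itertuples()
        ]


def expand_guides(
    em: ExpressionMatrix,
    guides: set[str],
    candidates: set[str],
    r_retain: float = 0.8,
) -> GuideNetwork:
    """Expand a guide set to its P1 partners at |Pearson r| > ``r_retain``.

    ``em`` is the replicate-averaged time course; correlations are computed
    on log2(TPM+1). Guides absent from the matrix are ignored; an empty
    guide overlap is an error. The result is invariant to the iteration
    order of ``guides`` and ``candidates``.
    """
    genes = set(em.gene_ids)
    guides_in = sorted(guides & genes)
    if not guides_in:
        raise ValueError("no guide gene present in the expression matrix")
    cand_in = sorted((candidates & genes) - set(guides_in))

    all_genes = guides_in + cand_in
    X = np.log2(em.values.loc[all_genes].to_numpy() + 1.0)
    sd = X.std(axis=1)
    ok = sd > 0
    corr = np.zeros((len(all_genes), len(all_genes)))
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            corr[np.ix_(ok, ok)] = np.corrcoef(X[ok])
    np.fill_diagonal(corr, 1.0)

    n_g = len(guides_in)
    to_guides = np.abs(corr[:, :n_g])
    is_p1 = np.zeros(len(all_genes), dtype=bool)
    is_p1[n_g:] = to_guides[n_g:].max(axis=1) > r_retain

    keep = np.zeros(len(all_genes), dtype=bool)
    keep[:n_g] = True
    keep |= is_p1
    kept_idx = np.flatnonzero(keep)

    edges = []
    for ii, i in enumerate(kept_idx):
        for j in kept_idx[ii + 1:]:
            r = corr[i, j]
            if abs(r) > r_retain:
                edges.append((all_genes[i], all_genes[j], float(r)))
    nodes = pd.DataFrame(
        {"role": ["guide"] * n_g + ["partner"] * int(is_p1.sum())},
        index=guides_in + [all_genes[i] for i in np.flatnonzero(is_p1)],
    )
    return GuideNetwork(
        nodes=nodes,
        edges=pd.DataFrame(edges, columns=["source", "target", "r"]),
        r_retain=r_retain,
    )


def hub_genes(
    model: NetworkModel,
    tf_flags: set[str] | None = None,
    top_frac: float = 0.10,
    use_whole_network_k: bool = False,
) -> set[str]:
    """Module hubs: every TF in a module, plus the top ``top_frac`` of each
    module by intramodular connectivity (ceil, so a 1-gene module still
    yields a hub). Connectivity ties break by gene id ascending.
    """
    tf_flags = tf_flags or set()
    conn = model.connectivity
    metric = "k" if use_whole_network_k else "kWithin"
    hubs: set[str] = set()
    for m in model.modules:
        sub = conn[conn["module"] == m]
        hubs.update(set(sub.index) & tf_flags)
        n_top = math.ceil(top_frac * len(sub))
        ranked = sub.sort_index(kind="stable").sort_values(
            metric, ascending=False, kind="stable"
        )
        hubs.update(ranked.head(n_top).index)
    return hubs


def display_subnetwork(network: GuideNetwork, r_view: float = 0.9) -> pd.DataFrame:
    """Edges with |r| > ``r_view``; nodes left isolated are dropped.

    ``r_view`` must be at least the network's retention threshold, so the
    displayed network is always a subgraph of the retained one.
    """
    if r_view < network.r_retain:
        raise ValueError(
            f"r_view ({r_view}) below the network's r_retain ({network.r_retain})"
        )
    return network.edges[network.edges["r"].abs() > r_view].reset_index(drop=True)
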