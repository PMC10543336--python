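"""Functional-category over-representation testing.

Each (module, category) pair is tested with a one-sided Fisher exact test —
the hypergeometric upper tail P(X >= k) for k category hits in an n-gene
module drawn from an N-gene universe containing K category members — and
Benjamini-Hochberg adjusted across all pairs jointly, significant at
FDR < 0.05.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["fisher_enrichment", "bh_adjust"]


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending-sorted p-values,
    clipped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fisher_enrichment(
    gene_sets: Mapping[int | str, set[str]],
    category_map: Mapping[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of functional categories in gene sets.

    Parameters
    ----------
    gene_sets
        Module id -> member genes; every member must belong to ``universe``.
    category_map
        Gene -> one or more category labels. Genes outside the universe are
        ignored; categories with zero universe hits are skipped.
    universe
        The background gene set (here, typically the genes that entered
        module detection).

    Returns a table with one row per (module, category) pair: k (hits in
    module), n (module size), K (hits in universe), N (universe size), the
    one-sided Fisher p, the BH q across all rows jointly, and the
    significance call at ``fdr``.
    """
    if not universe:
        raise ValueError("empty universe")
    universe = set(universe)
    for mod, genes in gene_sets.items():
        stray = genes - universe
        if stray:
            raise ValueError(
                f"module {mod!r} contains genes outside the universe, e.g. "
                f"{sorted(stray)[:3]}"
            )

    cat_members: dict[str, set[str]] = {}
    for g, cats in category_map.items():
        if g in universe:
            for c in cats:
                cat_members.setdefault(c, set()).add(g)
    N = len(universe)

    rows = []
    for mod in gene_sets:
        genes = gene_sets[mod]
        n = len(genes)
        for cat in sorted(cat_members):
            members = cat_members[cat]
            K = len(members)
            k = len(genes & members)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append(
                {"module": mod, "category": cat, "k": k, "n": n, "K": K, "N": N, "p": p}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        table["q"] = []
        table["significant"] = []
        return table
    table["p"] = table["p"].clip(upper=1.0)
    table["q"] = bh_adjust(table["p"])
    table["significant"] = table["q"] < fdr
    return table
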