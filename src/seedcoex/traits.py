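"""Integration of co-expression results with trait and haplotype data.

Four steps link network genes to seed traits across an accession panel:
Pearson correlation of per-gene expression with a trait; intersection of
trait-associated (TWAS) genes with co-expression hub genes ("overlap"
candidates); mining of TWAS genes inside guide-enriched modules that
correlate strongly with a guide; and pooled-variance Student's t tests of
trait or expression differences between the two major haplotype groups of a
gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, HaplotypeTable, TraitTable
from .modules import NetworkModel

__all__ = [
    "AssociationRecord",
    "CandidateSet",
    "HaplotypeTestResult",
    "trait_correlation",
    "overlap_candidates",
    "mine_candidates",
    "haplotype_test",
]


@dataclass
class CandidateSet:
    """Candidate genes with per-gene provenance."""

    method: str  # "overlap" or "mining"
    genes: set[str]
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class HaplotypeTestResult:
    gene: str
    hap_a: str
    hap_b: str
    response: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    p: float
    skipped: str | None = None


def trait_correlation(
    pop_expr: ExpressionMatrix, traits: TraitTable, trait: str
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression (TPM) with a trait.

    Accessions missing the trait are dropped per gene; two-sided p-values
    come from the t distribution with n-2 degrees of freedom. Zero-variance
    genes are reported with NaN correlation and flagged ``undefined``.
    Requires at least 3 accessions shared between expression and trait.
    """
    t_vals = traits.trait(trait)
    shared = [a for a in pop_expr.sample_ids if a in t_vals.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 accessions with both expression and trait")
    y = t_vals.loc[shared].to_numpy(dtype=float)
    X = pop_expr.values[shared].to_numpy(dtype=float)
    n = len(shared)

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    undefined = (sx == 0) | (sy == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[undefined] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p[undefined] = np.nan
    return pd.DataFrame(
        {
            "trait": trait,
            "n": n,
            "pcc": r,
            "p": p,
            "undefined": undefined,
        },
        index=pop_expr.gene_ids,
    )


def overlap_candidates(twas_genes: set[str], hub_genes: set[str]) -> CandidateSet:
    """Genes detected by both routes: TWAS-significant and co-expression hub."""
    genes = set(twas_genes) & set(hub_genes)
    prov = pd.DataFrame(
        {"twas": True, "hub": True}, index=sorted(genes)
    )
    return CandidateSet(method="overlap", genes=genes, provenance=prov)


def mine_candidates(
    twas_genes: set[str],
    guides: set[str],
    model: NetworkModel,
    em: ExpressionMatrix,
    enrich_p: float = 0.05,
    r_min: float = 0.8,
) -> CandidateSet:
    """Two-filter candidate mining in guide-enriched modules.

    Step 1 keeps modules over-represented for guide genes (hypergeometric
    upper-tail p < ``enrich_p``; universe = the networked genes). Step 2
    keeps TWAS genes inside those modules whose averaged log2(TPM+1) profile
    has |Pearson r| >= ``r_min`` with at least one guide. Provenance records
    each candidate's module and best-supporting guide.
    """
    labels = model.module_labels
    universe = set(labels.index)
    guides_in = guides & universe
    N, K = len(universe), len(guides_in)

    enriched = []
    for m in model.modules:
        members = set(labels.index[labels == m])
        n, k = len(members), len(members & guides_in)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        if p < enrich_p:
            enriched.append(m)
    if not enriched:
        import warnings

        warnings.warn("no module enriched for guide genes; empty candidate set")
        return CandidateSet(method="mining", genes=set(), provenance=pd.DataFrame())

    pool = sorted(
        g
        for g in (set(twas_genes) & universe)
        if labels[g] in enriched
    )
    guide_list = sorted(guides & set(em.gene_ids))
    if not pool or not guide_list:
        return CandidateSet(method="mining", genes=set(), provenance=pd.DataFrame())

    logv = np.log2(em.values + 1.0)
    G = _standard_rows(logv.loc[guide_list].to_numpy())
    rows = []
    genes = set()
    for g in pool:
        x = _standard_rows(logv.loc[[g]].to_numpy())[0]
        r = G @ x / (len(x) - 1)
        best = int(np.abs(r).argmax())
        if abs(r[best]) >= r_min:
            genes.add(g)
            rows.append(
                {
                    "gene": g,
                    "module": int(labels[g]),
                    "guide": guide_list[best],
                    "r": float(r[best]),
                }
            )
    prov = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
    return CandidateSet(method="mining", genes=genes, provenance=prov)


def _standard_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = np.inf  # zero-variance rows correlate 0 with everything
    return (X - mu) / sd


def haplotype_test(
    haps: HaplotypeTable,
    response: pd.Series,
    gene: str,
    response_name: str = "trait",
    min_group: int = 10,
    welch: bool = False,
) -> HaplotypeTestResult:
    """Student's t test between the two major haplotype groups of a gene.

    ``response`` maps accession -> value (a trait, or the gene's panel
    expression). The two most frequent haplotype labels are compared with a
    pooled-variance two-sample t test (Welch by flag). When fewer than two
    haplotypes reach ``min_group`` accessions with data the test is skipped,
    with the reason recorded.
    """
    calls = haps.calls_for(gene)
    shared = calls.index.intersection(response.dropna().index)
    calls = calls.loc[shared]
    counts = calls.value_counts()
    top = counts[counts >= min_group]
    if len(top) < 2:
        return HaplotypeTestResult(
            gene, "", "", response_name, 0, 0, np.nan, np.nan, np.nan, np.nan,
            skipped=f"fewer than two haplotypes with >= {min_group} accessions",
        )
    hap_a, hap_b = top.index[0], top.index[1]
    a = response.loc[calls.index[calls == hap_a]].to_numpy(dtype=float)
    b = response.loc[calls.index[calls == hap_b]].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return HaplotypeTestResult(
        gene=gene,
        hap_a=str(hap_a),
        hap_b=str(hap_b),
        response=response_name,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=float(t),
        p=float(p),
    )
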