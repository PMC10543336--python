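"""Domain containers and TSV/graph readers and writers shared by the pipeline.

All tabular inputs and outputs are tab-separated UTF-8 text with a header
row. Gene, sample and accession identifiers are opaque, case-sensitive
strings; no identifier mapping between assemblies or species is attempted.
Expression matrices are dense TPM (transcripts per million) with genes as
rows and samples as columns; missing expression values are rejected at load
time, while per-sample metadata fields (days after flowering, replicate)
may be absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "TraitTable",
    "HaplotypeTable",
    "LoadError",
    "read_expression",
    "write_expression",
    "write_network",
    "read_network",
    "read_gene_set",
    "write_gene_set",
    "read_tf_flags",
    "read_categories",
    "read_traits",
    "read_haplotypes",
    "load_config",
    "DEFAULT_CONFIG",
]

#: Every tunable threshold used by the pipeline, with its default.
DEFAULT_CONFIG: dict = {
    "qc_r2_threshold": 0.90,
    "n_stages": 5,
    "linkage": "average",
    "tau_threshold": 0.9,
    "tau_stage_threshold": 0.8,
    "min_tpm": 1.0,
    "n_expressed": 50000,
    "n_cv": 15000,
    "correlation": "spearman",
    "beta": 12,
    "r2_target": 0.8,
    "min_module_size": 30,
    "cut_height": 0.99,
    "kme_min": 0.5,
    "merge_threshold": 0.25,
    "r_retain": 0.8,
    "r_view": 0.9,
    "top_frac": 0.10,
    "fdr": 0.05,
    "enrich_p": 0.05,
    "r_min": 0.8,
    "min_group": 10,
}


class LoadError(ValueError):
    """Raised when a table violates a structural invariant at load time."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id. All
        entries must be finite and non-negative.
    sample_meta
        DataFrame indexed by sample id with columns ``tissue`` (str),
        ``daf`` (days after flowering, nullable) and ``replicate``
        (nullable). When omitted, a minimal metadata frame is created with
        the tissue label set to the sample id.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise LoadError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise LoadError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = v.columns[
                [not np.issubdtype(d, np.number) for d in v.dtypes]
            ][0]
            raise LoadError(f"non-numeric expression values in column {bad!r}")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise LoadError(
                f"non-finite value for gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise LoadError(
                f"negative TPM for gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(
                {
                    "tissue": list(v.columns),
                    "daf": pd.array([pd.NA] * v.shape[1], dtype="Int64"),
                    "replicate": pd.array([pd.NA] * v.shape[1], dtype="Int64"),
                },
                index=v.columns,
            )
        else:
            meta = self.sample_meta.copy()
            missing = v.columns.difference(meta.index)
            if len(missing):
                raise LoadError(f"sample metadata missing for: {list(missing)}")
            meta = meta.loc[v.columns]
            if "tissue" not in meta.columns:
                meta["tissue"] = list(v.columns)
            for col in ("daf", "replicate"):
                if col not in meta.columns:
                    meta[col] = pd.NA
                meta[col] = pd.array(
                    pd.to_numeric(meta[col], errors="coerce"), dtype="Int64"
                )
            self.sample_meta = meta

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_meta)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.sample_meta.copy())


@dataclass
class GeneAnnotation:
    """Transcription-factor flags, named guide-gene sets and functional categories.

    Annotation may reference genes absent from any particular expression
    matrix; consumers intersect explicitly.
    """

    tf_flags: set[str] = field(default_factory=set)
    guide_sets: dict[str, set[str]] = field(default_factory=dict)
    categories: dict[str, set[str]] = field(default_factory=dict)

    def is_tf(self, gene: str) -> bool:
        return gene in self.tf_flags


@dataclass
class TraitTable:
    """Accession x trait table (e.g. seed oil content and seed coat content, %)."""

    values: pd.DataFrame  # index accession, columns trait names

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise LoadError(f"duplicate accession id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise LoadError("non-finite trait value")

    def trait(self, name: str) -> pd.Series:
        if name not in self.values.columns:
            raise KeyError(f"unknown trait {name!r}")
        return self.values[name].dropna()


@dataclass
class HaplotypeTable:
    """Per-gene haplotype labels across accessions.

    Stored long-form with columns ``gene``, ``accession``, ``haplotype``.
    Labels are opaque tokens (e.g. ``hap.TCTCT``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene", "accession", "haplotype"}
        if not need.issubset(self.table.columns):
            raise LoadError(f"haplotype table needs columns {sorted(need)}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def calls_for(self, gene: str) -> pd.Series:
        """Accession -> haplotype label for one gene."""
        sub = self.table[self.table["gene"] == gene]
        if sub.empty:
            raise KeyError(f"gene {gene!r} absent from haplotype table")
        return pd.Series(
            sub["haplotype"].to_numpy(), index=sub["accession"].to_numpy()
        )


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype_backend="numpy_nullable", **kw)


def read_expression(path: str | Path, meta_path: str | Path | None = None) -> ExpressionMatrix:
    """Load a TPM matrix (first column gene ids, header row of sample ids).

    Raises :class:`LoadError` naming the offending row or column on
    duplicate identifiers, non-numeric cells or negative values. The number
    of loaded rows always equals the number of data rows in the file.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            bad = raw.index[pd.to_numeric(raw[col], errors="coerce").isna()]
            where = f"gene {bad[0]!r}" if len(bad) else "unknown row"
            raise LoadError(f"non-numeric cell in column {col!r} ({where})")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(raw.astype(float), meta)


def write_expression(
    em: ExpressionMatrix, path: str | Path, meta_path: str | Path | None = None
) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")
    if meta_path is not None:
        em.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


NETWORK_FORMATS = ("graphml", "sif", "tsv")


def write_network(
    edges: Iterable[tuple[str, str, float]], path: str | Path, format: str = "graphml"
) -> None:
    """Write a weighted undirected edge list as GraphML, SIF or 3-column TSV.

    Self-edges and non-finite weights are rejected. SIF carries no weights
    (interaction type is written as ``co``); use GraphML or TSV when the
    weights must round-trip.
    """
    edges = list(edges)
    for u, v, w in edges:
        if u == v:
            raise ValueError(f"self-edge on {u!r}")
        if not np.isfinite(w):
            raise ValueError(f"non-finite weight on edge ({u!r}, {v!r})")
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for u, v, w in edges:
            g.add_edge(u, v, weight=float(w))
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, _ in edges:
                fh.write(f"{u}\tco\t{v}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in edges:
                fh.write(f"{u}\t{v}\t{float(w):.17g}\n")
    else:
        raise ValueError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )


def read_network(path: str | Path, format: str = "graphml") -> list[tuple[str, str, float]]:
    """Re-load a weighted edge list written by :func:`write_network`."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return [(u, v, float(d.get("weight", 1.0))) for u, v, d in g.edges(data=True)]
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return [
            (str(r.source), str(r.target), float(r.weight)) for r in df.itertuples()
        ]
    if format == "sif":
        out = []
        with open(path) as fh:
            for line in fh:
                u, _, v = line.rstrip("\n").split("\t")
                out.append((u, v, 1.0))
        return out
    raise ValueError(f"unknown network format {format!r}")


def read_gene_set(path: str | Path) -> set[str]:
    """One gene id per line (a header line ``gene`` is tolerated)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and g != "gene":
                genes.add(g)
    return genes


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_tf_flags(path: str | Path) -> set[str]:
    """Two-column TSV gene<TAB>is_tf(0/1), or a plain one-column TF list."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 1:
        return set(df.iloc[:, 0].astype(str))
    flag = df.iloc[:, 1].astype(int).astype(bool)
    return set(df.iloc[:, 0].astype(str)[flag])


def read_categories(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV gene<TAB>category; multi-label genes occupy several rows."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for g, c in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
        out.setdefault(g, set()).add(c)
    return out


def read_traits(path: str | Path) -> TraitTable:
    return TraitTable(pd.read_csv(path, sep="\t", index_col=0).astype(float))


def read_haplotypes(path: str | Path) -> HaplotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return HaplotypeTable(df)


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML/JSON config file over the built-in defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        user = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg
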