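"""Seeded synthetic-data generators with planted ground truth.

The generators emulate the study design the pipeline targets: a seed
development time course of 26 time points (14-64 days after flowering, DAF,
in 2-day steps) with three biological replicates, partitioned into five
contiguous developmental stages; five planted co-expression modules, each
tied to one stage; a multi-tissue expression atlas in which the module genes
are seed-specific; and an accession panel in which biallelic haplotypes
shift gene expression and two antagonistic seed traits — seed oil content
(SOC) and seed coat content (SCC) — are built from module-gene expression
with mirrored weights, reproducing the oil/coat carbon-partitioning
trade-off.

Every output is a pure function of :class:`SynthConfig`; re-running with the
same seed reproduces every matrix bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation, HaplotypeTable, TraitTable

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "generate_timecourse",
    "generate_atlas",
    "generate_population",
    "SMALL_PRESET",
    "NULL_PRESET",
]

LIPID_MODULE = 2  # seed-filling stage: acyl-lipid biosynthesis
PHENYLPROPANE_MODULE = 3  # stable filling: seed-coat phenylpropane pathway
REF_HAP = "hap.TCTCT"
ALT_HAP = "hap.CGCTA"


@dataclass
class SynthConfig:
    """Parameters of the planted-truth generators.

    Expression noise acts on the log2 scale; trait noise on the trait (%)
    scale. ``stage_sizes`` must sum to ``n_timepoints``.
    """

    seed: int = 0
    n_timepoints: int = 26
    n_replicates: int = 3
    stage_sizes: tuple[int, ...] = (6, 4, 6, 4, 6)
    n_modules: int = 5
    genes_per_module: int = 150
    n_background: int = 1250
    noise_sd: float = 0.2  # log2-scale residual sd
    baseline: float = 0.5  # log2 level outside a module's stage
    peak: float = 8.0  # log2 level at the bump maximum
    amplitude_sd: float = 0.25  # sd of log amplitude (lognormal)
    tf_frac: float = 0.20  # fraction of module genes flagged TF
    guide_frac: float = 0.60  # fraction of lipid/phenylpropane genes used as guides
    n_nonseed_tissues: int = 10
    n_housekeeping: int = 200
    n_accessions: int = 300
    allele_freq: float = 0.3
    allele_effect: float = 1.0  # shift of the alternative haplotype, in residual SDs
    trait_noise_sd: float = 2.0
    weight_range: tuple[float, float] = (0.3, 0.6)
    n_weighted_per_module: int = 10  # genes per weighted module driving the traits
    n_twas_decoys: int = 20
    soc_baseline: float = 45.0  # mean seed oil content, %
    scc_baseline: float = 16.0  # mean seed coat content, %

    def __post_init__(self) -> None:
        if sum(self.stage_sizes) != self.n_timepoints:
            raise ValueError(
                f"stage_sizes {self.stage_sizes} must sum to n_timepoints "
                f"({self.n_timepoints})"
            )
        if len(self.stage_sizes) < self.n_modules:
            raise ValueError("need at least one stage per module")
        for name in ("n_timepoints", "n_replicates", "n_background", "n_accessions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.genes_per_module + self.n_background

    @property
    def dafs(self) -> np.ndarray:
        return 14 + 2 * np.arange(self.n_timepoints)


@dataclass
class SynthTruth:
    """Planted ground truth accompanying the generated matrices."""

    seed: int
    module_of_gene: dict[str, int]  # 0 = background
    stage_of_timepoint: dict[int, int]  # daf -> stage (1-based)
    seed_specific: set[str]
    housekeeping: set[str] = field(default_factory=set)
    tf_genes: set[str] = field(default_factory=set)
    guide_genes: dict[str, set[str]] = field(default_factory=dict)
    trait_weights: dict[str, float] = field(default_factory=dict)  # SOC weights
    twas_positives: set[str] = field(default_factory=set)
    twas_decoys: set[str] = field(default_factory=set)
    haplotype_effect: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        for k in ("seed_specific", "housekeeping", "tf_genes", "twas_positives", "twas_decoys"):
            d[k] = sorted(d[k])
        d["guide_genes"] = {k: sorted(v) for k, v in self.guide_genes.items()}
        return d


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _gene_ids(cfg: SynthConfig) -> tuple[list[str], np.ndarray]:
    """Gene ids and their planted module labels (0 = background)."""
    ids, labels = [], []
    g = 0
    for m in range(1, cfg.n_modules + 1):
        for _ in range(cfg.genes_per_module):
            ids.append(f"g{g:05d}")
            labels.append(m)
            g += 1
    for _ in range(cfg.n_background):
        ids.append(f"g{g:05d}")
        labels.append(0)
        g += 1
    return ids, np.asarray(labels)


def _stage_of_timepoints(cfg: SynthConfig) -> np.ndarray:
    """1-based stage index per time point, contiguous blocks."""
    return np.repeat(np.arange(1, len(cfg.stage_sizes) + 1), cfg.stage_sizes)


def _latent_profiles(cfg: SynthConfig) -> np.ndarray:
    """Module x time point latent log2 profile: raised-cosine bump on the
    module's stage block, flat baseline elsewhere."""
    stages = _stage_of_timepoints(cfg)
    t = np.arange(cfg.n_timepoints, dtype=float)
    lat = np.full((cfg.n_modules, cfg.n_timepoints), cfg.baseline)
    pad = 2.0  # time points of smooth decay into the neighbouring stages
    for m in range(1, cfg.n_modules + 1):
        idx = np.flatnonzero(stages == m)
        center = idx.mean()
        half_width = (len(idx) - 1) / 2.0 + pad + 1.0
        arg = np.clip(np.abs(t - center) / half_width, 0.0, 1.0)
        frac = 0.5 * (1.0 + np.cos(np.pi * arg))
        lat[m - 1] = cfg.baseline + (cfg.peak - cfg.baseline) * frac
    return lat


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_timecourse(
    cfg: SynthConfig,
) -> tuple[ExpressionMatrix, GeneAnnotation, SynthTruth]:
    """Replicated seed time course with planted stages and modules.

    Module-gene log2 expression is ``amplitude_g * latent_m(t) + noise``
    with gene amplitudes lognormal(0, ``amplitude_sd``); background genes sit
    at a gene-specific constant level. TPM = 2**x - 1, clipped at zero.
    """
    ids, labels = _gene_ids(cfg)
    stages = _stage_of_timepoints(cfg)
    lat = _latent_profiles(cfg)
    rng = _rng(cfg, 1)

    amp = rng.lognormal(0.0, cfg.amplitude_sd, size=len(ids))
    bg_level = rng.uniform(0.5, 5.0, size=len(ids))

    n_cols = cfg.n_timepoints * cfg.n_replicates
    x = np.empty((len(ids), n_cols))
    mean_profile = np.where(
        (labels > 0)[:, None],
        amp[:, None] * lat[np.clip(labels - 1, 0, None), :],
        bg_level[:, None],
    )  # genes x timepoints
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(ids), n_cols))
    x = np.repeat(mean_profile, cfg.n_replicates, axis=1) + noise
    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)

    dafs = cfg.dafs
    sample_ids = [
        f"seed_{d}DAF_R{r + 1}" for d in dafs for r in range(cfg.n_replicates)
    ]
    meta = pd.DataFrame(
        {
            "tissue": ["seed"] * n_cols,
            "daf": np.repeat(dafs, cfg.n_replicates),
            "replicate": list(range(1, cfg.n_replicates + 1)) * cfg.n_timepoints,
        },
        index=sample_ids,
    )
    em = ExpressionMatrix(pd.DataFrame(tpm, index=ids, columns=sample_ids), meta)

    # annotation: TFs among module genes; guides in the lipid and
    # phenylpropane modules
    tf_genes: set[str] = set()
    guide_sets: dict[str, set[str]] = {"acyl_lipid": set(), "phenylpropane": set()}
    categories: dict[str, set[str]] = {}
    cat_names = {
        LIPID_MODULE: "lipid metabolism",
        PHENYLPROPANE_MODULE: "phenylpropanoid pathway",
    }
    rng_ann = _rng(cfg, 2)
    for m in range(1, cfg.n_modules + 1):
        members = [g for g, l in zip(ids, labels) if l == m]
        n_tf = int(round(cfg.tf_frac * len(members)))
        tf_genes.update(rng_ann.choice(members, size=n_tf, replace=False))
        cat = cat_names.get(m, f"stage {m} program")
        for g in members:
            categories.setdefault(g, set()).add(cat)
        if m == LIPID_MODULE:
            n_guide = int(round(cfg.guide_frac * len(members)))
            guide_sets["acyl_lipid"].update(
                rng_ann.choice(members, size=n_guide, replace=False)
            )
        if m == PHENYLPROPANE_MODULE:
            n_guide = int(round(cfg.guide_frac * len(members)))
            guide_sets["phenylpropane"].update(
                rng_ann.choice(members, size=n_guide, replace=False)
            )
    bg = [g for g, l in zip(ids, labels) if l == 0]
    misc = ["housekeeping process", "unknown function", "general metabolism"]
    for g, c in zip(bg, rng_ann.choice(misc, size=len(bg))):
        categories.setdefault(g, set()).add(str(c))

    ann = GeneAnnotation(tf_flags=tf_genes, guide_sets=guide_sets, categories=categories)
    truth = SynthTruth(
        seed=cfg.seed,
        module_of_gene={g: int(l) for g, l in zip(ids, labels)},
        stage_of_timepoint={int(d): int(s) for d, s in zip(dafs, stages)},
        seed_specific={g for g, l in zip(ids, labels) if l > 0},
        tf_genes=tf_genes,
        guide_genes=guide_sets,
    )
    return em, ann, truth


def generate_atlas(
    cfg: SynthConfig,
    timecourse: ExpressionMatrix,
    truth: SynthTruth | None = None,
) -> ExpressionMatrix:
    """Multi-tissue atlas: seed columns from the time course plus non-seed
    tissues in which planted seed-specific genes are silent.

    Non-seed log2 levels: seed-specific genes <= 0.1; a disjoint
    housekeeping subset of background genes keeps its constant time-course
    level in every tissue; all remaining genes get independent moderate
    levels per tissue. When ``truth`` is given, the housekeeping set is
    recorded on it.
    """
    ids = timecourse.gene_ids
    rng = _rng(cfg, 3)
    _, labels = _gene_ids(cfg)
    is_module = labels > 0
    bg_idx = np.flatnonzero(~is_module)
    hk_idx = rng.choice(bg_idx, size=min(cfg.n_housekeeping, len(bg_idx)), replace=False)
    is_hk = np.zeros(len(ids), dtype=bool)
    is_hk[hk_idx] = True
    if truth is not None:
        truth.housekeeping = {ids[i] for i in hk_idx}

    # housekeeping tissue level = the gene's seed-course mean log2 level
    seed_log = np.log2(timecourse.values.to_numpy() + 1.0)
    hk_level = seed_log.mean(axis=1)

    n_t = cfg.n_nonseed_tissues
    x = rng.uniform(1.0, 5.0, size=(len(ids), n_t))
    x[is_module] = rng.uniform(0.0, 0.1, size=(int(is_module.sum()), n_t))
    x[is_hk] = hk_level[is_hk][:, None] + rng.normal(0.0, 0.05, size=(len(hk_idx), n_t))
    x = np.clip(x, 0.0, None)
    tpm = np.clip(np.exp2(x) - 1.0, 0.0, None)

    tissues = [f"tissue_{t:02d}" for t in range(1, n_t + 1)]
    cols = pd.DataFrame(tpm, index=ids, columns=tissues)
    atlas_vals = pd.concat([timecourse.values, cols], axis=1)
    meta = pd.concat(
        [
            timecourse.sample_meta,
            pd.DataFrame(
                {
                    "tissue": tissues,
                    "daf": pd.array([pd.NA] * n_t, dtype="Int64"),
                    "replicate": pd.array([pd.NA] * n_t, dtype="Int64"),
                },
                index=tissues,
            ),
        ]
    )
    return ExpressionMatrix(atlas_vals, meta)


def generate_population(
    cfg: SynthConfig, truth: SynthTruth
) -> tuple[ExpressionMatrix, TraitTable, HaplotypeTable, set[str]]:
    """Accession panel: haplotype-driven expression and antagonistic traits.

    Candidate genes (the lipid and phenylpropane modules) carry a biallelic
    haplotype per accession (alt frequency ``allele_freq``); expression is
    ``mu_g + allele_effect * [alt] + N(0,1)``. SOC sums weighted candidate
    expression (lipid +, phenylpropane -) plus noise; SCC mirrors the signs.
    The TWAS list is the weighted genes (|w| >= weight_range[0]) plus
    ``n_twas_decoys`` null background genes. Updates ``truth`` in place with
    weights, haplotype effects and the TWAS composition.
    """
    rng = _rng(cfg, 4)
    module_of = truth.module_of_gene
    lipid = sorted(g for g, m in module_of.items() if m == LIPID_MODULE)
    phenyl = sorted(g for g, m in module_of.items() if m == PHENYLPROPANE_MODULE)
    background = sorted(g for g, m in module_of.items() if m == 0)
    candidates = lipid + phenyl

    acc = [f"A{i:04d}" for i in range(1, cfg.n_accessions + 1)]
    n = cfg.n_accessions

    mu = rng.uniform(5.0, 10.0, size=len(candidates))
    alt = rng.random((len(candidates), n)) < cfg.allele_freq
    expr = (
        mu[:, None]
        + cfg.allele_effect * alt
        + rng.normal(0.0, 1.0, size=(len(candidates), n))
    )

    # trait weights: a seeded subset of each weighted module drives the traits
    lo, hi = cfg.weight_range
    k = min(cfg.n_weighted_per_module, len(lipid), len(phenyl))
    w_lipid = sorted(rng.choice(lipid, size=k, replace=False))
    w_phenyl = sorted(rng.choice(phenyl, size=k, replace=False))
    weights = {g: float(rng.uniform(lo, hi)) for g in w_lipid}
    weights.update({g: -float(rng.uniform(lo, hi)) for g in w_phenyl})

    centered = expr - expr.mean(axis=1, keepdims=True)
    w_vec = np.array([weights.get(g, 0.0) for g in candidates])
    signal = w_vec @ centered
    soc = cfg.soc_baseline + signal + rng.normal(0.0, cfg.trait_noise_sd, size=n)
    scc = cfg.scc_baseline - signal + rng.normal(0.0, cfg.trait_noise_sd, size=n)

    # null background genes fill out the panel matrix
    n_null = min(200, len(background))
    null_genes = sorted(rng.choice(background, size=n_null, replace=False))
    null_expr = rng.uniform(5.0, 10.0, size=(n_null, 1)) + rng.normal(
        0.0, 1.0, size=(n_null, n)
    )

    panel_genes = candidates + null_genes
    panel = np.vstack([expr, null_expr])
    panel = np.clip(panel, 0.0, None)
    meta = pd.DataFrame(
        {
            "tissue": ["seed"] * n,
            "daf": pd.array([pd.NA] * n, dtype="Int64"),
            "replicate": pd.array([pd.NA] * n, dtype="Int64"),
        },
        index=acc,
    )
    pop_em = ExpressionMatrix(pd.DataFrame(panel, index=panel_genes, columns=acc), meta)
    traits = TraitTable(pd.DataFrame({"SOC": soc, "SCC": scc}, index=acc))

    rows = []
    for gi, g in enumerate(candidates):
        for ai, a in enumerate(acc):
            rows.append((g, a, ALT_HAP if alt[gi, ai] else REF_HAP))
    haps = HaplotypeTable(pd.DataFrame(rows, columns=["gene", "accession", "haplotype"]))

    decoys = set(rng.choice(null_genes, size=min(cfg.n_twas_decoys, n_null), replace=False))
    twas = set(weights) | decoys

    truth.trait_weights = weights
    truth.twas_positives = set(weights)
    truth.twas_decoys = decoys
    truth.haplotype_effect = {g: cfg.allele_effect for g in candidates}
    return pop_em, traits, haps, twas


SMALL_PRESET = dict(
    genes_per_module=30,
    n_background=150,
    n_housekeeping=40,
    n_accessions=80,
    n_weighted_per_module=5,
    n_twas_decoys=10,
)

NULL_PRESET = dict(
    genes_per_module=1,
    n_modules=5,
    n_background=500,
    n_weighted_per_module=0,
    n_twas_decoys=20,
)
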