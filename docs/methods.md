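# Methods

This note documents the models and procedures implemented in `seedcoex`,
the tunable parameters and their defaults, what the synthetic-data
generators do and do not emulate, and the design choices made where the
workflow was genuinely open.

## Input model

Expression is dense TPM (transcripts per million), genes × samples, with
per-sample metadata: a tissue label, days after flowering (DAF) for
time-course samples, and a replicate number. Identifiers are opaque
case-sensitive strings. Missing expression values are rejected at load time
(the upstream quantification emits dense matrices); missing metadata fields
(DAF, replicate) are allowed. All thresholds named below live in a single
config (`seedcoex.io.DEFAULT_CONFIG`) and can be overridden from a YAML or
JSON file.

## Staging

Replicate quality is summarised as squared Pearson correlation (R²) between
replicate pairs of the same (tissue, DAF) group on log2(TPM+1); pairs below
`qc_r2_threshold` (default 0.90) are flagged, and a zero-variance replicate
yields an undefined (flagged, not raised) pair. Replicates are then averaged
arithmetically on the TPM scale and transformed to log2(TPM+1).

Stage assignment clusters the averaged time-point profiles with
**Pearson correlation distance** d = 1 − r over genes and **average
linkage**, cutting the tree into K clusters (default K = 5) and renumbering
stages 1..K by ascending mean DAF so stage 1 is the earliest. The linkage
criterion is configurable; average linkage is the default of the clustering
tools commonly used for this step. A zero-variance time-point profile gets
correlation 0 (distance 1) with a warning. PCA (samples as observations,
centered genes as features, exact SVD) is provided for visual QC of the
staging; it does not influence the assignment.

Properties that hold by construction and are enforced by tests: the stage
labels partition the time points; the assignment is invariant to gene order
and to per-gene positive affine rescaling (a property of the correlation
distance).

## Tissue specificity (tau)

Samples are collapsed to one column per tissue label (mean TPM), genes whose
maximum TPM never exceeds `min_tpm` (default 1.0) are excluded, and the
remaining values are transformed to x = log2(TPM+1). With x̂_i = x_i /
max_i(x) over N tissues,

    tau = sum_i (1 - x̂_i) / (N - 1),

which is 1 for single-tissue expression and 0 for uniform expression. A gene
is seed-specific when tau > `tau_threshold` (default 0.9) **and** its
highest-expressing tissue is a seed tissue. The same index computed over the
K per-stage means of the seed course (threshold `tau_stage_threshold`,
default 0.8; argmax stage wins; max TPM must exceed `min_tpm`) screens
stage-marker genes. The stage-level criterion is this package's
operationalisation of "stage-specific screening"; it is declared, not
inferred from any external convention.

Whether tau should see per-sample or per-tissue-mean columns is ambiguous in
general; the default here collapses to per-tissue means first.

## Co-expression modules

1. **Gene filtering** (for large matrices): keep the `n_expressed` (50,000)
   genes with highest mean TPM, then among those the `n_cv` (15,000) with
   highest coefficient of variation (sd/mean, sample sd). Ties break by
   gene id ascending; a constant gene ranks last. The order of the two
   passes is fixed.
2. **Correlation**: pairwise Spearman (average ranks on ties) by default,
   Pearson by option, computed on log2(TPM+1) of the averaged course.
   Zero-variance genes correlate 0 with everything, with a warning.
3. **Signed adjacency**: a_ij = ((1 + ρ_ij)/2)^β with β a positive integer
   (default 12). Negative correlations map to near-zero adjacency — this is
   a signed network. The diagonal is held at zero so connectivities and TOM
   exclude self-edges.
4. **β selection** (optional): for each β on a grid, connectivities
   k_i = Σ_j a_ij are binned into 10 equal-occupancy bins and log10 of the
   per-bin degree **density** ((count/total)/bin width) is regressed on
   log10 of the per-bin mean k. The fit index is R², signed negative when
   the slope is positive. The smallest β reaching `r2_target` (0.8) wins,
   else the argmax. The density normalisation matters: with equal-occupancy
   bins the raw per-bin frequency is constant by construction and would
   carry no signal. On the synthetic defaults the planted degree
   distribution is bimodal (five modules over a diffuse background), so no
   β on the default grid reaches 0.8 and the argmax fallback applies; the
   default β = 12 is used throughout unless selection is requested.
5. **Topological overlap**: TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)
   with ℓ = A², TOM_ii = 1; dissimilarity is 1 − TOM.
6. **Module cutting**: average-linkage clustering of 1 − TOM, **static cut
   at the absolute dissimilarity height `cut_height`** (default 0.99),
   clusters smaller than `min_module_size` (30) unassigned (label 0). Genes
   whose **module membership kME** — the Pearson correlation between their
   profile and their module's eigengene — falls below `kme_min` (0.5) are
   unassigned, and modules shrinking below the size floor dissolve. Modules
   whose eigengenes have dissimilarity (1 − r) below `merge_threshold`
   (0.25) merge iteratively, closest pair first. Labels are renumbered by
   decreasing size. This deterministic cut replaces the dynamic
   tree-cutting family: it is reproducible, parameter-transparent and
   recovers planted structure. The kME pruning step is essential with few
   samples: at 26 time points the chance Spearman correlation between
   independent genes has sd ≈ 0.2, and under average linkage unstructured
   background genes otherwise chain into module clusters at any static cut
   height (on the synthetic defaults, ~250 of 1,250 background genes;
   pruning reduces module/background confusion to a few genes and raises
   the adjusted Rand index vs the planted labels from ~0.65 to ~0.95).
7. **Eigengenes**: genes standardized to zero mean/unit variance over
   samples; the eigengene is the leading right singular vector (unit-norm
   sample profile), sign-aligned to correlate positively with the module's
   mean standardized expression; the explained-variance fraction is
   reported. A single-gene module's eigengene is that gene's standardized,
   unit-normalized profile.
8. **Connectivity**: whole-network k_i = Σ_j a_ij and intramodular kWithin
   (row sums restricted to the gene's own label).

## Guide-gene networks

Given a guide set (e.g. acyl-lipid pathway genes) and a candidate set
(typically the genes assigned to modules), a candidate is a first-degree
partner (P1) when |Pearson r| of its averaged log2(TPM+1) profile with at
least one guide exceeds `r_retain` (0.8); all guide–guide, guide–P1 and
P1–P1 edges above the same threshold are retained. Absolute correlation is
used here deliberately even though the module network is signed — the two
thresholds serve different steps and both are kept as published practice.
Hubs are, per module, every transcription factor plus the top
ceil(`top_frac` · module size) genes by intramodular connectivity (default
10%; ceil so a one-gene module still yields a hub; ties break by gene id).
A display network keeps edges with |r| > `r_view` (0.9) and drops isolated
nodes; it is always a subgraph of the retained network (`r_view ≥
r_retain` is enforced).

## Enrichment

Per (module, category) pair: one-sided Fisher exact test, i.e. the
hypergeometric upper tail P(X ≥ k) for k category hits in an n-gene module
drawn from an N-gene universe with K category members. The universe defaults
to the genes that entered module detection (post-filter); categories with no
universe hits are skipped. Benjamini–Hochberg step-up q-values are computed
across **all** module × category tests jointly (a declared choice — a
per-module family would also be defensible), significant at q < 0.05.

## Trait and haplotype integration

* **Expression–trait correlation**: Pearson r of raw TPM against the trait
  across accessions (log by flag), two-sided p from the t distribution with
  n − 2 df; accessions missing the trait are dropped per gene; at least 3
  shared accessions are required; zero-variance genes are flagged undefined.
  Raw p-values are reported without multiplicity correction by default
  (matching how such candidate tables are usually presented); BH is
  available.
* **Overlap candidates**: the intersection of a TWAS-significant gene list
  with the co-expression hub set, with per-gene provenance.
* **Mined candidates**: modules over-represented for guide genes
  (hypergeometric upper tail p < `enrich_p`, universe = networked genes),
  then TWAS genes inside those modules with |Pearson r| ≥ `r_min` (0.8) to
  at least one guide. This two-filter definition is this package's own
  re-specification of guide-based candidate mining; both filters are
  exposed as parameters.
* **Haplotype tests**: pooled-variance Student's t between the two most
  frequent haplotype groups of a gene (Welch by flag), requiring
  `min_group` (10) accessions per group, reporting group sizes, means, t
  and p.

## Synthetic data with planted truth

`SynthConfig` defaults define the emulated study: 26 time points (14–64 DAF,
2-day steps) × 3 replicates; 5 contiguous stages of sizes (6, 4, 6, 4, 6);
5 modules of 150 genes, one per stage, plus 1,250 background genes;
log2-scale noise sd 0.2; a 10-tissue non-seed atlas extension; and a
300-accession panel (a desk-scale stand-in for panels of several hundred
accessions) with biallelic haplotypes (alternative-allele frequency 0.3,
effect 1.0 residual SD) and antagonistic SOC/SCC traits.

Module-gene expression is `amplitude_g × latent_m(t) + N(0, σ²)` per
replicate on the log2 scale, amplitudes lognormal(0, 0.25), TPM = 2^x − 1
clipped at zero. The latent profile is a raised-cosine bump over the
module's stage block (baseline 0.5, peak 8) whose shoulders decay smoothly
about two time points into the neighbouring stages rather than dropping to
the baseline at the block edge. The tails are what make the design
internally consistent: with a hard block-limited bump, stage-edge time
points are structurally intermediate (stage recovery fails even at σ = 0)
and ranks outside the block are pure noise, capping within-module Spearman
at ~0.55; with the tails, co-members share rank structure course-wide, as
co-regulated genes do, and the five stages are recovered exactly for σ up
to at least 0.3. Background genes sit at gene-specific constant levels
(uniform 0.5–5 log2) plus noise. 20% of module genes are flagged as
transcription factors; 60% of the lipid-module and phenylpropane-module
genes form the two guide sets.

The atlas keeps the averaged seed course as the seed tissue and adds 10
non-seed tissues: planted seed-specific genes (all module genes) at log2
≤ 0.1, a 200-gene housekeeping subset of the background at its seed-course
level everywhere, remaining genes at independent uniform(1, 5) levels.

The panel draws a haplotype per candidate gene per accession, shifts
expression by the allele effect, and builds SOC as a weighted sum of the
centered expression of 10 lipid-module genes (positive weights, |w| ~
uniform(0.3, 0.6)) and 10 phenylpropane-module genes (negative weights)
plus N(0, 2²) noise around a 45% baseline; SCC mirrors the weight signs
around 16%. Mirrored weights reproduce the oil-vs-coat carbon-partitioning
trade-off (corr(SOC, SCC) ≈ −0.5 at the defaults). Weighting a 10-gene
subset per module rather than all 150 keeps each causal gene's share of the
trait variance large enough for its correlation sign to be recoverable at
n = 300 — with all module genes weighted and independent panel expression,
no single gene could reach a detectable correlation. The TWAS list is
exactly the 20 weighted genes (|w| ≥ 0.3) plus 20 background decoys.

Every generator output is a pure function of `SynthConfig` (seeded streams
per generator), so reruns are byte-identical.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: read-count sampling noise (no negative-binomial
layer), linkage disequilibrium and kinship structure in the panel,
correlated module activity (modules are tied to disjoint stages),
batch effects, and unbalanced replicate designs. Recovery rates on this
benchmark are upper bounds for field data.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1]; zero-variance vectors correlate 0
  (with warnings) rather than raising, except where an operation is
  undefined (tau with one tissue, staging with K > time points).
* PCA and eigengenes use exact SVD; eigengene sign is fixed by positive
  correlation with the module mean profile.
* Top-k selections (gene filter, hubs) break ties by (metric descending,
  gene id ascending) with stable sorts, so outputs are order-independent.
* TSV output uses 17 significant digits; write→read round-trips reproduce
  values to < 1e-12.
* p-values of exactly |r| = 1 are reported as 0; BH q-values are clipped at
  1 and never fall below their p-value.

## Known limitations

* The static cut + kME pruning is simpler than dynamic hybrid tree cutting;
  very close or nested modules that the hybrid algorithm would separate may
  merge or dissolve here.
* The scale-free β criterion is diagnostic, not decisive, for short series
  (26 samples) with block structure; β = 12 is the sensible default.
* Trait integration performs no population-structure or kinship
  correction; TWAS lists and haplotype tables are taken as given inputs.
* Module counts on real atlases (tens of modules over ~15,000 genes) are
  not a target of the synthetic benchmark, which plants five.
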