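# Methods

This note documents the models, conventions and numerical choices
behind `dptscope`, and what the synthetic generators do and do not
emulate.

## Clonal entropy indices

Clonotypes are defined by the set of productive CDR3 sequences of a
cell (α and β chains concatenated, contig order ignored) and are
**patient-scoped**: identical CDR3 sets in two patients are distinct
clones, so public clonotypes are deliberately out of scope. Cells with
no productive contig are dropped and counted.

All entropies use natural logarithms. Normalizations are:
`expa_i = 1 − H_i/ln N_i` (within-cluster clone-size entropy over
`N_i` clones), `tran_i` = clone-mass-weighted mean of per-clone
cluster-occupancy entropy normalized by `ln K`, and `ptran` the
pairwise variant normalized by `ln 2` with clone weights taken as cell
mass within the pair. Conventions at the boundaries: a monoclonal
cluster (`N_i = 1`, a 0/0 case) is assigned `expa = 1`, since
monoclonality is maximal expansion; `tran` requires `K ≥ 2`. The
expanded-clone threshold is **strict** (`size > 10`): a clone of
exactly 10 cells is excluded.

The implementation is vectorized over a clone × cluster contingency
table; the test suite checks it against an independent double-loop
oracle to 1e-12 on random tables.

## CyTOF phenotyping

Raw intensities are transformed with `asinh(x / 5)` (the mass-cytometry
convention; the cofactor is configurable). Gating thresholds for
CD4/CD8 default to the trough of a univariate two-component Gaussian
mixture per marker — the point between the component means where
posterior membership flips — and can be overridden with fixed cutoffs.
The four compartments partition every cell; DPT requires both markers
above threshold.

Cluster frequencies are computed per (patient, region) sample and sum
to 1 per sample. Region enrichment is assigned by the argmax of the
cluster's patient-mean frequency; significance is a paired two-sided
t-test across patients of the winning region's frequency against the
mean of the other regions (a Wilcoxon variant would be a one-line
change; the t-test matches the group-comparison statistic used
throughout the package). Exact mean ties yield "none"; with a single
patient the p-value is undefined and flagged. Whether such enrichment
calls should come from the argmax or from the test alone is genuinely
open; both the label and its p-value are always reported together.

Coexpression is pairwise-complete Pearson correlation with per-pair
p-values; per-file subsampling (default cap 6,000 cells per sample) is
provided for the O(n²) embedding stages. A k-means helper exists purely
as plumbing so downstream stages have cluster labels when no external
clustering is supplied; it makes no claim of fidelity to any published
clustering solution.

## scRNA-seq QC and normalization

The four QC indices are per-cell UMI total, detected genes,
mitochondrial UMI fraction (genes prefixed `MT-` by default) and
dissociation/sorting-stress fraction (gene list supplied by the
caller). "Upper boxplot outlier" is operationalized as the Tukey fence
`> Q3 + 1.5·IQR`, quartiles by linear interpolation, with the four
rules applied **jointly** on the full cell set (applying them
sequentially would shift quartiles; the joint rule is order-free).
Cells with fewer than 200 detected genes are always removed. Reasons
are recorded per cell. Once fences are frozen, re-application removes
nothing — the rule is idempotent at fixed thresholds.

Normalization divides each cell by its UMI total, multiplies by
10,000 and applies ln(1 + v); pre-log values sum to exactly 10,000 per
retained cell, and zero-UMI cells are excluded with a warning.

Variable genes are ranked by mean-standardized dispersion computed on
the log-normalized matrix, using median-based normalization within
equal-frequency mean bins. A z-score-based bin normalization was
rejected because in matrices whose gene means concentrate in few bins
it inflates low-mean Poisson genes and deflates genuinely bimodal
genes; the median-based statistic recovers planted high-dispersion
genes essentially perfectly in the tests. Ribosomal and heat-shock
gene sets are removed from the ranked list before the top-n cut.
Confounder regression (per-gene OLS residualization on UMI total and
mitochondrial fraction) is provided as an optional stage.

## Signature construction and scoring

Signatures are the top 20 genes by **signed** Pearson correlation with
the anchor (FGFBP2 → cytotoxicity, IFNG → activation, HAVCR2 →
exhaustion), computed across all cells of the scored population; an
absolute-value ranking is available behind a flag. Ties are broken by
gene-name lexicographic order, making construction deterministic.
Which cell population the correlations are computed over is
configurable (the compartment being scored, by default).

The per-cell score is the mean of member genes' z-scaled
log-normalized expression (z-scaling across the scored cells; a
constant gene contributes 0). This makes the score invariant to member
order and to affine rescaling of any member. Cluster summaries add the
PDCD1 detection rate: the fraction of cells with at least one PDCD1
UMI. Cross-compartment transcriptomic similarity is the Pearson
correlation of cluster mean-expression vectors restricted to the union
of per-cluster top-50 mean-log-fold-change markers (marker detection
is standard plumbing, not a contribution).

## Diffusion map

Standard construction: squared Euclidean distances, Gaussian kernel
`exp(−d²/ε)` with ε defaulting to the median pairwise squared distance,
α = 1 density normalization (Laplace–Beltrami) to suppress sampling-
density artifacts, row normalization to a Markov matrix, and
eigendecomposition via the symmetric conjugate for numerical
stability. Components are the nontrivial right eigenvectors scaled by
their eigenvalues, with each component's sign fixed so its largest-
magnitude coordinate is positive (reproducible orientation).
Duplicate-point degeneracies trigger a jitter warning. Inputs above
6,000 cells are subsampled (dense O(n²) kernel).

## Spatial statistics

Neighbor counts use a KD-tree per tissue core with an **inclusive**
boundary (d ≤ r; deterministic on grid fixtures) and the index cell
excluded from its own counts; cores never share neighbors. Radii
default to 15 and 45 µm. Edge effects are uncorrected by default, as
is conventional for these comparisons; a brute-force O(n²) counter is
kept as the oracle. Count comparisons use the pooled-variance two-sided
Student's t-test with per-cell counts as the unit (per-core averaging
can be applied by the caller on the returned table). Densities are
cells per mm² with a convex-hull area fallback.

## Survival

Dichotomization defaults to the sample median with ties to "low"; a
fixed threshold is available. Kaplan–Meier estimation, the two-group
log-rank test and the univariate Cox model are delegated to
`lifelines` behind this module's interface; Cox uses Efron tie
handling, appropriate for month-granularity times with heavy ties.
Non-convergence (e.g. complete separation) is flagged rather than
raised. The hazard ratios reported in the literature for DPT
infiltrates (≈ 0.35) are used only as generator settings for recovery
tests — they depend on a specific patient cohort and are not
reproducible quantities here.

## Synthetic generators: what they emulate, and what they do not

Every generator is deterministic given its seed. Defaults describe a
study-like cohort: 13 patients × 3 matched regions, DPT populations
enriched at the leading edge (8% of L-region T cells for the PD-1⁺
subset vs 1–2% in T/N), and a planted PD-1–CD45RO correlation (ρ = 0.6)
within PD-1⁺ DPT cells. Marker values are Gaussian **directly on the
arcsinh scale** (no inverse-transform round trip, since all downstream
computation operates on the transformed scale).

UMI counts are gamma-Poisson (negative binomial, shape 2) with
lognormal library sizes (median 2,500 UMIs, σ = 0.2) over ~1,500 genes
including mitochondrial, dissociation, ribosomal/heat-shock families
and PDCD1. Planted signature genes have expectations linearly coupled
to their anchor's lognormal latent activity; cluster program
multipliers (default ×3 for one program per cluster; recovery tests of
score separation configure a strong ×5 effect) create separable
cluster-level scores. Low-quality cells are planted by multiplying
mitochondrial means ×10 (5% of cells) or shrinking the library to
~100 UMIs (<200 detected genes, 1%); the moderate cell-to-cell noise
(σ ≈ 0.15–0.2 on propensities) keeps honest-cell Tukey false flags at
the few-percent level, as in real data.

Clone sizes follow a discrete power law (exponent 2.5, truncated at 60
cells — heavy-tailed expansion with one parameter); each clone is
seeded in a home cluster and its cells spread by a multinomial on the
home row of the transition matrix, clipped to cluster capacity. The
identity matrix yields zero sharing exactly. The spatial generator is
a marked parent–offspring process: a fraction `min(attraction, 1)` of
PD-1⁺CD8⁺ cells scatter (Gaussian, σ = 8 µm) around uniform PD-1⁺DPT
parents on a 1 mm² core; attraction 0 is complete spatial randomness
for every phenotype. Survival times are Weibull (shape 1.5, scale 40
months) with a proportional-hazards group effect and independent
Weibull censoring whose scale targets the nominal censoring fraction.

Not emulated: V(D)J recombination and sequence-level TCR structure,
ambient RNA and doublets, imaging segmentation error, spatial edge
heterogeneity, and informative censoring. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
the stated generative assumptions, not robustness to those real-data
artifacts.

## Problem sizes in the tests

Recovery and calibration checks use: 100 random tables (≤ 300 cells)
for oracle equivalence; 100 replicates × 3,000 cells for ancestry
recovery; 50 matrices × 2,000 cells for QC; 2,000 cells for signature
recovery; 500 cores × 1,500 cells for null calibration and 50
replicates for power; 50 replicates × 375 cells for branch geometry;
200 replicates × 400–500 patients for hazard-ratio recovery and CI
coverage. These sizes were chosen to put Monte-Carlo error comfortably
inside the asserted margins.
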