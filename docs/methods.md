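# Methods

This note documents the models, estimators, defaults, and numerical
choices behind `pleiomap`, and states what the synthetic validation
studies do and do not establish about real data.

## Conditional and conjunctional FDR

For aligned p-value vectors of two traits, the conditional FDR of the
primary trait given the secondary is the empirical-Bayes estimator

cFDR(a | b) = π₀ · a · #{P₂ ≤ b} / #{P₁ ≤ a ∧ P₂ ≤ b},

clamped to ≤ 1 and evaluated at every SNP's own (a, b). π₀ = 1 by default
(conservative; configurable). The bivariate counts are computed exactly
with a Fenwick tree over dense secondary ranks (O(M log M)); groups of
tied p₁ values are inserted before querying so that "≤" counts are exact
under ties. p-values are floored at 1e-300 with a warning. The
conjunctional FDR is max(cFDR₁|₂, cFDR₂|₁), with strict `< 0.05`
significance.

Two properties anchor the implementation: conditioning at b = 1 reduces
*exactly* to the unconditional empirical FDR a·M/rank(a), and the
estimator agrees with quadratic brute-force counting on random instances
with ties. Because a·M/rank(a) is not monotone in a, per-SNP
monotonization would break the reduction identity; it is therefore an
opt-in flag (`monotonize=True`, cumulative max along the p₁ order within
equal p₂), not the default. LD-weighted lookup via random pruning is
deliberately out of the default path: on synthetic data the exact
estimator is preferable, and the empirical checks below measure its
behaviour under LD directly.

Exclusion regions (extended MHC chr6:25,119,106–33,854,733 and 8p23.1
chr8:7,242,715–12,483,982, 1-based inclusive) are dropped before
estimation; `chr`-prefixed labels are normalized.

## Locus definition

Greedy clumping sorts significant SNPs ascending by conjFDR (ties broken
by SNP id), repeatedly keeps the best remaining SNP and discards SNPs
with r² ≥ 0.6 to it; lead SNPs repeat the procedure over the independent
set at r² ≥ 0.1. The boundary case r² = 0.6 prunes (a SNP exactly at the
threshold is treated as linked), while candidate tagging uses strict
r² > 0.6 as printed conventions state. Candidates are SNPs with
conjFDR < 0.10 tagged by an independent SNP, plus the independent set
itself. Locus spans are the bp range of the member candidates; spans on
one chromosome with a gap ≤ 250 kb merge, measured between span
boundaries (not lead-to-lead), and the merged lead is the member with
minimum conjFDR. Positional mapping reports a gene when a candidate SNP
falls within gene body ± 10 kb (window configurable to 0; mapping whole
locus spans is available as an option). The greedy procedure is verified
against an independently coded exhaustive best-first oracle on all
instances with ≤ 12 significant SNPs.

## Coordinate-based meta-analysis

The engine is a deliberately simple, fully testable coordinate-based
random-effects meta-analysis ("single-kernel reconstruction + sign-flip
permutation"), not a reimplementation of subject-image imputation
pipelines. Per study: each reported peak is converted to Hedges g with
d = t·√(1/n₁+1/n₂), J = 1 − 3/(4(n₁+n₂)−9), g = J·d,
var(g) = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)); the study map takes, at each
voxel, the contribution of the single peak maximizing |g·K(dist)| with an
isotropic Gaussian K (FWHM 20 mm, truncated at 3σ), resolving overlaps by
maximum rather than summation to avoid inflating adjacent peaks; voxels
beyond every kernel are zero with the study's median peak variance (a
null-finding study contributes an all-zero map with unit variance).

Pooling is DerSimonian–Laird: τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) with
w = 1/v, then pooled = Σw*y/Σw*, se = 1/√Σw*, w* = 1/(v+τ²). When the
moment estimate hits zero this equals the fixed-effect estimate exactly.
Heterogeneity: I² = max(0, (Q−df)/Q)·100, clamped to [0, 100]. Egger:
regress y/se on 1/se with intercept, two-sided t-test on the intercept
with k−2 df (intercept only, p = NaN, for k = 2). Q/I²/Egger are reported
at cluster peak voxels of the FWE-thresholded map.

TFCE is the discrete right-endpoint threshold sum
TFCE(v) = Σ_{h=Δh,2Δh,...} e_h(v)^E · h^H · Δh with defaults E = 0.5,
H = 2, Δh = max|z|/100, 26-connectivity; positive and negative parts are
enhanced separately (the negative part on −z, re-negated). At the default
step the discrete statistic carries threshold-alignment jitter of roughly
1% of the map maximum relative to a 10×-finer sum; the agreement test
therefore runs at Δh = max|z|/300, where jitter is ~0.5% and the
comparison tests implementation correctness rather than step size.

FWE control multiplies each study's map by an independent ±1 per
permutation, repools, and records the maximum |TFCE|;
fwe_p = (1 + #{perm max ≥ |TFCE_obs|})/(1 + n_perm), so the attainable
floor is 1/(n_perm+1) and untouched voxels get exactly 1. Default grid
for synthetic work: 24³ voxels at 4 mm; Talairach→MNI conversion is out
of scope (inputs are declared MNI; a user affine can be supplied).

## Expression preprocessing

Probes are kept when called above background in ≥ 50% of samples (a probe
at exactly half is kept: exclusion requires strictly more than half
below). Differential stability is the mean over donor pairs of the
Spearman correlation between region-averaged expression profiles on
shared regions (≥ 3 regions required per pair); the argmax probe
represents each gene, ties to the lowest probe id, and a single-donor
bundle falls back to mean intensity with a log message. SRS maps
x ↦ 1/(1+exp(−(x−median)/(IQR/1.35))) then min-max rescales; quartiles
use linear interpolation (type 7) for bit-reproducibility; zero IQR
yields a constant 0.5 with a warning. The matrix is assembled by applying
SRS per gene within donor and then again within donor × structure class —
the second pass is this package's concrete reading of "additional
within-structure normalization", which upstream descriptions leave
undefined. SRS is applied across samples per gene (the standard choice
where the orientation is ambiguous). Sample metadata is never modified.

## PLS association

The response is the meta-analytic z-map sampled at expression sample
coordinates by nearest voxel, standardized after dropping out-of-grid
samples. PLS is deflation-based with a single response: the
first-component weight vector equals X'y normalized — an exact identity
tested to 1e-10 and cross-checked against scikit-learn — and subsequent
components repeat on the deflated predictors. "Variance explained" is
incremental R² of the *response* on the accumulated scores (the
predictor-variance reading is the other possible interpretation; the
response reading is what the permutation test needs). Numerically-zero
X'y (below 1e-12 of the problem scale) is treated as exact orthogonality.

Surrogate maps: permute y; smooth with a k-nearest-neighbour exponential
kernel at each candidate bandwidth k ∈ {5, 10, 20, 40, 80}; fit
nonnegative (β, α) by NNLS so β·γ_smooth + α·γ_noise matches the target
variogram (25 bins up to the 0.25 distance quantile); keep the best-SSE
bandwidth; emit √β·smoothed + √α·noise, rank-remapped onto the original
value multiset by default. Component significance:
perm_p = (1 + #{surrogate expl_var ≥ observed})/(1 + n_surr), with ties
counted in the numerator; a component is carried forward only when
expl_var > 0.20 *and* perm_p < 0.05 — the variance gate applies
regardless of the permutation result.

Gene scores: bootstrap resampling of samples (degenerate constant-y
resamples redrawn and counted), each resample's PLS1 weights sign-aligned
to the point estimate, boot_se the SD across resamples (ddof 1, n_boot ≥
2 enforced), z = weight/boot_se, two-sided normal p, Bonferroni over the
number of genes entering PLS (not the pre-filter probe count, and genes
only — not genes × tails).

A documented caveat: when the response is spatially smooth, bootstrap z
for genes that merely share the spatial autocorrelation is
anti-conservative (the resampling null ignores spatial structure); the
surrogate permutation guards the component-level claim, and the null
calibration study below therefore uses a non-spatial response, where the
per-gene Bonferroni selection rate stays under 5%.

## Gene-set integration

Symbols are harmonized (uppercase, stripped, numeric version suffixes
removed; no alias resolution — mismatches are reported, since alias
tables would require an external database). Overlaps, the core
intersection, and all 2^T Venn region counts are computed set-exactly and
verified against brute-force region enumeration. Enrichment is the exact
hypergeometric upper tail P(X ≥ x) via `scipy.stats.hypergeom`, BH-adjusted
within each run via `statsmodels`; the background universe is always the
explicitly supplied one. PPI statistics: background graph from
STRING-style edges with combined score ≥ 0.4 (0–1000 scores auto-scaled);
observed edges of the query-induced subgraph; expected edges under a
degree-configuration (Chung–Lu) null, m_exp = Σ_{i<j} min(1, kᵢkⱼ/2E),
with a density null available by flag; p = Poisson upper tail;
betweenness is unnormalized shortest-path counting (networkx) on the
unweighted subgraph. Query genes absent from the background count as
isolated nodes.

## Synthetic data: what it emulates, and what it does not

**Bivariate GWAS.** z = R(√N·β) + ε, ε ~ N(0, R), with R block-diagonal
AR(1) (corr r^|i−j| within 100-SNP blocks, r = 0.8, zero across blocks);
blocks are tiled over 22 chromosomes at 1 kb SNP spacing with 1 Mb
inter-block gaps, so distinct blocks can never merge into one locus.
Causal classes are planted blockwise: each block draws one non-null class
(trait-1-only / trait-2-only / shared) with probability proportional to
the mixture, and SNPs within it are causal with probability
π₁₀+π₀₁+π₁₁. Per-SNP class marginals equal the mixture exactly, while
distinct non-null classes never co-locate in one block — under π₁₁ = 0
there is consequently no cross-trait LD confounding, and a conjFDR
discovery implies a truly shared block. (With per-SNP class assignment,
a 200-block genome would co-locate trait-1 and trait-2 causals in ~30
blocks, producing joint associations that are real but not shared-causal;
at genome scale that co-location is rare, so the blockwise scheme is the
faithful desk-scale analogue.) Shared causals carry one standardized
effect scaled per trait (effect correlation 1.0): the same variant drives
both traits. Default mixture (0.985, 0.005, 0.005, 0.005); effect SDs are
calibrated analytically to a mean χ² of 1.6 per trait via
E[z²] = 1 + N·σ²·π_causal·(1+r²)/(1−r²). Allele frequencies, MAF-dependent
power, imputation quality and population structure are *not* modelled;
alleles are placeholders.

**Expression atlas.** Sample coordinates uniform in a 100-mm box; spatial
fields are k-nearest-neighbour kernel-smoothed i.i.d. noise (k = 20
neighbours by default) — cheap, with a nontrivial variogram, but not an
exact Gaussian process. Signal genes add 2 × the target map. Each gene
gets a clean and a noisy probe (SDs 0.2 / 1.0) and ~10% of probes get a
poor above-background rate, so the filtering and probe-selection stages
have real work. Donors are assigned round-robin, regions are Voronoi
cells of random centers, structure classes cycle cortex / subcortex /
cerebellum. Left-hemisphere-only donor asymmetry, batch effects and
donor-specific expression shifts beyond what SRS removes are not
emulated.

**Study peaks.** Peaks are the strongest local extrema of |truth map|,
jittered uniformly within ± jitter_mm per axis; t magnitudes are drawn
uniformly in t_range with the truth map's sign, *independently of the
group sizes* drawn in n_range — which deliberately induces funnel
asymmetry (smaller studies carry larger standardized effects), giving
Egger's test something real to detect.

**Annotations.** Genes tile chromosomes without overlap (1-based
inclusive); `block_gene_annotation` instead assigns one gene per LD block
spanning the block's bp range, which ties the GWAS genome to the
expression gene universe for end-to-end runs (the pipeline plants the
imaging signal at shared blocks' genes, so the core intersection has a
ground truth). Gene sets are uniform draws plus planted sets; the PPI is
a Chung–Lu background with Pareto expected degrees plus dense planted
modules at high score.

All generators are pure functions of their arguments including the seed
(single `default_rng` per call).

## Validation studies and their scale

The study conditions are fixed: pleiotropy recovery at M = 20,000 SNPs,
π₁₁ = 0.005, mean χ² ≈ 1.6, 20 seeds (mean shared-block recovery ≥ 50%,
with a π₁₁ = 0 control at the same effect sizes whose median discovery
count is 0, 11 seeds); gene recovery at 2000 genes / 30 signal / 200
samples / 200 bootstrap resamples over 10 seeds (mean ROC-AUC of |z|
against truth ≥ 0.9); surrogate null calibration over 200 datasets of 50
samples with 40 surrogates each (one-sided KS against uniform at
α = 0.01). These sizes were chosen so each study completes in seconds to
a couple of minutes on a single core while leaving the tested claims
statistically sharp. Passing them shows the estimators are correct and
calibrated *under the generators' assumptions*; it does not certify
behaviour under real LD structure, allele-frequency spectra, AHBA donor
idiosyncrasies, or real spatial autocorrelation.

The published worked example (five per-trait overlap counts 20/17/78/
87/82 and the six-gene core KBTBD4, FNBP4, MYBPC3, SLC39A13, PTPMT1,
NUP160) is exercised against a synthetic stand-in bundle constructed to
be consistent with those printed numbers, because the underlying
supplementary gene lists are not redistributable inputs of this package;
the construction is labelled synthetic where it is defined.

## Known limitations

- The condFDR estimator is only asymptotically calibrated; π₀ = 1 makes
  it conservative but sample overlap between GWAS is not corrected.
- Locus-to-gene assignment is positional only; eQTL and chromatin
  interaction mapping are out of scope, as is functional annotation of
  candidate SNPs against external databases (annotation columns pass
  through verbatim).
- The meta-analysis engine reconstructs effects from peaks with a single
  isotropic kernel; meta-regression on study covariates is not
  implemented (subgroup analysis is a config-filtered rerun).
- Bootstrap gene z-scores inherit spatial anti-conservatism for smooth
  responses (see above); interpret the Bonferroni gene list together
  with the surrogate component test.
- GO-DAG-aware enrichment and live STRING access are out of scope; the
  user supplies GMT and edge-list files.
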