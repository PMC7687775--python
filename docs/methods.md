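# Methods

## Model and procedure

The package decomposes shared genetic risk across a set of case-control (or
standardised quantitative) GWAS using only their summary statistics. Three
obstacles shape the design: effect estimates β̂ carry noise whose scale
depends on sample size and allele frequency; SNPs are correlated through LD,
so naive decompositions double-count evidence; and the vast majority of
SNPs are null, so unshrunk decompositions largely organise studies by their
noise structure rather than by trait.

**Scaling.** Var(β̂) for an additive effect factorises into a sample-size
term and 1/(2f(1−f)) with f the allele frequency. Only the latter is
removed: σ_MAF(f) = 1/√(2f(1−f)). Dividing by the full standard error
would over-shrink small studies relative to large ones; dividing by σ_MAF
makes SNPs comparable while leaving study size alone.

**Shrinkage weight.** Within each LD block (recombination-boundary
defined), and separately for each training study, the Wakefield asymptotic
approximate Bayes factor

log ABF = ½·log(se²/(se²+W)) + ½·z²·W/(se²+W),  z = β̂/se,

is computed per SNP and converted to a posterior probability of causality
by a softmax over the block — the "at most one causal variant per block"
model with a flat prior over SNPs. The per-SNP weight w is the (by default
equal-weighted) average of these posteriors across studies. The posteriors
are not interpreted as calibrated probabilities (the causal variant may not
be typed); the method uses them only as an LD-aware, association-gated
shrinkage. An optional per-block null-model mass (`null_prior_odds`)
shrinks further in blocks with no signal; the default is the pure softmax.

**Prior.** W = 0.2² = 0.04, the conventional fine-mapping prior variance
for a log odds ratio (prior SD 0.2 ≈ most causal ORs within 0.67–1.5);
configurable. Results are insensitive to W at the level of basis structure
because w enters every trait identically.

**Basis.** The n × p matrix of γ̂ = wβ̂/σ_MAF over the shared variant
index, with an appended all-zero *control* row (the infinite-sample null
GWAS), is column mean-centred (the control row is included in the mean) and
decomposed by thin SVD. No column standardisation. Component signs are
fixed by making each column's largest-magnitude entry positive, so bases
are reproducible and serialisable. The retained rank is the smallest m
whose rank-m reconstruction attains the minimal mean squared error
(ties within 10⁻¹² broken downward); centring makes the last of n
components exactly redundant, so generic data give m = n − 1.

**Driver SNPs.** Each retained column Q_k is hard-thresholded:
Q_k(α) zeroes entries with |Q_ik| ≤ α, and the distortion
D_k(α) = 1 − cor(M^c Q_k, M^c Q_k(α)) is evaluated on the centred training
matrix. α_k is the largest value on the exact grid of distinct |Q_ik| with
D_k(α_k) < tol (default 10⁻³); if no grid value qualifies, α_k = 0. The
scan is exhaustive — no monotonicity of D along the grid is assumed — and
the grid is finite, so α_k is exactly reproducible. Nonzero entries of the
thresholded column are the component's driver SNPs.

**Projection.** An independent study aligned to the basis index is shrunk
with the *training* w and σ_MAF (frozen in the basis container; projected
studies never alter weights) and multiplied by the sparse rotation:
δ̂ = γ̂ᵀQ_s. Because centring cancels in differences, δ̂ equals the
centred projection of the trait minus the projected control. Variants
missing from the study enter with γ̂ = 0, which biases δ̂ toward the null
(conservative; a warning is emitted above 5% missingness).

**Inference.** Treating the sparse-rotation weights a_ik = Q_s,ik·w_i/σ_MAF,i
as fixed and β̂ as Gaussian with the study's standard errors and the
panel's block-diagonal LD correlation r,

Var(δ̂)_kl = Σ_blocks Σ_{i,j∈block} a_ik a_jl r_ij se_i se_j.

The global null δ = 0 is tested by T = δ̂ᵀV⁺δ̂ with p from χ² at
df = rank(V) (eigen-decomposition with relative cutoff 10⁻¹⁰, so degenerate
covariances lose degrees of freedom rather than fail); each component gets
a two-sided normal test on δ̂_k/√V_kk. Benjamini–Hochberg FDR is applied
across traits independently within user-supplied categories, overall and
per component; a trait is *component-significant* only if significant both
overall and on that component (strict thresholds, default 0.01). A
diagonal-LD option exists for panels without usable LD.

In the hard-threshold comparison mode (`z_threshold`, Z set to 0 when the
two-sided p > 10⁻³), the projection covariance treats kept Z scores as
unit-variance and ignores the selection nonlinearity; the mode exists for
method comparison, not inference.

**Consistency.** To guard against a significant δ̂_k produced by a single
outlier SNP, the trait's γ̂ is correlated with Q_ik over driver SNPs pruned
to pairwise r² < 0.01 (greedy, in decreasing |Q_ik|), using a weighted
Spearman statistic: values are converted to average ranks and correlated by
weighted Pearson with weights w/σ_MAF. No canonical weighted Spearman
exists; this rank-then-weight construction reduces exactly to ordinary
Spearman under equal weights. Significance comes from permuting the trait's
values: p = (1 + #{|ρ_perm| ≥ |ρ|})/(n_perm + 1), default n_perm = 10,000,
seed mandatory.

**Subset-selected FDR.** For a trait significant on ≥ 1 component, GWAS
p-values (two-sided from β̂/se) at the union of those components' driver
SNPs are BH-adjusted *within that subset only*, ranked by increasing ssFDR
(ties by raw p, then variant key), and greedily LD-pruned so that no
retained SNP has r² > 0.1 with a higher-placed one (ties at the bound
survive; pruned SNPs are flagged, not dropped, in the output table).

**Clustering.** Projected traits are clustered on the Euclidean distance
between δ̂ vectors under Ward's minimum-variance criterion; scipy's `ward`
linkage on raw observations implements exactly the Ward.D2 update. Output
includes the merge table and a Newick serialisation with branch lengths as
merge-height differences.

## Harmonisation rules

Variants are keyed chrom:pos:ref:alt, positions 1-based inclusive (GRCh37
convention); BED inputs (masks, block files) are 0-based half-open and
converted on read. Study alleles matching the panel exactly keep β̂'s sign;
swapped alleles flip it; strand-ambiguous palindromic SNPs (A/T, C/G) and
unmatched or multi-allelic records are dropped — no strand inference is
attempted. Indels are dropped by default (`keep_indels` retains bi-allelic
ones). Default filters: MAF > 1% and exclusion of the MHC
(chr6:20–40 Mb, GRCh37, overridable) whose long-range LD and outsized
effects would otherwise dominate the basis. No allele-frequency
concordance check between study and panel is performed. Missing-variant
handling lives entirely in projection (γ̂ = 0); harmonisation only records
missingness.

## Synthetic data

The generator mirrors the three inputs the method consumes.

*Panel*: equally sized contiguous blocks (default 200 blocks of 100 SNPs),
within-block correlation r_ij = ρ^|i−j| (AR(1), default ρ = 0.9 — chosen
for analytic tractability of the variance oracle), alt-allele frequencies
uniform on (0.05, 0.95), allele pairs never palindromic so no simulated
variant is lost to strand ambiguity.

*Traits*: true effects are loadings × sparse latent components, each
component placing at most one causal SNP per block (matching the
fine-mapping assumption) in a `causal_density` fraction of blocks (default
10%), with per-SNP effects N(0, 0.15²) — log odds ratios mostly within
0.75–1.35, typical of common-variant associations for complex immune
diseases. Observed β̂ adds block-correlated sampling noise with
se = σ_MAF(f)/√N_eff, N_eff = 4/(1/N_cases + 1/N_controls) (default
10,000/10,000), exactly the standard error reported — so closed-form
variance calculations are exact oracles — plus optional i.i.d. technical
noise not reflected in se.

*Scenario helpers*: `latent_recovery_scenario` draws orthogonalised
loadings with per-component strengths (1.8, 1.0, 0.55). PCA identifies the
generating axes, not just their span, only when the factors contribute
distinguishably; orthogonal, strength-separated loadings encode distinct
latent risk processes of differing total contribution, the regime in which
axis recovery is a meaningful ask. `simulate_paired_cohorts` gives each of
4 diseases a basis GWAS (5,000/5,000) and a small projected replicate
(1,000/1,000); all replicates share one biobank-style error component
(scale 1.5× the small-study sampling error), the signature of shared
controls. Basis-study noise is comparable in total magnitude to the
disease signal, as in real GWAS where almost all SNPs are null — the
regime in which an unshrunk basis wastes components on study noise and
projected replicates collapse toward the origin, clustering by cohort,
while continuous shrinkage recovers disease pairing.

What the generator does **not** emulate: realistic human LD (no hotspot
length variation, no long-range LD, no MAF–LD coupling), population
structure or ancestry mismatch between study and panel, imputation error,
case-control ascertainment beyond the N_eff approximation, and shared
controls *between basis studies*. Passing tests therefore demonstrate
internal correctness and the claimed qualitative contrasts under the
model's own assumptions, not performance on real data.

## Numerical choices

- PCA via `numpy.linalg.svd` on the centred matrix; deterministic sign
  fixing as above; rank ties broken toward smaller m within 10⁻¹²
  (relative to the leading MSE).
- Softmax posteriors via log-sum-exp; log-ABF computed wholly in log space.
- Covariance rank detection at relative eigenvalue cutoff 10⁻¹⁰; V is
  symmetrised before use.
- Sparsification distortion is computed by cumulative subtraction over the
  sorted entries (O(n·p) per component), then verified in tests against a
  direct per-threshold recomputation.
- Basis serialisation writes floats at 17 significant digits and verifies
  sha256 checksums on load; readers use round-trip float parsing, so
  save → load → save is byte-identical and projections through a reloaded
  basis agree exactly.
- Degenerate inputs: empty blocks, all-zero matrices, zero-variance
  component scores, constant rank vectors and sub-3-SNP pruned driver sets
  raise informative errors rather than returning NaN.

## Problem sizes used in the test suite

Structural checks (rank selection, sparsification fidelity) run at the
package's default scenario — 13 traits, 20,000 SNPs, 200 blocks — where a
basis builds in a few seconds. Calibration uses 2,000 projected null
studies on a 2,000-SNP basis; the Monte-Carlo variance oracle uses 10⁵
resamples on a 90-SNP, 3-block panel; the shrinkage-vs-naive contrast uses
20 seeds of the paired-cohort scenario; latent recovery runs at the full
default size. These sizes were chosen so each property is tested in its
asymptotically meaningful regime while the whole suite stays interactive.

## Known limitations

- The single-causal-variant model understates w where a block carries
  several independent signals; the paper's scope excludes multi-signal
  fine-mapping, and so does this package.
- Weights learnt from training studies with shared controls or platforms
  would absorb that shared structure into the basis; basis studies are
  assumed independent.
- The delta-method covariance conditions on the learnt weights; it ignores
  uncertainty in w and in the panel LD estimates.
- Setting missing γ̂ to zero is conservative for testing but biases δ̂
  magnitudes toward zero; traits sensitive to missingness should be
  externally imputed before projection (out of scope here).
- The MAF filter, MHC mask and LD-block definition come from the reference
  panel; results are only as good as that panel's match to the studies'
  ancestry.
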