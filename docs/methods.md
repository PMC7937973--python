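# Methods

## Scope and model

The package implements a global-to-local facial endophenotype analysis: dense
corresponded 3D landmarks per individual are reduced to symmetric, aligned,
covariate-adjusted shape vectors; the face is partitioned into a nested
hierarchy of segments driven by landmark covariation; a two-group contrast
defines one trait direction per segment; individuals are scored against these
directions; and the scores are carried into SNP association, meta-analysis
and polygenic-score testing. Every stage is exercised against synthetic
cohorts whose generative structure matches the assumptions listed below.

## Shape preparation

**Symmetrization.** Reflection negates x and re-indexes landmarks by the
template's left–right pairing involution, so landmark identity is preserved.
One configuration's symmetric component is the average of the original and
its reflection after a two-shape GPA onto their joint mean, followed by exact
projection onto the mirror-symmetric subspace. This last projection is a
numerical guarantee (the GPA-averaged pair is symmetric only up to the
frame); it assumes inputs arrive roughly in template orientation, which holds
for template-mapped data.

**GPA.** Iterative superimposition: centre, optionally scale (unit centroid
size, with per-iteration optimal rescaling), rotate by proper orthogonal
Procrustes onto the running consensus; converged when the consensus moves
< 1e-8 (Frobenius), max 100 iterations. Improper rotations are excluded —
reflections are handled explicitly by the pairing map. The final solution is
put in a canonical orientation (consensus on its principal axes, signs fixed
by the largest-magnitude coordinate): without this convention GPA output is
only defined up to a global rotation, and with it the procedure is exactly
equivariant under rigid motions of the inputs. Whole-face GPA removes scale
and exports centroid size as the "facial size" covariate.

**QC.** Mahalanobis distance of each shape to the mean is computed in a
PCA-reduced space (enough components for 98% variance by default) so the
covariance is invertible; distances are standardised to Z-scores and faces
with z > 2 (or high missingness) are flagged. The reduced space is a design
choice: full-coordinate covariance is singular whenever 3p > n.

**Covariate adjustment.** PLSR of the shape block on the centred covariates
with as many components as covariates (capped at their rank, with a warning);
the fitted effect is removed and the grand mean retained. At the full
component count on full-rank covariates this equals least-squares
residualisation, making residuals exactly uncorrelated with every covariate
— a property the tests verify against an independent OLS oracle. Cohorts are
adjusted separately and concatenated afterwards.

## Segmentation

**Similarity.** Escoufier's RV between each pair of landmarks' 3-column
blocks, computed in one blocked cross-product pass. RV is invariant to
rotation of either block, which makes the similarity insensitive to the
global orientation convention.

**Hierarchy.** Recursive two-way spectral bisection of the similarity:
symmetric normalized Laplacian L = I − D^{−1/2} S D^{−1/2}, Fiedler vector
scaled back to the random-walk embedding, split by seeded 2-means (10
restarts). Five rounds below the full face give 63 segments in heap
numbering (root 1; children 2i, 2i+1). Two guards make the deep tree
reliable at desk scale: (a) children at level l must keep at least
3·2^(5−l) landmarks so every branch can support the remaining rounds, and
(b) when 2-means would violate that floor — mirror-paired landmarks halve
the effective count and genuinely tiny tight clusters occur — the split
falls back to the minimum-normalized-cut threshold along the sorted Fiedler
embedding subject to the size constraint. 2-means remains the primary rule;
the fallback only engages at the floor. Spatial contiguity is not enforced:
clusters follow covariance only.

**Per-segment shape spaces.** Each segment is re-aligned by its own GPA
removing position and orientation only — scale was removed once at the
whole-face stage, so relative segment size remains shape information. PCA
follows, with the retained dimension k chosen by Horn's parallel analysis
(100 column permutations, 95th percentile). Two numerical points:

* Procrustes-aligned coordinates live in the orthogonal complement of the
  translation/rotation modes at the consensus. Permuted data is not so
  confined, so the null spectra are computed after projecting the permuted
  data onto that complement and rescaling to the observed total variance;
  without this, isotropic noise appears to have full structure (every one of
  the 3m−6 retained dimensions beats the null) or, conversely, the null is
  deflated. With it, pure noise retains ≤ 1 component ~95% of the time and
  planted low-rank structure is recovered exactly.
* `fit_segment_model` rejects a segment with k = 0 by default; the pipeline
  passes `min_k=1` (with a warning) because trait definition needs at least
  the leading component in every segment.

**Projection.** New faces are superimposed onto a segment's mean by
translation and proper rotation only, then multiplied by the orthonormal
basis. This makes projection an exact left inverse of the basis synthesis
(project(mean + c·b_j) = c·e_j) and invariant to rigid motions of the input.

## Endophenotype traits

With a single centred binary predictor, the one-component PLSR weight vector
is the covariance between label and PC scores — i.e. exactly parallel to the
group-mean difference — so the contrast is implemented in closed form
(sklearn's NIPALS implementation serves as an independent cross-check in the
tests). The direction is unit-normalised and oriented so that moving along it
increases the parent-group mean; the effect size is the pooled
R² = 1 − SS_res/SS_tot over the k responses. Significance is by label
permutation with the add-one convention p = (1 + #{R²_perm ≥ R²_obs}) /
(1 + n_perm), n_perm = 10,000 by default, so p ≥ 1/(n_perm+1). Scoring is
the cosine distance in PC space, in [0, 2], scale-invariant in the
individual's vector.

The effective number of tests m_eff applies the Li–Ji eigenvalue count
f(λ) = 1(λ≥1) + (λ − ⌊λ⌋) to the Pearson correlation matrix of the
per-individual trait score vectors ("pairwise multivariate correlations" is
read as correlations of the univariate cosine scores — the quantity actually
tested downstream; a multivariate association coefficient between
different-dimensional PC spaces would be an equally defensible reading).
Eigenvalues are rounded to 9 decimals before the floor, which is
discontinuous at integers (λ = 3 − 1e−16 must count as 3). Bonferroni
thresholds follow as α/m_eff: 0.05/41 ≈ 1.2e−3 and 0.05/38 ≈ 1.3e−3 at the
reference trait counts, and 5e−8/59 ≈ 8.47e−10 for the study-wide GWAS
threshold.

## GWAS and PRS

Association is simple per-cohort OLS of the score on the additive
major-allele dosage (no covariates — adjustment happened on shapes; an
optional hook exists), t on n−2 df; meta-analysis is fixed-effect IVW;
distance clumping takes the per-SNP best p across traits, then greedily
assigns SNPs within ±500 kb (inclusive, 1-based positions) to the best
remaining lead, ties broken by (chromosome, position). Loci are disjoint by
construction.

PRS: summary SNPs are intersected with the target panel (allele-mismatched
SNPs dropped and counted), LD-clumped greedily by ascending p removing
unretained SNPs with r² > 0.1 within ±250 kb of each index SNP, and summed
as β × dosage over SNPs passing each threshold. Effect alleles are aligned
by flipping the beta sign when the counted allele is the other allele — the
convention under which swapping A1/A2 and negating β leaves scores exactly
unchanged (re-coding dosages as 2−d would shift scores by a constant).
Missing dosages are imputed at twice the effect-allele frequency. The
threshold grid is 5×10⁻⁸ to 1 in steps of 5×10⁻⁵ (20,001 thresholds as
realized; the grid is a parameter and the count is recorded in the run
manifest); inclusion sets are nested, and scores are accumulated
incrementally in p-order. The scan regresses the PRS (response) on each
trait score (predictor), reports the per-trait minimum p across thresholds,
and flags it against α/m_eff of the tested traits. Scans run per cohort; no
combined scan.

## Synthetic data: what it emulates and what it does not

* **Template**: a parametric half-ellipsoid lattice (rows × odd columns, the
  middle column on the midline), with seeded symmetric jitter. It preserves
  the symmetry/pairing semantics of an anthropometric facial mask at any p;
  p must have an odd divisor ≥ 3 (the mirror pairing needs an odd column
  count) — p = 100/150/250 used throughout. It is not a face render.
* **Cohorts**: configurations = template + Σ_k z_ik b_k + covariate effects
  + group shift + isotropic noise. The latent bases b_k are unit-norm smooth
  Gaussian fields with length scales spanning 0.9 down to ~0.12 face units
  (multi-scale, so nearby landmarks covary at every scale — the structure
  the RV segmentation assumes), amplitudes 0.5·0.9^k. Noise sd defaults to
  0.01: small against latent structure at every segment scale, as real
  facial variation is against sensor noise. Covariate effects are linear
  with fixed documented coefficients along covariate-specific smooth fields.
  The group shift is a localized, mirror-symmetric unit field scaled by
  `effect_size`; no published effect scale exists for the parent-control
  contrast, so effect_size is a free parameter (default 1 in the pipeline).
* **Genotypes**: hard-call dosages from thresholded latent Gaussians;
  within-block AR(1) copula with ρ_z = sin(π·r/2) targeting genotype
  correlation r (exact at MAF 0.5, within the ±0.1 tolerance for MAF ≥ 0.2);
  X-chromosome males carry one haplotype coded 0/2. Causal SNPs define a
  standardized genetic score scaled to an exact population variance share
  h². No imputation uncertainty, phasing, or population structure is
  simulated.
* **Discovery summary statistics**: per-SNP linear regression of a simulated
  liability (genetic score + noise), columns SNP/CHR/BP/A1/A2/BETA/SE/P.

Passing tests therefore demonstrate correctness of the algorithms and
recoverability of planted structure under smooth, homoscedastic, unrelated-
individual conditions; they do not certify behaviour under mesh artifacts,
relatedness, ancestry stratification or imputation error.

## Problem sizes and defaults

The default pipeline configuration uses p = 250 landmarks, 120+120
"unselected" individuals in two cohorts, 80 parents + 160 controls, 400 SNPs
and 400 discovery individuals — sizes chosen so a full end-to-end run
completes in well under a minute while every stage retains detectable planted
structure. The analysis parameters themselves keep their full-study defaults
regardless of the desk-scale sample sizes (five segmentation levels, 10,000
permutations, α = 0.05, ±500 kb GWAS window, 5×10⁻⁸ genome-wide threshold,
r² = 0.1 / ±250 kb PRS clumping, 5×10⁻⁵ threshold step). Parameter-recovery checks run at their stated
conditions (e.g. trait direction at n = 500/group; causal-SNP power at
n = 3,000, which sits near 50% per replicate by the non-central t
calculation and is asserted as ≥ 10 of 20 seeded replicates).

## Known limitations

* Recursive bisection yields a binary tree; a k-way spectral variant per
  level would be an alternative reading of "hierarchical spectral
  clustering" and could produce different (non-binary) segmentations.
* The planted trait direction is only recoverable up to the similarity modes
  that superimposition removes (typically a few percent of its norm);
  recovery is measured against the mode-projected truth.
* The permutation test's vectorised label shuffling holds all n_perm
  permutation columns in memory (n × n_perm doubles).
* LD clumping computes pairwise r² on the fly (no banded cache); fine at
  desk scale, quadratic worst case in dense significant regions.
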