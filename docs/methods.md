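# Methods

## Network construction

A subject's network has one node per region of the bundled 68-region
Desikan-Killiany parcellation (34 per hemisphere). For regions A and B with
n₁ and n₂ vertices carrying d-dimensional feature vectors (d ≤ 6), the edge
weight derives from the combined Euclidean distance

e(A,B) = n₁n₂/(n₁+n₂) · [ 2/(n₁n₂) Σ‖aᵢ−bⱼ‖ − 1/n₁² Σ‖aᵢ−aⱼ‖ − 1/n₂² Σ‖bᵢ−bⱼ‖ ],

a scaled two-sample energy distance: the between-region term is penalized by
both regions' internal spread, so e = 0 iff the empirical distributions
coincide, and e is symmetric, translation-invariant and homogeneous of
degree one under uniform feature scaling. Pairwise sums are accumulated with
`scipy`'s `cdist`/`pdist` in double precision in a fixed order, so repeated
runs are bit-identical. The theory guarantees e ≥ 0; floating-point
negatives within 1e-10 are clipped to zero and anything more negative raises
an error rather than being silently absorbed.

Per subject, the V×V distance matrix is min–max normalized and exponentiated:
e_n = (e − e_min)/(e_max − e_min), c = exp(−e_n).

Two conventions here were genuinely open and are both implemented:

- **Range of the min–max.** The diagonal is structurally zero; including it
  would pin e_min = 0 for every subject and reduce the normalization to pure
  max-scaling. The default takes min and max over the off-diagonal upper
  triangle only, which maps the most-similar pair to c = 1 and the
  least-similar to c = e⁻¹ ≈ 0.368; the diagonal is set to 1 by definition.
  `include_diagonal_in_minmax=True` restores the other reading, under which
  off-diagonal values can approach but not reach 1 from below e⁻¹ upward.
- **Feature standardization.** Thickness (mm), area (mm²) and volume (mm³)
  live on incompatible scales, and the 2-norm would otherwise be dominated
  by whichever feature has the largest numeric spread. Each feature column
  is therefore z-scored against the subject's own pooled vertex mean/SD
  before the distance; the default is on for d > 1 and off for d = 1 (a
  single feature only changes by an affine map, which the min–max
  normalization absorbs anyway). The flag actually used is recorded in the
  matrix provenance.

## Graph analysis

Matrices are binarized by keeping the round(S · V(V−1)/2) strongest
off-diagonal weights at sparsity S (default sweep 20–40% in 1% steps). Ties
at the cutoff are broken by lexicographic (i, j) order so thresholding is
deterministic. Metrics are binary: Watts–Strogatz nodal clustering
(degree < 2 contributes 0) averaged into Cp; characteristic path length Lp
as the mean over reachable ordered pairs, with the number of unreachable
pairs reported rather than folded into the mean (harmonic or infinite-length
conventions change low-sparsity values; exclusion matches common toolkit
behaviour); exact Brandes betweenness with even splitting over tied shortest
paths, hubs being nodes above mean + SD (population SD).

Small-worldness compares Cp and Lp with the means of a null ensemble:
γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩, σ = γ/λ. The default null is
Maslov–Sneppen double-edge-swap rewiring (10·|E| swaps, 100 nulls), which
preserves the degree sequence exactly — a stricter and more standard null
than matching only node and edge counts; an Erdős–Rényi G(n, m) null is
available via `null_model="erdos_renyi"` for the looser reading. Null
generation is seeded and reproducible.

## Reliability

ICC(1,1), the single-rater one-way random-effects estimator: with n subjects
and k sessions, σ²_within = MSW, σ²_between = (MSB − MSW)/k, and
ICC = (MSB − MSW)/(MSB + (k−1)·MSW), with an F test (MSB/MSW on n−1, n(k−1)
df) for the between-subject effect. The one-way decomposition is exactly the
between/(between + within) variance fraction; sessions are not modelled as a
fixed factor. Negative estimates (MSB < MSW) are reported as computed with a
flag, not truncated, since truncation hides estimator behaviour near zero.
Bands: ICC > 0.75 "excellent", 0.59–0.75 "good". For betweenness, a per-node
ICC is computed and averaged across nodes (constant-BC nodes are skipped) to
give one curve point per sparsity; per-node results can be recovered by
calling `icc_one_way` directly.

## Classification

Each subject's upper triangle (2278 edges at V = 68) is one feature row.
Inside leave-one-out cross-validation, the training rows are z-scored
column-wise and the Lasso (½‖Xw−y‖² + λ‖w‖₁ on the ±1 labels) selects
edges; the held-out row is reduced to the same columns and scored by a
soft-margin SVM with RBF kernel exp(−‖x₁−x₂‖²/2σ²). Hyperparameters:

- λ: by default chosen per fold on a logarithmic path below ‖Xᵀy‖_∞ via
  stratified inner cross-validation of squared error on the training rows
  only; a fixed-λ mode is available for the classical single-λ protocol.
- (C, σ): grid search. The default `literal` protocol picks the pair
  maximizing the LOOCV accuracy itself — the historically common but
  optimistically biased choice; `nested` selects per outer fold on inner
  folds only, at higher cost, and reports carry the protocol tag.

A fold whose selection is empty (λ at or above the fold's ‖Xᵀy‖_∞) falls
back to all edges and is flagged, keeping the LOOCV total intact.
Sensitivity is defined on the +1 (patient) class. The ROC is built by
threshold sweep over decision values and the AUC equals the Mann–Whitney
pair-counting statistic with ties counted ½ — the sweep and the pair count
are checked against each other in the tests. Discriminative edges are the
strict intersection of per-fold selections, mapped to region pairs with
intra-left / intra-right / inter-hemispheric tags; edge–score (MMSE/CDR)
correlations are Pearson r with unadjusted two-sided p, flagged at p < 0.05.

### A note on the permutation control

Under label permutation the pipeline should score at chance. That only
holds when the kernel width grid spans the scale of the selected features:
with σ far below the typical inter-subject distance the Gram matrix
degenerates to the identity, the SVM reduces to a constant majority vote,
and — because each LOO training fold is imbalanced against the held-out
subject's class — the null accuracy collapses toward 0 rather than 0.5 (the
known LOOCV "anti-learning" artifact of majority-vote rules). The default
grids include widths matched to selected-feature dimensions, where
selection overfitting makes per-fold predictions effectively random and the
permuted-label accuracy lands in the binomial chance band.

### Numerical choices

The Lasso is solved by coordinate descent (scikit-learn, with the
α = λ/n objective mapping). Direct `lasso_select` calls default to a 1e-8
duality-gap tolerance, verified against the soft-threshold closed form on
orthonormal designs and an ISTA reference on random problems. Inside LOOCV
the support is detected at 1e-6, and the inner λ path search uses
warm-started `lasso_path` at 1e-3 — support identification is insensitive
to the looser gaps, and this keeps the n = 80 pipeline at roughly two
minutes on one CPU.

## Competitor constructions

The five single-feature formulas operate on per-region thickness summaries
(mean T, SD σ, mean absolute deviation, vertex count):

- Kong: symmetric KL between Gaussian-KDE densities (Silverman bandwidth,
  512-point shared grid over the pooled range ± 3 bandwidths, densities
  floored at 1e-12 before logs), c = exp(−KL).
- Kim: c = (Z(i,j) + Z(j,i))/2 with Z(i,j) = (T(i)−T(j))/σ_j. Both
  orderings average the same two terms, so the value is symmetric in (i, j)
  but signed; the magnitude is used when ranking edges for sparsity
  thresholding while the signed value is retained as a classification
  feature.
- Wee: c = exp(−(T(i)−T(j))²/2(σ_i+σ_j)²).
- Dai: c = exp(−(T(i)−T(j))²/η); η defaults to the median of the subject's
  squared mean differences (self-tuning) and is overridable.
- Zheng: c_precision = mad_i/mad_j (reciprocal under swap, undefined for
  zero deviation) and c_rough = (T(i)−T(j))². The two statistics are not
  combined in their source; the default network maps c_rough (a distance)
  through the same min–max + exponential as the energy construction and
  attaches the c_precision matrix as an auxiliary, with the choice recorded
  in provenance.

All six constructions emit the same `SimilarityMatrix` type and feed the
identical thresholding/classification machinery.

## Synthetic cohorts

The generator emulates what the pipeline consumes — FreeSurfer-like
vertex-wise exports — not the imaging process. Per region, a uniform vertex
count (default 40–120) and i.i.d. Gaussian feature vectors around
region-specific means; population scales are realistic per feature
(thickness 2.5 ± 0.3 mm, per-vertex area 0.6 ± 0.2 mm², volume
1.5 ± 0.5 mm³, sulcal depth / metric distortion / curvature dimensionless
around 0), with between-region mean heterogeneity so regions are
distinguishable and the unit-disparity motivating standardization is
present. Subjects get a stable trait deviation of regional means
(`between_subject_sd`, default 0.15 vertex-SDs); test–retest pairs share the
trait and the vertex-noise stream while session 2 perturbs regional means by
`within_subject_sd` (so zero session noise reproduces the table
byte-identically and any deterministic property has ICC = 1). Group effects
shift the affected regions' means by `effect_size` vertex-SDs with 15%
subject-to-subject variation in magnitude; MMSE-like scores decrease with
the realized magnitude (clipped to [0, 30]) and CDR-like scores map the same
latent severity to {0, 0.5, 1, 2, 3}.

Not modelled: spatial autocorrelation on the surface, non-Gaussian feature
distributions, scanner/site effects, and correlated multi-feature
covariance within a vertex. Passing tests therefore demonstrate the
statistical machinery — estimator correctness, invariances, planted-signal
recovery, null calibration — on data satisfying the pipeline's assumptions;
they do not certify effect sizes or reliability levels on real cohorts.

## Problem sizes

Default test and acceptance scales were chosen to keep full runs at a few
minutes on one CPU while preserving the structure being tested: 68 regions
throughout; 10–40 vertices per region in graph/ICC exercises and 40–120
(the generator default) in classification cohorts; 40 + 40 subjects with a
2-vertex-SD planted effect for classification; 100 nulls for small-world
indices; n = 500 subjects for ICC parameter recovery; n = 10,000 samples
for the KDE–KL closed-form comparison.

## Known limitations

- The energy-distance construction is O(V² · n̄²) per subject in vertex
  count n̄; real FreeSurfer meshes (10³–10⁴ vertices per region) are
  tractable but slower, and no subsampling is built in.
- `literal` hyperparameter selection is optimistically biased by design
  (it reproduces the classical protocol); use `nested` for unbiased
  estimates.
- Binary graph metrics only; weighted variants, modularity, efficiency and
  group-level statistical comparison of metric curves are out of scope.
- The ICC is the one-way ICC(1,1); two-way variants are not provided.
- Only delimited-text inputs are read; binary FreeSurfer formats
  (.mgh/.annot/.surf) require prior export to text.
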