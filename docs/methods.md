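# Methods

## The multi-scale co-occurrence model

A quantized volume `I` with gray levels `0 .. Ng-1` and a boolean VOI
mask defines, for displacement `d`, stride `s` and canonical digital
direction `θ`, the pair-count matrix

```
C_{i,j}(d, θ, s) = #{ p : p on the stride grid, mask(p), mask(p + d·θ),
                      p + d·θ inside the array, I(p) = i, I(p + d·θ) = j }
```

Pairs whose partner leaves the array or the mask are skipped silently
(the classical boundary convention; padding would fabricate texture at
the rim of small VOIs). With `symmetrize=true` (the default) the
transpose is added, which is equivalent to also counting the antipodal
direction; all shipped measures are invariant under this symmetrization,
and the one-sided counts remain inspectable by passing
`symmetrize=false`.

**Stride grid.** Origins sit at indices `{b, b+s, b+2s, …}` per strided
axis, where `b` is the VOI bounding-box minimum on that axis — anchoring
at the crop rather than the array makes results invariant to how
generously a lesion was cropped. In 3D the stride applies to the two
in-plane axes (array axes 0 and 1) while the slice axis (axis 2) is
traversed densely; this treats the volume as a stack of strided slices.
`stride_all_axes=true` strides all three axes instead. The in-plane
choice is the package's own convention for extending a 2D definition to
volumes; both variants are tested against the exhaustive oracle.

**Directions.** A digital direction is a nonzero integer offset vector;
antipodal pairs are collapsed by the half-space rule "keep `v` when
`dy > 0`, or `dy = 0, dx > 0`, or `dx = dy = 0, dz > 0`" (2D: `dx > 0`,
or `dx = 0, dy > 0`). "Displacement ≤ D" uses the Chebyshev norm, whose
half-ball counts are 13 / 62 / 171 for D = 1 / 2 / 3 — the familiar
direction-group sizes of volumetric texture analysis. De-duplication
removes non-primitive vectors (gcd of components > 1), i.e. collinear
repeats of a shorter ray, leaving 13 / 49 / 145. Sets are ordered by
(Chebyshev norm, then lexicographically on (dy, dx, dz)), so the set for
D is a prefix of the set for D+1 and enumeration is deterministic.

**Quantization.** Masked intensities are binned linearly into `Ng`
equal-width bins, by default over the per-VOI min–max range after air
cleansing (`Ng = 32` by default — a common radiomics choice that keeps
matrices reasonably dense for VOIs of a few thousand voxels). A fixed
`(lo, hi)` range is available for cross-lesion comparability on
calibrated scales. A constant VOI maps to bin 0, not an error.

## Measure roster

Gray levels in the formulas are the 0-based bin indices. Natural
logarithms throughout, with `0·log 0 := 0`. The 14 classic statistics
(angular second moment, contrast, correlation, sum-of-squares variance,
inverse difference moment, sum average, sum variance, sum entropy,
entropy, difference variance, difference entropy, the two information
measures of correlation, and the maximal correlation coefficient) follow
the standard definitions, with two documented choices:

* **sum variance** is the second moment of `p_{x+y}` about the *sum
  average* (the self-consistent form; the historical formula references
  sum entropy there, a well-known erratum);
* **sum-of-squares variance** is centered on `μ_x`.

Sixteen extensions complete the 30-measure roster: autocorrelation,
joint average, cluster average, cluster tendency, cluster shade, cluster
prominence, dissimilarity, maximum probability, inverse difference,
inverse difference normalized, inverse difference moment normalized,
inverse variance, the `μ_y`-centered marginal variance, the two marginal
entropies, and `homogeneity1`. Two entries are structural by design:

* `cluster_average = Σ ((i-μ_x) + (j-μ_y)) p(i,j)` is identically zero
  for every valid matrix (both centered marginal means vanish);
* `homogeneity1 = Σ_k p_{|i-j|}(k) / (1+k)` is analytically equal to
  `inverse_difference = Σ p(i,j) / (1+|i-j|)` — the same sum accumulated
  through the difference distribution instead of the joint matrix.

The **retained 28-measure roster** drops those two, and is the
per-direction block used by every descriptor. The historical 30-measure
roster this mirrors is not published formula-by-formula; this package's
roster is therefore its own documented definition satisfying the same
structural constraints (one identically-zero measure, one equivalent
pair, the classic 14 as a subset).

**Degenerate conventions.** When `σ_x σ_y = 0`, correlation-type
measures return 0; point-mass distributions have entropy 0; the maximal
correlation coefficient is computed on the submatrix of occupied levels
with eigenvalues clipped into [0, 1] and returns 0 when fewer than two
levels are occupied. A configuration that collects zero pairs (tiny mask
plus large stride/displacement) contributes the measure vector of a
point mass at level (0, 0) — entropies 0, ASM and maximum probability 1,
dispersions 0 — with a logged warning, rather than failing the lesion.

## Descriptors and scheme grids

MSGLCM descriptors concatenate retained-28 blocks in direction-set
order: `N_angles × 28` values (364 for the 13-direction base). The
2D baseline (`HF2D`) instead summarizes the 14 classic measures over the
four in-plane directions as 14 means + 14 ranges (28 values). Scheme
grids enumerate configurations deterministically: multiple displacements
{1,2,3} at stride 1; multiple strides {1..9} at displacement 1; multiple
angle groups {13, 62, 171} (or the de-duplicated {13, 49, 145}) at
d = s = 1; and the hybrid displacement × stride (27 configurations) and
angle-group × stride grids. Each configuration is tagged with its full
parameter tuple so feature tables are self-describing.

## Evaluation harness

Default protocol: 100 stratified train/test splits of a 31 benign + 32
malignant cohort into 15 + 16 train / 16 + 16 test, sampled without
replacement from the space of stratified splits and checked for
uniqueness; a master seed derives one sub-seed per iteration. Per split:

1. **Ranking** — mean Gini-impurity importance from a random forest
   fitted on the training fold (scikit-learn `RandomForestClassifier`);
   exact importance ties break by original column index (stable sort).
2. **Forward selection** — nested prefixes of the ranking (sizes
   1..`max_subset_size`, default 30) are scored and the argmax kept,
   first-found winning ties. Default scoring is **out-of-bag AUC on the
   training fold** (`leakage-safe`). The alternative `test-scored` mode
   scores prefixes on the test fold; it reproduces protocols that do not
   describe an inner validation split, but leaks test labels into model
   selection and inflates the reported AUC — it is shipped for
   comparison, clearly flagged, never as the default.
3. **Classification** — a forest with 2000 trees and `sqrt(n_features)`
   candidate variables per node, fitted on the selected subset; test
   scores are class-1 vote fractions.
4. **Metrics** — AUC by the rank-sum (Mann–Whitney) formulation with
   average ranks for ties (cross-checked against trapezoidal ROC
   integration in the tests); accuracy, sensitivity and specificity at
   the 0.5 vote-fraction threshold (an operating point chosen for
   symmetry, since vote fractions are calibrated around the training
   class balance, which is near 1:1 here).

## Synthetic phantoms

Each phantom lesion is Gaussian white noise smoothed with an isotropic
Gaussian kernel (standard deviation = the class correlation length),
rescaled to a target standard deviation and mean, inside a randomly
sized ellipsoidal mask — an isotropic stochastic texture with no
oriented structure, which is how soft-tissue lesion texture presents on
CT. Defaults define the study conditions: 31 + 32 lesions, 24³-voxel
VOIs, HU-like intensities (mean 50, SD 15), correlation length 1.5
voxels, air at −900, air fraction 0.05. The `separation` scalar shifts
both correlation length and contrast by `±separation/2` between classes,
so 0 yields exchangeable classes and ~1 a clearly separable cohort.

Air pockets are connected regions grown by dilation from random seeds
inside the mask until the target fraction is reached. Air cleansing is
a plain global threshold (default `air_value + 3·SD = −855`), a
deliberately simple stand-in for adaptive cleansing algorithms used on
real CTC data: on these phantoms air is a single well-separated mode, so
thresholding removes exactly the pocket voxels.

What the phantoms do *not* emulate: CT acquisition physics (beam
hardening, reconstruction kernels), anisotropic voxel spacing,
anatomical lesion morphology, partial-volume mixing at the air boundary,
and inter-scanner variation. Passing phantom tests therefore
demonstrates the correctness and statistical sanity of the pipeline —
chance-level AUC on exchangeable classes, high AUC when a texture gap
exists, air-cleansing recovering separability — not clinical
performance on real cohorts.

## Problem sizes and numerical notes

The shipped experiments use reduced ensemble settings (200 trees, 20
iterations, forward selection over the first 10 ranked variables, one
descriptor configuration at d = 1, s = 2) — sizes chosen so the full
synthetic study runs in a few minutes on a single core while keeping
Monte-Carlo error on the mean AUC near 0.02. The full-protocol defaults
(2000 trees, 100 iterations, 27-configuration grids) are plain
configuration changes.

The null-cohort check compares the mean AUC against 0.5 within three
standard errors computed from the between-split SD. With all iterations
drawn from one finite cohort, splits share the cohort's sampling noise,
so an individual cohort can sit a little off 0.5 in either direction;
the band is interpreted per-cohort, and the package reports the SD
alongside the mean so users can judge both sources of variation.

Known limitations: the maximal correlation coefficient is numerically
fragile on very sparse matrices (handled by level restriction and
eigenvalue clipping, but users comparing against other implementations
should expect small discrepancies there); stride monotonicity of the
pair total holds for full masks but can be violated locally by irregular
masks interacting with the grid; and descriptor values depend on `Ng`
and the quantization range policy, which must be held fixed across a
cohort for features to be comparable.
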