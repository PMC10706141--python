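# Methods

This note records the model, the conventions the implementation fixes,
and the reasoning behind design choices that the underlying problem
leaves open. It states no empirical result beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Problem and model

Trabecular bone attenuates X-rays in proportion to its mineral content,
so the HU statistics and spatial texture of a trabecular region on an
axial CT slice carry a bone-density signal. The pipeline regresses
DXA-referenced BMC (g) and BMD (g/cm²) on a fixed 45-dimensional texture
representation of one slice per scan, and regresses the two-year BMC/BMD
change on the 90-dimensional concatenation of a subject's two scans.
Model class: linear with a bias, ŷ = w₀ + Σ wᵢxᵢ, fitted on z-scored
features and targets. Assumptions:

* one axial slice (the largest trabecular cross-section) is
  representative of the scanned region;
* the feature→reference relation is approximately linear in the z-scored
  variables, and the case count comfortably exceeds 46 parameters, so an
  unregularized least-squares fit is appropriate for the headline model;
* L1 penalization is used for interpretability/sparsity, not accuracy —
  the λ path deliberately trades fit for fewer active features.

## Pipeline conventions

**ROI.** Thresholding keeps `hu_low ≤ HU ≤ hu_high`, default [50, 400]:
typical trabecular attenuation sits between marrow (≈ −100…0 HU) and
cortical bone (> 700 HU); the window is a reconstruction choice, not a
measured constant. Slice selection maximizes the in-window pixel count,
ties broken by lowest index (determinism). The circular ROI is centred
at the thresholded mask's centroid with radius
`shrink × d(centroid, exterior)`, where the exterior is measured against
the convex hull of the mask — the thresholded struts are fragmented at
the trabecular scale, and the hull is a parameter-free envelope of the
territory they span — and the image border counts as exterior half a
pixel beyond the outermost pixel centres. `shrink = 0.9` keeps the disk
clear of the cortical rim. The returned ROI is the full disk (all pixels
strictly inside the circle), marrow included: the texture contrast
between strut and marrow *is* the signal. Pixels are row-major,
0-indexed, centres at integer coordinates. Degenerate cases (empty
window, disk under 16 pixels) raise typed exclusions rather than passing
silently.

**Histogram features.** Mean; sample SD (ddof = 1); skewness and
kurtosis as third/fourth central moments over SD³ and SD⁴; Shannon
entropy in bits over a 64-bin equal-width histogram spanning the ROI's
[min, max]. A constant ROI defines SD = skewness = kurtosis = entropy
= 0.

**Quantization.** ROI-relative equal-width binning of [min, max] into
levels 1…n, half-open bins with the top edge closed (the maximum maps to
n); a constant ROI maps to level 1. Because binning is range-relative,
all GLCM features are invariant to additive HU shifts.

**GLCM.** Ordered (asymmetric) distance-1 pairs, offsets (0, +1)
horizontal and (+1, 0) vertical, both pixels in-ROI. Statistics use
level indices i, j ∈ 1…n; correlation is defined 0 when a marginal SD
vanishes. Feature index j = 5 + 20(l−1) + 5(m−1) + n is the
lexicographic order of (direction, level count, statistic).

## Regression numerics

* Z-scoring uses sample SD; zero-variance columns are dropped with a
  logged warning and recorded so prediction accepts raw matrices.
* The least-squares fit solves the bias-augmented system with the
  Moore–Penrose pseudoinverse: minimum-norm on rank-deficient designs.
  By default the estimator refuses designs with fewer samples than
  parameters (`require_overdetermined=True`); the pipeline relaxes this
  for the 90-feature change models only, with a logged warning, so small
  demonstration cohorts can still produce all four models. In-sample
  residuals of any bias-fitted model average zero to machine precision,
  which is why the in-sample paired t-test returns p = 1.
* LASSO minimizes Σ(y−ŷ)² + λΣ|w| (bias unpenalized) by cyclic
  coordinate descent with the closed-form soft-threshold update;
  convergence when max |Δw| < 1e-8 in a sweep, budget 10⁵ sweeps,
  non-convergence raising an error that carries the last iterate.
  Weights below the 1e-8 resolution are snapped to exact zero. With
  z-scored data the all-zero solution becomes optimal at
  λ_max = max|2 xᵀy|.
* The λ grid defaults to {0, 0.04} ∪ 20 log-spaced points on
  [1e-3, λ_max]. Along a path, fits are warm-started in ascending λ.
  The λ = 0 endpoint is computed in closed form via the pseudoinverse:
  at λ = 0 a collinear design gives the descent no unique minimizer to
  settle on. The cohort's feature sets are strongly collinear (the same
  statistic across neighbouring level counts correlates near 1;
  measured design condition numbers are ~10⁴), so near-zero λ fits
  approach their optimum along near-null directions too slowly for any
  practical budget; `lasso_path(..., on_nonconvergence="warn")` — used
  by the pipeline with a 2000-sweep budget — keeps the budget-exhausted
  iterate with a logged warning instead of aborting.
* The printed form of the penalty in the source material sums absolute
  *data* values over samples; that admits no optimization over {w, b}
  and is implemented as the standard penalty on weights.
* The optional neural network (hidden layers 8–8–2, ReLU, linear scalar
  output) is trained by seeded full-batch gradient descent on MSE,
  default learning rate 0.005. It is a baseline only; no acceptance
  property depends on it.

## Synthetic cohort generator

The generator plants known ground truth so recovery can be measured.
Per subject, (BMC, BMD) are drawn from a bivariate normal — defaults
BMC ~ N(15 g, 3 g), BMD ~ N(1.0, 0.15) g/cm², correlation 0.9, matching
the scale of L1 measurements in adults and the strong empirical BMC–BMD
coupling — and the timepoint-2 BMC adds N(−0.5 g, 0.5 g), a slow loss
plausible for a two-year interval, floored at 0.5 g.

Texture is a thresholded Gaussian random field: white noise smoothed
with σ = 1.5 px (the trabecular correlation length at 0.7 mm pixels),
binarized at the empirical quantile that yields bone fraction
f(BMC) = clip(0.5 + 0.45·(BMC − 15)/9, 0.05, 0.95) — a monotone link
spanning the clip band at ±3 SD of BMC. Struts get 400 HU, marrow 0 HU,
plus N(0, 20 HU) noise. Stacks have 5 slices whose bone area tapers 15%
per slice away from the centre, so slice selection has a unique,
testable maximum. The timepoint-2 latent field is 0.98·field₁ +
√(1−0.98²)·fresh, emulating the strong within-subject correlation of
longitudinal scans; without it, field-realization noise would swamp the
small planted change signal.

What the generator deliberately does **not** emulate: vertebral or
femoral anatomy (no cortical shell, no surrounding soft tissue), scanner
physics (beam hardening, reconstruction kernels, dose), patient motion,
or degenerative changes. Passing recovery tests therefore shows the
chain is correct and sensitive under the stated texture model — not
that clinical accuracy at any level is guaranteed.

## Problem sizes used by the tests

Parameter-recovery checks run a 400-subject cohort with a 300/100
subject-level split (both timepoints of a subject stay on one side to
avoid leakage); the in-sample unbiasedness check uses 200 cases; the
Monte-Carlo texture and monotonicity checks use 100 renders per arm;
reproducibility runs a 24-subject end-to-end pipeline twice and
byte-compares feature tables and model files. These sizes were chosen
to estimate each property stably.

## Known limitations

* The HU window, circle-fitting rule and feature-index formula are
  deterministic reconstructions of a procedure whose source describes
  them only qualitatively; results on real data will depend on the ROI
  protocol.
* GLCM features use a single pixel offset and two directions; no
  rotation-invariant averaging, run-length or wavelet features.
* The change regressor inherits all error of both timepoints' ROIs; on
  real longitudinal data, repositioning and protocol drift would add
  variance the generator does not model.
* Coordinate descent at near-zero λ on strongly collinear designs
  reports a budget-limited iterate (see above); the unpenalized model is
  exact via the pseudoinverse.
* DICOM support covers uncompressed 16-bit single-frame slices with
  standard rescale tags only.
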