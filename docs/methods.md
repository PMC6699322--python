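# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations of `ivimhsi`.

## Signal model and fitting

The biexponential IVIM model describes the normalized DWI decay as

    S_b / S_0 = (1 − PF)·exp(−b·D) + PF·exp(−b·D*)

with `D` (pure diffusion) and `D*` (pseudodiffusion) in 10⁻³ mm²/s and `PF`
(perfusion fraction) dimensionless. The model assumes two well-mixed
compartments per voxel, no exchange, and b-independent noise. The
monoexponential ADC is the negated slope of a log-linear least-squares fit
of `ln S` versus `b` over all b-values (with intercept, so it is invariant
to global signal rescaling); the two-point variant uses only the endpoint
pair. "Slope" is a dimensionless decay index defined here as the
least-squares slope of `S_b/S_0` against `b/1000`; no standard formula
exists for it, so this convention (which yields order 0.1–1 values) is a
package definition, with the log-signal slope available through `fit_adc`.

Fitting is two-stage:

1. **Segmented**: `D` from a log-linear fit on `b ≥ b_split`
   (default 250 s/mm², the point where `exp(−b·D*)` has decayed below ~0.1
   for typical lesion `D*` ≈ 9×10⁻³); `PF = 1 − exp(intercept)`; `D*` from a
   bounded scalar minimization of the full-curve residual.
2. **Full** (default): bounded trust-region nonlinear least squares over
   `(D, D*, PF)` with an analytic Jacobian, started from the segmented
   estimate. Bounds are `D ∈ [0.05, 3.5]`, `D* ∈ [1, 60]`, `PF ∈ [0, 0.6]`,
   bracketing all breast tissue classes with margin.

Non-convergence is flagged, never raised; flagged pixels hold NaN in the
parameter maps and are excluded from summaries. On noiseless biexponential
input the full fit recovers the generating parameters to well under 1 %
(the global optimum has zero residual).

### Precision limits at clinical noise

With Rician noise at SNR 50 (σ = 2 for a baseline of 100) and 12 b-values,
the Cramér–Rao bound for a single pixel's `D` is large for high-diffusivity,
moderate-perfusion tissue — roughly 0.26×10⁻³ mm²/s (≈ 23 % of the value)
for normal parenchyma and 0.6×10⁻³ for cyst fluid — because the likelihood
is nearly flat along a `D`–`D*`–`PF` ridge. Two practical consequences,
both visible in the test suite:

* Per-pixel `D` cannot separate classes whose means differ by ~0.1–0.45 in
  these units; classification must rely on the far more precise ADC (see
  below).
* The bounded maximum-likelihood estimate of `D` carries a small-sample
  bias: per-tissue means at SNR 50 recover the lesion classes to within a
  few percent, but the normal-parenchyma mean comes out ~6–7 % low. The
  acceptance suite documents this with a 5 % assertion that the normal
  class does not meet; the bias is intrinsic to per-pixel NLS at this noise
  level (it persists under multi-start optimization, order constraints
  `D* ≥ D`, absolute-signal fitting with free `S0`, and log-domain fitting),
  and removing it would require pooling information across pixels, which
  this package deliberately does not do (no spatial or hierarchical
  regularization of fits).

## Band expansion

The band expansion process generates, from `L` original bands: the
elementwise squares (`L`), pairwise products with `k < l` (`L(L−1)/2`), and
at third order cubes (`L`), squared-cross products `B_k²B_l` for `k ≠ l`
(`L(L−1)`, ordered pairs), and triple products with `k < l < m` (`C(L,3)`);
optional square-root and log stretches add `L` bands each. A 12-band cube
at second order yields 12 + 12 + 66 = 90 bands — the pipeline default.
Band order is fixed and recorded in a manifest. The log stretch uses
`log(1+x)` so zero-valued air pixels remain finite; variance normalization
(dividing each product band by its source bands' standard deviations) is
available but off by default. Band values stay in floating point; nothing
is rescaled to integer gray levels.

## Target generation and detection

**ATGP** starts from the maximum-norm pixel and repeatedly selects the
pixel with the largest orthogonal-subspace-projection residual
`‖P_U⊥ r‖²`, with `P_U⊥ = I − U(UᵀU)⁻¹Uᵀ`. Stopping: a fixed target count
(default 5), an optional angle-based rule (stop when the new target is
within ε of the previous by SAM), and a span-exhaustion rule (stop when the
largest residual falls below 10⁻¹⁰ of the largest pixel norm, which occurs
on low-rank cubes such as noiseless phantoms).

**SAM** is the arccosine of the normalized inner product, clipped into
[−1, 1] before `arccos`. Training samples for each target are all pixels
within an angle threshold (default 0.05 rad); their mean is the desired
signature `d`.

**CEM** solves `min_w wᵀRw` s.t. `wᵀd = 1` with `R = (1/N)Σ rᵢrᵢᵀ`, giving
`δ(r) = dᵀ(R+ρI)⁻¹r / dᵀ(R+ρI)⁻¹d`; the ridge ρ defaults to
`10⁻⁶·tr(R)/M` (scale-free conditioning). **KCEM** is the same detector in
a kernel feature space, evaluated on a background sample `B` of up to 2000
pixels (all pixels when fewer; a seeded uniform subsample otherwise)
through the matrix-inversion lemma:

    δ(r) = [k(d,r) − k_dᵀ(nρI + K)⁻¹k_r] / [k(d,d) − k_dᵀ(nρI + K)⁻¹k_d]

with `K` the background Gram matrix. This form is exactly CEM for the
linear kernel with the full background (the package's kernelization sanity
anchor, asserted to 10⁻⁶ in the tests). The RBF bandwidth defaults to the
median pairwise distance of a seeded 500-pixel subsample. Note that the
large-σ limit of RBF-KCEM is *not* plain linear CEM: the first-order kernel
expansion embeds a constant feature, so the limit is CEM on the affine map
`g(x) = [1 − ‖x‖²/2σ², x/σ]`, which is what the corresponding test checks.
Per-target detection maps are merged by pixelwise maximum.

## Thresholding

Detection maps are min–max quantized to 256 levels (order-preserving;
constant maps are an error). The local-entropy threshold builds the
symmetric gray-level co-occurrence matrix over horizontal and vertical
neighbor pairs and maximizes the sum of Shannon entropies of the
background–background and foreground–foreground quadrants, each
renormalized to unit mass; Otsu maximizes between-class variance of the
histogram. In both, foreground is *strictly above* the threshold (lesions
have high detector response) and argmax ties break toward the smaller
threshold (more inclusive masks). The entropy criterion depends only on
the induced partition, so it is exactly invariant under strictly increasing
relabelings; Otsu's criterion uses the level values and is only invariant
under affine relabelings.

## Breast-region extraction

Per slice: Laplacian (3×3) high-pass sharpening; Otsu binarization of the
sharpened image (via the same min–max quantization, hence invariant to
constant intensity offsets); a 2×2 morphological opening that detaches
1-pixel bridges; retention of the largest 8-connected component; hole
filling so the mask is the solid body region; and a Sobel edge pass for the
silhouette contour. An optional midline/sternum exclusion mask can be
supplied for bilateral clinical slices but is off by default — the phantom
has no sternum, and no standard structuring element exists for it.
Inter-volume motion is handled by integer-shift alignment maximizing
normalized cross-correlation over ±5 pixels; deformable registration and
bias-field correction are out of scope (the phantom's optional polynomial
bias field exists to exercise the segmentation's robustness, not to be
corrected).

## Classification

The decision tree applies two cuts on a primary parameter: below the tumor
cut → tumor; at or above the cyst cut (optionally with a PF confirmation)
→ cyst; otherwise normal. Tumor pixels are then split into central (at or
below the within-tumor cut; ties central) and peripheral zones; a median
split (strictly below the within-tumor median) is available.

**Choice of the primary parameter.** Biophysically `D` is the most
informative discriminator, and a D-driven tree (cuts at midpoints of
published class means: tumor 1.035, cyst 1.365, PF 0.361, central/peripheral
0.845) is available via `derive_thresholds(..., primary_param="D")`. At
clinical noise, however, the CRLB analysis above shows per-pixel `D` cannot
separate normal tissue from cysts, whereas the ADC — a linear fit using all
12 points — has ~50× smaller variance and separates all four classes by
many standard deviations. The default tree therefore splits on ADC, with
cuts derived as midpoints of the reference tissue classes' noiseless ADC
values under the 12-point schedule (tumor 1.369, cyst 1.824,
central/peripheral 1.100); all cuts and split parameters are configurable.
Pixels with invalid fits are labelled "other". When a detected lesion mask
is supplied, the central/peripheral split is evaluated inside it and
tumor-tree pixels outside default to peripheral; the pipeline classifies
all valid body pixels so that whole-image accuracy is well defined.

Histogram statistics use the Fisher–Pearson sample skewness and excess
kurtosis (normal → 0); statistics undefined at the sample size are NaN.
Case summaries report per-slice, per-class means of all five parameters;
the overall row is the arithmetic mean of per-slice means, weighting slices
equally regardless of pixel count.

## The phantom

The generator emulates a 64×64×3 axial acquisition at
b = 0, 15, 30, 45, 60, 100, 250, 400, 550, 700, 850, 1000 s/mm²: a body
ellipse of normal parenchyma containing a two-zone tumor (core + annular
rim) and a cyst, each pixel's noiseless signal following its tissue's
biexponential decay. Tissue parameters are published breast-class means
(central tumor D 0.76 / D* 9.38 / PF 0.215; peripheral 0.93 / 9.02 / 0.253;
cyst 1.59 / 4.62 / 0.411; normal 1.14 / 5.98 / 0.311). Baselines S0
(normal 100, tumor 110, cyst 130, air 0) are a convention chosen for
T2-like contrast — DWI baseline contrast is not a published class property.
Noise is Rician, applied independently per b-value image (independent
acquisitions); σ = 2 corresponds to SNR 50 against the parenchyma baseline.
Rasterization uses the pixel-center convention with 0-based indices.
Overlapping lesions of different tissues are an error; annuli express
nested zones without overlap.

What the phantom does *not* model — and hence what passing tests do not
demonstrate about clinical data: partial-volume mixing at tissue borders,
T1/T2 relaxation and echo-time effects, spatially correlated noise, ghosting
and EPI distortion, respiratory motion beyond integer shifts, intra-class
parameter heterogeneity (each class is homogeneous at its mean), and the
sternum/chest-wall anatomy that clinical breast masking must handle.

## Problem sizes and determinism

The test suite exercises the full chain on the 64×64×3 reference phantom
(≈ 5400 fitted pixels per condition) and the detectors on cubes up to
~12 000 pixels × 90 bands; the KCEM background sample is capped at 2000
pixels, keeping Gram matrices at most 2000². All stochastic steps (noise,
background subsampling, bandwidth heuristic) derive from explicit seeds;
identical configuration and seed reproduce every artifact bit-for-bit.

## Known limitations

* Per-pixel `D`, `D*`, `PF` at clinical SNR carry large variance and a
  small-sample bias (see above); treat single-pixel biexponential
  parameters as distributional, not pointwise, measurements.
* The tree is a fixed-threshold classifier, not a learned one; thresholds
  derived from class means assume roughly symmetric within-class spreads.
* The local-entropy threshold is fully automatic here; on clinical maps a
  per-slice manual override (`ivimhsi threshold --level`) may be needed.
* DICOM input is limited to what `read_ivim_cube` expects after conversion
  to NIfTI; DICOM writing is not supported.
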