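# ivimhsi

IVIM diffusion-MRI parameter mapping and hyperspectral-style breast lesion
detection.

`ivimhsi` is for researchers working with multi-b-value diffusion-weighted
MRI (DWI) of the breast who want a contrast-agent-free analysis chain: it
fits intravoxel incoherent motion (IVIM) parameters per pixel, treats the
b-value stack as a multispectral image cube, expands it into correlated
hyperspectral-style bands, detects lesion candidates with subpixel target
detection filters, and classifies tissue into central tumor, peripheral
tumor, cyst, and normal parenchyma. Because clinical DWI cohorts are rarely
shareable, the package ships a synthetic phantom generator with exact
ground truth, so every stage is testable end to end.

## The models

**Signal model.** DWI signal decay with diffusion weighting `b` (s/mm²) is
monoexponential for pure diffusion,

```
ln(S_b / S_0) = −b · ADC,
```

but perfusing capillary blood adds a fast pseudodiffusion compartment. The
IVIM biexponential model separates the two:

```
S_b / S_0 = (1 − PF) · exp(−b·D) + PF · exp(−b·D*),
```

with `D` the pure (tissue) diffusion coefficient, `D*` the pseudodiffusion
coefficient, and `PF` the perfusion fraction. Diffusivities are in
10⁻³ mm²/s throughout. Fitting is segmented (log-linear `D` on
b ≥ 250 s/mm², `PF` from the intercept deficit, bounded 1-D search for `D*`)
optionally followed by bounded joint nonlinear least squares.

**Detection.** The 12 b-value images form a 12-band cube. The band
expansion process (BEP) grows it to 90 bands (originals + elementwise
squares + pairwise products). The automatic target generation process
(ATGP) selects maximally orthogonal candidate pixels via orthogonal
subspace projection `P = I − U(UᵀU)⁻¹Uᵀ`; the spectral angle mapper (SAM)
gathers training pixels around each target; and constrained energy
minimization (CEM), `w = R⁻¹d / (dᵀR⁻¹d)` with `R` the sample correlation
matrix, or its RBF-kernel version (KCEM), produces real-valued detection
maps. A co-occurrence local-entropy threshold (with an Otsu baseline)
binarizes them into lesion masks.

**Classification.** A threshold decision tree on the fitted parameter maps
labels each pixel tumor / cyst / normal, then splits tumor pixels into a
low-diffusivity central core and a higher-diffusivity peripheral rim;
histogram statistics (mean, median, skewness, excess kurtosis) summarize
each region.

## Worked example

Generate the reference phantom (64×64×3, tumor core + rim and a cyst inside
a parenchyma ellipse) at SNR 50, run the full chain, and print per-class
parameter means:

```python
from ivimhsi import (PipelineConfig, generate_phantom,
                     reference_phantom_spec, run_pipeline)

spec = reference_phantom_spec(noise_sigma=2.0, seed=7)  # SNR 50 vs parenchyma
cube, true_labels, truth = generate_phantom(spec)
art = run_pipeline(PipelineConfig(seed=7), cube)

summary = art["summary"]
print(summary[summary["slice"] == "all"].round(3).to_string(index=False))
print("detected lesion pixels:", int(art["lesion_mask"].sum()))
```

Output:

```
slice            label   ADC  slope     D  Dstar    PF    n
  all           normal 1.527 -0.796 1.067  7.285 0.355 4661
  all             cyst 2.117 -0.911 1.579  6.586 0.416  243
  all    tumor_central 0.988 -0.624 0.723  9.772 0.237  112
  all tumor_peripheral 1.213 -0.699 0.901  9.690 0.273  339

detected lesion pixels: 635
```

Each row is a tissue class with the mean of its fitted maps: tumor pixels
show low `D`/`ADC` with high `D*` and moderate `PF` (cellular tissue, rich
perfusion), the cyst shows high `D`/`ADC` with high `PF` and low `D*` (free
fluid), and the generating values (D 0.76 / 0.93 / 1.59 / 1.14 for central,
peripheral, cyst, normal) are recovered to within a few percent at this
noise level. The label map in `art["label_map"]` matches the phantom's
ground-truth classes for ≥ 99% of body pixels.

The same chain is available from the shell:

```
ivimhsi phantom --seed 7 --out ph/
ivimhsi pipeline --cube ph/cube.nii.gz --seed 7 --out results/
```

## Layout

| module | role |
|---|---|
| `ivimhsi.phantom` | synthetic IVIM cubes with ground truth |
| `ivimhsi.ivim_model` | signal models and per-pixel fitting |
| `ivimhsi.bep` | band expansion process |
| `ivimhsi.detect` | ATGP, SAM, CEM/KCEM |
| `ivimhsi.threshold` | local-entropy and Otsu thresholding |
| `ivimhsi.breastseg` | breast-region extraction, integer alignment |
| `ivimhsi.classify` | decision tree, histogram stats, case summaries |
| `ivimhsi.io`, `ivimhsi.pipeline`, `ivimhsi.cli` | NIfTI/CSV/YAML I/O, end-to-end pipeline, CLI |

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
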