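"""Synthetic IVIM phantoms with known per-pixel tissue labels and parameters.

A phantom is a body ellipse of "normal" breast parenchyma containing
elliptical (optionally annular) lesions, each assigned the IVIM parameters of
a named tissue.  The noiseless signal of every in-body pixel follows the
biexponential IVIM decay of its tissue across the b-value schedule; air is
zero.  Magnitude-MRI noise is modelled as Rician, and an optional low-order
polynomial bias field emulates receive-coil shading.

Default tissue parameters are clinical breast-tissue class means
(diffusivities in 1e-3 mm^2/s):

====================  =====  =====  =====
tissue                  D      D*     PF
====================  =====  =====  =====
tumor (central)        0.76   9.38  0.215
tumor (peripheral)     0.93   9.02  0.253
cyst                   1.59   4.62  0.411
normal parenchyma      1.14   5.98  0.311
====================  =====  =====  =====

Baseline amplitudes S0 (normal 100, tumor 110, cyst 130, air 0) are a
convention giving T2-like lesion contrast; DWI baseline contrast is
acquisition-dependent and not a class property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ivimhsi import labels
from ivimhsi.ivim_model import (
    IVIMCube,
    ParamMaps,
    TissueParams,
    biexp_signal,
    fit_adc,
    fit_slope,
    validate_bvalues,
)

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "DEFAULT_BVALUES",
    "DEFAULT_TISSUES",
    "generate_phantom",
    "add_rician_noise",
    "reference_phantom_spec",
]

#: the 12-point clinical breast IVIM schedule (s/mm^2)
DEFAULT_BVALUES = (0, 15, 30, 45, 60, 100, 250, 400, 550, 700, 850, 1000)

DEFAULT_TISSUES = {
    "normal": TissueParams(D=1.14, Dstar=5.98, PF=0.311, S0=100.0),
    "tumor_central": TissueParams(D=0.76, Dstar=9.38, PF=0.215, S0=110.0),
    "tumor_peripheral": TissueParams(D=0.93, Dstar=9.02, PF=0.253, S0=110.0),
    "cyst": TissueParams(D=1.59, Dstar=4.62, PF=0.411, S0=130.0),
}


@dataclass(frozen=True)
class Ellipse:
    """An axis-aligned elliptical region in pixel coordinates.

    ``center`` and ``semi_axes`` are (row, col); ``slices`` is an inclusive
    (first, last) range, or None for all slices.  A nonzero ``hole_semi_axes``
    carves a concentric elliptical hole, turning the region into an annulus.
    A pixel belongs to the region if its center lies inside (0-based,
    pixel-center convention).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    slices: tuple[int, int] | None = None
    hole_semi_axes: tuple[float, float] | None = None

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        rows, cols, nslices = shape
        r, c = np.mgrid[0:rows, 0:cols].astype(float)
        inside = self._inside2d(r, c, self.semi_axes)
        if self.hole_semi_axes is not None:
            inside &= ~self._inside2d(r, c, self.hole_semi_axes)
        out = np.zeros(shape, dtype=bool)
        lo, hi = (0, nslices - 1) if self.slices is None else self.slices
        out[:, :, lo : hi + 1] = inside[:, :, None]
        return out

    def _inside2d(self, r, c, axes):
        ar, ac = axes
        return ((r - self.center[0]) / ar) ** 2 + ((c - self.center[1]) / ac) ** 2 <= 1.0


@dataclass(frozen=True)
class Lesion:
    shape: Ellipse
    tissue: str
    name: str = ""


@dataclass
class PhantomSpec:
    """Full description of a synthetic IVIM acquisition."""

    shape: tuple[int, int, int] = (64, 64, 3)
    bvals: tuple = DEFAULT_BVALUES
    body: Ellipse = field(default_factory=lambda: Ellipse((32.0, 32.0), (26.0, 22.0)))
    body_tissue: str = "normal"
    lesions: tuple[Lesion, ...] = ()
    tissues: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    noise_sigma: float = 0.0
    bias_coeffs: np.ndarray | None = None  # 2-D polynomial coefficient matrix (np.polynomial.polyval2d)
    seed: int = 0

    def __post_init__(self) -> None:
        self.bvals = tuple(float(b) for b in validate_bvalues(self.bvals, require_zero=True))
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.body_tissue not in self.tissues:
            raise ValueError(f"unknown body tissue {self.body_tissue!r}")
        for les in self.lesions:
            if les.tissue not in self.tissues:
                raise ValueError(f"unknown lesion tissue {les.tissue!r}")


def _tissue_code(name: str, extra: dict) -> int:
    if name in labels.CODES:
        return labels.CODES[name]
    if name not in extra:
        extra[name] = max(list(labels.CODES.values()) + list(extra.values())) + 1
    return extra[name]


def rasterize_labels(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Paint body and lesion tissues into an integer label map.

    Overlapping lesions of different tissues are an error; lesions must lie
    inside the body ellipse.
    """
    shape = spec.shape
    label_map = np.zeros(shape, dtype=np.int16)
    tissue_of_code = {labels.BACKGROUND: None}
    extra: dict = {}

    body_mask = spec.body.mask(shape)
    body_code = _tissue_code(spec.body_tissue, extra)
    label_map[body_mask] = body_code
    tissue_of_code[body_code] = spec.body_tissue

    owner = np.full(shape, -1, dtype=int)  # lesion index owning each pixel
    for i, les in enumerate(spec.lesions):
        m = les.shape.mask(shape)
        if not m.any():
            continue
        if np.any(m & ~body_mask):
            raise ValueError(f"lesion {les.name or i!r} extends outside the body ellipse")
        clash = m & (owner >= 0)
        if clash.any():
            j = int(owner[clash][0])
            other = spec.lesions[j]
            if other.tissue != les.tissue:
                raise ValueError(
                    f"lesions {other.name or j!r} and {les.name or i!r} overlap "
                    f"with different tissues ({other.tissue} vs {les.tissue})"
                )
        code = _tissue_code(les.tissue, extra)
        label_map[m] = code
        owner[m] = i
        tissue_of_code[code] = les.tissue
    return label_map, tissue_of_code


def _bias_field(shape: tuple[int, int, int], coeffs: np.ndarray) -> np.ndarray:
    rows, cols, _ = shape
    r = np.linspace(-1.0, 1.0, rows)
    c = np.linspace(-1.0, 1.0, cols)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    field2d = np.polynomial.polynomial.polyval2d(rr, cc, np.asarray(coeffs, dtype=float))
    return np.repeat(field2d[:, :, None], shape[2], axis=2)


def generate_phantom(spec: PhantomSpec) -> tuple[IVIMCube, np.ndarray, ParamMaps]:
    """Generate (cube, label map, ground-truth parameter maps) from a spec.

    The result is a pure function of the spec (including its seed): repeated
    calls reproduce the cube bit-for-bit.
    """
    label_map, tissue_of_code = rasterize_labels(spec)
    b = np.asarray(spec.bvals)
    shape = spec.shape
    data = np.zeros(shape + (b.size,), dtype=float)

    gt = {name: np.full(shape, np.nan) for name in ParamMaps.PARAM_NAMES}
    valid = np.zeros(shape, dtype=bool)

    for code, tissue in tissue_of_code.items():
        if tissue is None:
            continue
        tp: TissueParams = spec.tissues[tissue]
        sel = label_map == code
        sig = tp.S0 * np.asarray(biexp_signal(tp, b))
        data[sel, :] = sig
        gt["D"][sel] = tp.D
        gt["Dstar"][sel] = tp.Dstar
        gt["PF"][sel] = tp.PF
        # ground-truth ADC/slope are the definitions applied to the noiseless decay
        gt["ADC"][sel] = fit_adc(sig, b)
        gt["slope"][sel] = fit_slope(sig, b)
        valid |= sel

    if spec.bias_coeffs is not None:
        data *= _bias_field(shape, spec.bias_coeffs)[..., None]

    cube = IVIMCube(data=data, bvals=b)
    if spec.noise_sigma > 0:
        cube = add_rician_noise(cube, spec.noise_sigma, seed=spec.seed)
    return cube, label_map, ParamMaps(valid=valid, **gt)


def add_rician_noise(cube: IVIMCube, sigma: float, seed=0) -> IVIMCube:
    """Corrupt a cube with Rician (magnitude-MRI) noise.

    Each voxel of each b-value image independently becomes
    sqrt((S + n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2); sigma = 0 returns
    an identical copy.  ``seed`` may be an int or a Generator.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return IVIMCube(data=cube.data.copy(), bvals=cube.bvals.copy())
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=cube.data.shape)
    n2 = rng.normal(0.0, sigma, size=cube.data.shape)
    noisy = np.sqrt((cube.data + n1) ** 2 + n2**2)
    return IVIMCube(data=noisy, bvals=cube.bvals.copy())


def tissue_prototypes(tissues: dict | None = None, bvals=DEFAULT_BVALUES) -> dict:
    """Per-class parameter prototypes: the generating D, Dstar, PF plus the
    ADC and slope that the noiseless class decay yields under a b schedule.

    These are the class-mean vectors a perfectly measured cohort would
    report, and the natural inputs to threshold derivation.
    """
    tissues = dict(DEFAULT_TISSUES) if tissues is None else tissues
    b = validate_bvalues(bvals, require_zero=True)
    out = {}
    for name, tp in tissues.items():
        sig = tp.S0 * np.asarray(biexp_signal(tp, b))
        out[name] = {
            "ADC": fit_adc(sig, b),
            "slope": fit_slope(sig, b),
            "D": tp.D,
            "Dstar": tp.Dstar,
            "PF": tp.PF,
        }
    return out


def reference_phantom_spec(noise_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """The 64x64x3 reference phantom: a parenchyma ellipse holding a
    two-zone tumor (central core + peripheral rim) and a cyst.

    ``noise_sigma`` is in signal units; 2.0 corresponds to SNR 50 relative to
    the normal-tissue baseline of 100.
    """
    tumor_center = (22.0, 24.0)
    lesions = (
        Lesion(
            Ellipse(tumor_center, (7.0, 7.0), hole_semi_axes=(3.5, 3.5)),
            tissue="tumor_peripheral",
            name="tumor-rim",
        ),
        Lesion(Ellipse(tumor_center, (3.5, 3.5)), tissue="tumor_central", name="tumor-core"),
        Lesion(Ellipse((42.0, 40.0), (5.0, 5.0)), tissue="cyst", name="cyst"),
    )
    return PhantomSpec(lesions=lesions, noise_sigma=noise_sigma, seed=seed)
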