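"""Mono- and biexponential diffusion signal models and per-pixel IVIM fitting.

The intravoxel incoherent motion (IVIM) model describes the diffusion-weighted
MRI signal of perfused tissue as a mixture of slow tissue-water diffusion and
fast capillary pseudodiffusion:

    S_b / S_0 = (1 - PF) * exp(-b * D) + PF * exp(-b * D*)

where ``b`` is the diffusion weighting (s/mm^2), ``D`` the pure diffusion
coefficient, ``D*`` the pseudodiffusion coefficient and ``PF`` the perfusion
fraction.  Diffusivities are stored in units of 1e-3 mm^2/s throughout, the
convention used in clinical tables.

The monoexponential apparent diffusion coefficient (ADC) is the negated
log-linear decay rate of the same signal; on biexponential data the perfusion
term inflates the ADC above D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "DIFF_SCALE",
    "TissueParams",
    "BValueSeries",
    "IVIMCube",
    "IVIMFitResult",
    "ParamMaps",
    "FitBounds",
    "biexp_signal",
    "adc_two_point",
    "fit_adc",
    "fit_slope",
    "fit_ivim",
    "compute_param_maps",
]

#: diffusivities are expressed in 1e-3 mm^2/s; b-values in s/mm^2
DIFF_SCALE = 1.0e-3

#: type alias: an ordered, strictly increasing 1-D array of b-values (s/mm^2)
BValueSeries = np.ndarray


@dataclass(frozen=True)
class TissueParams:
    """IVIM parameters of one tissue.

    D and Dstar are in 1e-3 mm^2/s; PF is a fraction in [0, 1]; S0 is the
    unit-free baseline signal amplitude at b = 0.
    """

    D: float
    Dstar: float
    PF: float
    S0: float = 1.0

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if not (0.0 <= self.PF <= 1.0):
            raise ValueError(f"PF must lie in [0, 1], got {self.PF}")
        if self.S0 <= 0:
            raise ValueError(f"S0 must be positive, got {self.S0}")
        if self.Dstar < self.D:
            warnings.warn(
                f"Dstar ({self.Dstar}) < D ({self.D}): pseudodiffusion is "
                "normally faster than tissue diffusion",
                stacklevel=2,
            )


def validate_bvalues(bvals, *, require_zero: bool = False, min_len: int = 1) -> np.ndarray:
    """Validate and return a b-value schedule as a float array."""
    b = np.asarray(bvals, dtype=float).ravel()
    if b.size < min_len:
        raise ValueError(f"need at least {min_len} b-values, got {b.size}")
    if np.any(np.diff(b) <= 0):
        raise ValueError("b-values must be strictly increasing")
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    if require_zero and b[0] != 0:
        raise ValueError("first b-value must be 0 for normalized fits")
    return b


@dataclass
class IVIMCube:
    """A multi-b-value DWI stack: ``data[row, col, slice, b_index]``.

    ``bvals`` is the acquisition schedule in s/mm^2, aligned to the last axis.
    """

    data: np.ndarray
    bvals: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"cube must be 4-D (rows, cols, slices, b), got {self.data.ndim}-D")
        self.bvals = validate_bvalues(self.bvals)
        if self.data.shape[3] != self.bvals.size:
            raise ValueError(
                f"cube has {self.data.shape[3]} volumes but schedule lists {self.bvals.size} b-values"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_bands(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the biexponential fit, in 1e-3 mm^2/s (PF unitless).

    Defaults bracket breast tissue classes (tumor, cyst, normal parenchyma)
    with margin.
    """

    D: tuple[float, float] = (0.05, 3.5)
    Dstar: tuple[float, float] = (1.0, 60.0)
    PF: tuple[float, float] = (0.0, 0.6)


@dataclass(frozen=True)
class IVIMFitResult:
    """Per-pixel fit output: ADC/slope from the monoexponential view, D, D*,
    PF from the biexponential fit, plus diagnostics."""

    ADC: float
    slope: float
    D: float
    Dstar: float
    PF: float
    residual_norm: float
    converged: bool


@dataclass
class ParamMaps:
    """Five parametric maps sharing a cube's spatial shape, plus validity.

    Invalid pixels (outside the mask, or failed fits) are flagged in
    ``valid`` and hold NaN in every map — never a silent zero.
    """

    ADC: np.ndarray
    slope: np.ndarray
    D: np.ndarray
    Dstar: np.ndarray
    PF: np.ndarray
    valid: np.ndarray

    PARAM_NAMES = ("ADC", "slope", "D", "Dstar", "PF")

    def __post_init__(self) -> None:
        shape = self.ADC.shape
        for name in self.PARAM_NAMES:
            if getattr(self, name).shape != shape:
                raise ValueError("all parameter maps must share one spatial shape")
        if self.valid.shape != shape:
            raise ValueError("validity mask shape mismatch")

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.PARAM_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def biexp_signal(params: TissueParams, b) -> np.ndarray | float:
    """Relative signal S_b/S_0 of the biexponential IVIM model.

    ``b`` may be a scalar or array of b-values (s/mm^2).
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    s = (1.0 - params.PF) * np.exp(-b * params.D * DIFF_SCALE) + params.PF * np.exp(
        -b * params.Dstar * DIFF_SCALE
    )
    return float(s) if s.ndim == 0 else s


def _biexp_rel(b: np.ndarray, D: float, Dstar: float, PF: float) -> np.ndarray:
    return (1.0 - PF) * np.exp(-b * D * DIFF_SCALE) + PF * np.exp(-b * Dstar * DIFF_SCALE)


def adc_two_point(S_b1: float, S_b2: float, b1: float, b2: float) -> float:
    """Two-point monoexponential ADC, in 1e-3 mm^2/s.

    ADC = -ln(S_b1 / S_b2) / (b1 - b2).
    """
    if b1 == b2:
        raise ValueError("b1 and b2 must differ")
    if S_b1 <= 0 or S_b2 <= 0:
        raise ValueError("signals must be positive for a log-ratio ADC")
    return -np.log(S_b1 / S_b2) / (b1 - b2) / DIFF_SCALE


def _check_signals(sig: np.ndarray, b: np.ndarray) -> None:
    bad = b[sig <= 0]
    if bad.size:
        raise ValueError(f"nonpositive signal at b = {bad.tolist()}; log fits require S > 0")


def fit_adc(sig, bvals) -> float:
    """Log-linear least-squares ADC over all b-values, in 1e-3 mm^2/s.

    Fits ln(S) = ln(S0) - b * ADC with an intercept, so the estimate is
    invariant to a global rescaling of the signal.  Exact on noiseless
    monoexponential input.
    """
    b = validate_bvalues(bvals, min_len=2)
    sig = np.asarray(sig, dtype=float).ravel()
    if sig.size != b.size:
        raise ValueError("signal and b-value series lengths differ")
    _check_signals(sig, b)
    A = np.column_stack([b, np.ones_like(b)])
    coef, *_ = np.linalg.lstsq(A, np.log(sig), rcond=None)
    return -coef[0] / DIFF_SCALE


def fit_slope(sig, bvals) -> float:
    """Least-squares slope of the normalized signal S_b/S_0 versus b/1000.

    A dimensionless decay index of order 0.1-1 for breast tissue; the 1000
    s/mm^2 scaling makes it comparable across b schedules.
    """
    b = validate_bvalues(bvals, min_len=2)
    sig = np.asarray(sig, dtype=float).ravel()
    if sig.size != b.size:
        raise ValueError("signal and b-value series lengths differ")
    _check_signals(sig, b)
    y = sig / sig[0]
    A = np.column_stack([b / 1000.0, np.ones_like(b)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0])


def _segmented_init(y: np.ndarray, b: np.ndarray, b_split: float, bounds: FitBounds):
    """Segmented estimate (D from high b, PF from the intercept deficit,
    D* from a bounded 1-D search) used alone or as the full-fit start."""
    high = b >= b_split
    if high.sum() < 2:
        raise ValueError(f"fewer than 2 b-values at or above b_split={b_split}")
    A = np.column_stack([b[high], np.ones(high.sum())])
    coef, *_ = np.linalg.lstsq(A, np.log(y[high]), rcond=None)
    D = float(np.clip(-coef[0] / DIFF_SCALE, *bounds.D))
    PF = float(np.clip(1.0 - np.exp(coef[1]), *bounds.PF))

    def sse_dstar(ds: float) -> float:
        r = y - _biexp_rel(b, D, ds, PF)
        return float(r @ r)

    res = minimize_scalar(sse_dstar, bounds=bounds.Dstar, method="bounded")
    Dstar = float(res.x)
    return D, Dstar, PF, bool(res.success)


def fit_ivim(
    sig,
    bvals,
    method: str = "full",
    b_split: float = 250.0,
    bounds: FitBounds = FitBounds(),
) -> IVIMFitResult:
    """Fit the biexponential IVIM model to one signal series.

    ``method='segmented'`` uses the classic two-step estimator: log-linear D
    on b >= ``b_split`` (where the pseudodiffusion term has decayed), PF from
    the extrapolated intercept deficit, then a bounded 1-D search for D* on
    the full curve.  ``method='full'`` (default) refines all three parameters
    jointly by bounded nonlinear least squares started from the segmented
    estimate.  ADC and slope are always computed from the monoexponential
    view of the same series.

    Non-convergence is reported through the ``converged`` flag, not raised.
    """
    if method not in ("segmented", "full"):
        raise ValueError(f"unknown method {method!r}")
    b = validate_bvalues(bvals, require_zero=True, min_len=3)
    sig = np.asarray(sig, dtype=float).ravel()
    if sig.size != b.size:
        raise ValueError("signal and b-value series lengths differ")
    _check_signals(sig, b)
    y = sig / sig[0]

    adc = fit_adc(sig, b)
    slope = fit_slope(sig, b)
    D, Dstar, PF, converged = _segmented_init(y, b, b_split, bounds)

    if method == "full":
        lo = np.array([bounds.D[0], bounds.Dstar[0], bounds.PF[0]])
        hi = np.array([bounds.D[1], bounds.Dstar[1], bounds.PF[1]])
        x0 = np.clip([D, Dstar, PF], lo, hi)

        def resid(x):
            return _biexp_rel(b, *x) - y

        def jac(x):
            d, ds, pf = x
            ed = np.exp(-b * d * DIFF_SCALE)
            es = np.exp(-b * ds * DIFF_SCALE)
            return np.column_stack(
                [
                    -(1.0 - pf) * b * DIFF_SCALE * ed,
                    -pf * b * DIFF_SCALE * es,
                    es - ed,
                ]
            )

        res = least_squares(resid, x0, jac=jac, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        D, Dstar, PF = (float(v) for v in res.x)
        converged = bool(res.success)

    r = y - _biexp_rel(b, D, Dstar, PF)
    return IVIMFitResult(
        ADC=adc,
        slope=slope,
        D=D,
        Dstar=Dstar,
        PF=PF,
        residual_norm=float(np.linalg.norm(r)),
        converged=converged,
    )


def compute_param_maps(
    cube: IVIMCube,
    mask: np.ndarray,
    method: str = "full",
    b_split: float = 250.0,
    bounds: FitBounds = FitBounds(),
) -> ParamMaps:
    """Fit every masked pixel of a cube and return five parametric maps.

    Pixels whose signal violates fit preconditions (nonpositive values) are
    flagged invalid rather than aborting the map.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube spatial shape")
    if not mask.any():
        raise ValueError("empty mask: nothing to fit")

    shape = cube.spatial_shape
    maps = {name: np.full(shape, np.nan) for name in ParamMaps.PARAM_NAMES}
    valid = np.zeros(shape, dtype=bool)

    idx = np.argwhere(mask)
    for r, c, s in idx:
        sig = cube.data[r, c, s, :]
        if np.any(sig <= 0):
            continue
        try:
            fit = fit_ivim(sig, cube.bvals, method=method, b_split=b_split, bounds=bounds)
        except ValueError:
            continue
        if not fit.converged:
            continue
        maps["ADC"][r, c, s] = fit.ADC
        maps["slope"][r, c, s] = fit.slope
        maps["D"][r, c, s] = fit.D
        maps["Dstar"][r, c, s] = fit.Dstar
        maps["PF"][r, c, s] = fit.PF
        valid[r, c, s] = fit.converged

    return ParamMaps(valid=valid, **maps)
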