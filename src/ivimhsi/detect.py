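"""Unsupervised target generation and constrained-energy-minimization detection.

Operates on an expanded band cube viewed as N pixel vectors of length M:

* **ATGP** (automatic target generation process) picks the brightest pixel,
  then repeatedly projects the data onto the orthogonal complement of the
  targets found so far and picks the pixel with the largest residual — a
  sequence of maximally spectrally distinct candidate targets.
* **SAM** (spectral angle mapper) measures similarity between two spectra as
  the angle between them; it is used to gather training pixels around each
  ATGP target.
* **CEM** (constrained energy minimization) designs the FIR filter w that
  minimizes average output energy w'Rw subject to w'd = 1 for a desired
  signature d; its closed form is w = R^{-1} d / (d' R^{-1} d) with R the
  sample correlation matrix.  **KCEM** is the same detector in a kernel
  feature space, evaluated via the kernel trick on a background sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

from ivimhsi.bep import BandCube

__all__ = [
    "TargetSet",
    "KernelSpec",
    "osp_projector",
    "atgp",
    "sam",
    "select_training_samples",
    "correlation_matrix",
    "cem",
    "kcem",
    "rbf_kernel",
    "detect_lesions",
]


def _as_pixel_matrix(cube) -> tuple[np.ndarray, tuple | None]:
    """Return (N, M) pixel matrix and the source spatial shape if known."""
    if isinstance(cube, BandCube):
        return cube.pixels(), cube.data.shape[:3]
    arr = np.asarray(cube, dtype=float)
    if arr.ndim == 2:
        return arr, None
    if arr.ndim == 4:
        return arr.reshape(-1, arr.shape[3]), arr.shape[:3]
    raise ValueError("expected a BandCube, an (N, M) matrix or a 4-D cube")


@dataclass
class TargetSet:
    """Ordered ATGP targets: signatures (k, M), flat pixel indices, and the
    stopping rule that produced them."""

    signatures: np.ndarray
    indices: np.ndarray
    spatial_shape: tuple | None = None
    stop_reason: str = "n_targets"

    def __len__(self) -> int:
        return self.signatures.shape[0]

    def spatial_indices(self) -> np.ndarray:
        if self.spatial_shape is None:
            raise ValueError("targets were built from a flat matrix; no spatial shape")
        return np.column_stack(np.unravel_index(self.indices, self.spatial_shape))


def osp_projector(U: np.ndarray) -> np.ndarray:
    """Orthogonal-subspace projector P = I - U (U'U)^{-1} U'.

    P is symmetric, idempotent and annihilates the columns of U.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if U.ndim != 2:
        raise ValueError("U must be a 2-D matrix of column signatures")
    if np.linalg.matrix_rank(U) < U.shape[1]:
        raise ValueError("U is rank-deficient; remove linearly dependent targets")
    G = U.T @ U
    return np.eye(U.shape[0]) - U @ np.linalg.solve(G, U.T)


def atgp(
    cube,
    n_targets: int | None = 5,
    epsilon: float | None = None,
    measure=None,
) -> TargetSet:
    """Automatic target generation process.

    The first target is the maximum-norm (brightest) pixel; each subsequent
    target maximizes the squared norm of its projection onto the orthogonal
    complement of all previous targets.  Stops after ``n_targets`` targets,
    or earlier when ``measure(t_prev, t_new) <= epsilon`` (the triggering
    target is discarded).  ``measure`` defaults to :func:`sam`.
    """
    X, spatial_shape = _as_pixel_matrix(cube)
    N = X.shape[0]
    if n_targets is None and epsilon is None:
        raise ValueError("provide n_targets and/or (epsilon, measure)")
    if n_targets is not None and n_targets > N:
        raise ValueError(f"n_targets={n_targets} exceeds pixel count {N}")
    norms2 = np.einsum("ij,ij->i", X, X)
    if norms2.max() == 0:
        raise ValueError("all-zero cube: no brightest pixel")
    if measure is None:
        measure = sam

    idx = [int(np.argmax(norms2))]
    stop_reason = "n_targets"
    while True:
        if n_targets is not None and len(idx) >= n_targets:
            break
        U = X[idx, :].T
        P = osp_projector(U)
        scores = np.einsum("ij,ij->i", X @ P, X)  # ||P r||^2, P idempotent+symmetric
        scores[idx] = -np.inf
        cand = int(np.argmax(scores))
        if scores[cand] <= 1e-10 * norms2.max():
            # remaining pixels lie in the span of the targets found so far
            stop_reason = "span_exhausted"
            break
        if epsilon is not None and measure(X[idx[-1]], X[cand]) <= epsilon:
            stop_reason = "epsilon"
            break
        idx.append(cand)
    return TargetSet(
        signatures=X[idx, :].copy(),
        indices=np.asarray(idx),
        spatial_shape=spatial_shape,
        stop_reason=stop_reason,
    )


def sam(s, t) -> float:
    """Spectral angle between two vectors, in radians.

    arccos of the normalized inner product; scale-invariant and symmetric.
    """
    s = np.asarray(s, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    ns, nt = np.linalg.norm(s), np.linalg.norm(t)
    if ns == 0 or nt == 0:
        raise ValueError("spectral angle is undefined for a zero vector")
    return float(np.arccos(np.clip(s @ t / (ns * nt), -1.0, 1.0)))


def _sam_to_all(X: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Angles from every row of X to t; zero rows map to pi (maximal)."""
    nt = np.linalg.norm(t)
    nx = np.linalg.norm(X, axis=1)
    cosv = np.zeros(X.shape[0])
    nz = nx > 0
    cosv[nz] = (X[nz] @ t) / (nx[nz] * nt)
    ang = np.arccos(np.clip(cosv, -1.0, 1.0))
    ang[~nz] = np.pi
    return ang


def select_training_samples(cube, targets: TargetSet, angle_threshold: float):
    """Gather, for each ATGP target, the pixels within a SAM angle of it.

    Returns a list of ``(indices, mean_signature)`` pairs; the mean signature
    is the desired-signature d fed to CEM/KCEM.  A target whose neighborhood
    is empty falls back (with a warning) to the singleton {target}.
    """
    if angle_threshold <= 0:
        raise ValueError("angle_threshold must be positive")
    X, _ = _as_pixel_matrix(cube)
    out = []
    for k in range(len(targets)):
        t = targets.signatures[k]
        ang = _sam_to_all(X, t)
        sel = np.flatnonzero(ang <= angle_threshold)
        if sel.size == 0:
            warnings.warn(f"no pixels within {angle_threshold} rad of target {k}; using the target alone")
            sel = np.asarray([targets.indices[k]])
        out.append((sel, X[sel].mean(axis=0)))
    return out


def correlation_matrix(cube) -> np.ndarray:
    """Sample correlation matrix R = (1/N) sum_i r_i r_i' of all pixels."""
    X, _ = _as_pixel_matrix(cube)
    return X.T @ X / X.shape[0]


def _auto_ridge(trace: float, dim: int) -> float:
    return 1e-6 * trace / dim


def cem(cube, d, ridge="auto") -> np.ndarray:
    """Constrained energy minimization detection map.

    Output at pixel r is d'(R + ridge I)^{-1} r / (d'(R + ridge I)^{-1} d),
    so a pixel equal to d scores exactly 1.  ``ridge='auto'`` uses the
    scale-free default 1e-6 * trace(R)/M; ``ridge=0`` requires R to be
    well conditioned.
    """
    X, spatial_shape = _as_pixel_matrix(cube)
    d = np.asarray(d, dtype=float).ravel()
    M = X.shape[1]
    if d.size != M or not np.any(d):
        raise ValueError("desired signature must be nonzero with one entry per band")
    R = correlation_matrix(X)
    rho = _auto_ridge(np.trace(R), M) if ridge == "auto" else float(ridge)
    Rr = R + rho * np.eye(M)
    if rho == 0 and np.linalg.cond(Rr) > 1e12:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular or near-singular; pass ridge > 0 (or ridge='auto')"
        )
    w = np.linalg.solve(Rr, d)
    out = (X @ w) / (d @ w)
    return out.reshape(spatial_shape) if spatial_shape is not None else out


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice for KCEM: 'linear', or 'rbf' with bandwidth sigma
    ('auto' = median pairwise distance of a seeded 500-pixel subsample)."""

    name: str = "rbf"
    sigma: float | str = "auto"

    def __post_init__(self) -> None:
        if self.name not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.name == "rbf" and self.sigma != "auto" and not self.sigma > 0:
            raise ValueError("rbf sigma must be positive")


def rbf_kernel(x, y, sigma: float) -> float:
    """Gaussian RBF kernel exp(-||x - y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, spec: KernelSpec, sigma: float) -> np.ndarray:
    if spec.name == "linear":
        return A @ B.T
    d2 = cdist(A, B, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def median_heuristic_sigma(X: np.ndarray, seed=0, n_sample: int = 500) -> float:
    """Median pairwise Euclidean distance of a seeded pixel subsample."""
    rng = np.random.default_rng(seed)
    if X.shape[0] > n_sample:
        X = X[rng.choice(X.shape[0], n_sample, replace=False)]
    d = cdist(X, X)
    d = d[np.triu_indices_from(d, k=1)]
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def kcem(
    cube,
    d,
    kernel: KernelSpec = KernelSpec(),
    ridge="auto",
    background_subsample: int = 2000,
    seed=0,
    chunk: int = 4096,
) -> np.ndarray:
    """Kernel CEM detection map.

    The CEM filter is formed in the kernel feature space over a background
    sample B of up to ``background_subsample`` pixels (all pixels when the
    cube is small enough; a seeded uniform subsample otherwise).  With
    K the Gram matrix of B, regularized correlation R = K-features/n + ridge I,
    the response is evaluated through the matrix-inversion lemma as

        delta(r) = [k(d,r) - k_d' (n*ridge I + K)^{-1} k_r] /
                   [k(d,d) - k_d' (n*ridge I + K)^{-1} k_d]

    which is normalized so delta(d) = 1 and, for the linear kernel with the
    full background, coincides with :func:`cem` at the same ridge.
    """
    X, spatial_shape = _as_pixel_matrix(cube)
    d = np.asarray(d, dtype=float).ravel()
    N, M = X.shape
    if d.size != M or not np.any(d):
        raise ValueError("desired signature must be nonzero with one entry per band")

    rng = np.random.default_rng(seed)
    if N > background_subsample:
        bg_idx = np.sort(rng.choice(N, background_subsample, replace=False))
        B = X[bg_idx]
    else:
        B = X
    n = B.shape[0]

    sigma = 1.0
    if kernel.name == "rbf":
        sigma = (
            median_heuristic_sigma(X, seed=seed) if kernel.sigma == "auto" else float(kernel.sigma)
        )

    K = _kernel_matrix(B, B, kernel, sigma)
    rho = _auto_ridge(np.trace(K) / n, M) if ridge == "auto" else float(ridge)
    if rho <= 0:
        raise ValueError("kcem requires ridge > 0 (the feature-space correlation is rank-deficient)")
    try:
        cf = cho_factor(K + n * rho * np.eye(n), lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized Gram matrix is not positive definite; increase ridge"
        ) from exc

    k_d = _kernel_matrix(B, d[None, :], kernel, sigma).ravel()
    alpha = cho_solve(cf, k_d)
    k_dd = _kernel_matrix(d[None, :], d[None, :], kernel, sigma).item()
    denom = k_dd - k_d @ alpha
    if denom <= 0:
        raise np.linalg.LinAlgError("degenerate KCEM denominator; increase ridge")

    out = np.empty(N)
    for start in range(0, N, chunk):
        xs = X[start : start + chunk]
        k_dr = _kernel_matrix(xs, d[None, :], kernel, sigma).ravel()
        k_r = _kernel_matrix(B, xs, kernel, sigma)
        out[start : start + chunk] = (k_dr - alpha @ k_r) / denom
    return out.reshape(spatial_shape) if spatial_shape is not None else out


def detect_lesions(
    band_cube,
    n_targets: int = 5,
    angle_threshold: float = 0.05,
    kernel: KernelSpec = KernelSpec(),
    ridge="auto",
    background_subsample: int = 2000,
    seed=0,
):
    """End-to-end unsupervised detection: ATGP targets -> SAM training
    samples -> per-target KCEM maps merged by pixelwise maximum.

    Returns ``(merged_map, per_target_maps, targets)``.
    """
    targets = atgp(band_cube, n_targets=n_targets)
    samples = select_training_samples(band_cube, targets, angle_threshold)
    maps = [
        kcem(
            band_cube,
            d_mean,
            kernel=kernel,
            ridge=ridge,
            background_subsample=background_subsample,
            seed=seed,
        )
        for _, d_mean in samples
    ]
    merged = np.maximum.reduce(maps)
    return merged, maps, targets
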