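"""Band expansion process (BEP): grow an L-band cube into correlated bands.

A multi-b-value DWI stack carries too few bands for hyperspectral subpixel
analysis.  The BEP manufactures additional bands as nonlinear functions of
the originals — elementwise auto-correlation (B_l^2), cross-correlation
(B_k B_l), optional third-order products, and optional square-root and
logarithmic stretches — so that detectors operating on spectral vectors see
second- (and third-) order statistics of the signal decay, not just the raw
decay.  A 12-band cube expanded with second-order auto and cross terms yields
12 + 12 + 66 = 90 bands.

Band order is deterministic and recorded in a manifest: originals, auto
(ascending l), pairwise cross (lexicographic k < l), then for order 3 cubes,
squared-cross (B_k^2 B_l, k != l), triple cross (k < l < m), then sqrt and
log stretches.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from ivimhsi.ivim_model import IVIMCube

__all__ = ["BandCube", "band_count", "band_manifest", "expand_bands"]


@dataclass
class BandCube:
    """An expanded cube ``data[row, col, slice, band]`` with provenance.

    Each manifest entry is a ``(tag, indices)`` pair, e.g. ``("cross", (0, 5))``
    for the elementwise product of original bands 0 and 5; ``("cross2", (k, l))``
    is B_k^2 * B_l.  Indices are 0-based into the original cube.
    """

    data: np.ndarray
    manifest: tuple
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("band cube must be 4-D")
        if self.data.shape[3] != len(self.manifest):
            raise ValueError("manifest length must equal band count")

    @property
    def n_bands(self) -> int:
        return self.data.shape[3]

    def pixels(self) -> np.ndarray:
        """Flatten to an (N, M) matrix of pixel spectral vectors."""
        return self.data.reshape(-1, self.n_bands)


def band_manifest(
    L: int, order: int = 2, include_sqrt: bool = False, include_log: bool = False
) -> tuple:
    """Enumerate the (tag, indices) manifest expand_bands would emit."""
    if L < 1:
        raise ValueError("need at least one band")
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    entries = [("original", (l,)) for l in range(L)]
    if order >= 2:
        entries += [("auto", (l,)) for l in range(L)]
        entries += [("cross", kl) for kl in combinations(range(L), 2)]
    if order >= 3:
        entries += [("cube", (l,)) for l in range(L)]
        entries += [("cross2", (k, l)) for k in range(L) for l in range(L) if k != l]
        entries += [("cross3", klm) for klm in combinations(range(L), 3)]
    if include_sqrt:
        entries += [("sqrt", (l,)) for l in range(L)]
    if include_log:
        entries += [("log", (l,)) for l in range(L)]
    return tuple(entries)


def band_count(
    L: int, order: int = 2, include_sqrt: bool = False, include_log: bool = False
) -> int:
    """Closed-form number of bands the expansion emits.

    order 1: L; order 2 adds L auto + C(L,2) cross; order 3 further adds
    L cubes + L(L-1) squared-cross + C(L,3) triple-cross; each stretch adds L.
    """
    if L < 1:
        raise ValueError("need at least one band")
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    n = L
    if order >= 2:
        n += L + comb(L, 2)
    if order >= 3:
        n += L + L * (L - 1) + comb(L, 3)
    if include_sqrt:
        n += L
    if include_log:
        n += L
    return n


def expand_bands(
    cube,
    order: int = 2,
    include_sqrt: bool = False,
    include_log: bool = False,
    normalize: bool = False,
    log_offset: bool = True,
) -> BandCube:
    """Expand an L-band cube into its correlated band images.

    ``cube`` may be an :class:`~ivimhsi.ivim_model.IVIMCube` or a 4-D array.
    With ``normalize`` each correlated band is divided by the product of its
    source bands' standard deviations.  The log stretch uses log(1 + x) on
    nonnegative data unless ``log_offset`` is disabled, in which case strictly
    positive pixels are required.
    """
    data = cube.data if isinstance(cube, IVIMCube) else np.asarray(cube, dtype=float)
    if data.ndim != 4:
        raise ValueError("cube must be 4-D (rows, cols, slices, bands)")
    L = data.shape[3]
    manifest = band_manifest(L, order, include_sqrt, include_log)

    if include_sqrt and np.any(data < 0):
        raise ValueError("sqrt stretch requires nonnegative pixel values")
    if include_log:
        if log_offset:
            if np.any(data < 0):
                raise ValueError("log(1+x) stretch requires nonnegative pixel values")
        elif np.any(data <= 0):
            raise ValueError("log stretch without offset requires strictly positive pixels")

    std = data.reshape(-1, L).std(axis=0)
    std = np.where(std > 0, std, 1.0)  # constant bands: skip normalization

    out = np.empty(data.shape[:3] + (len(manifest),), dtype=float)
    for j, (tag, idx) in enumerate(manifest):
        if tag == "original":
            band = data[..., idx[0]]
            scale = 1.0
        elif tag == "auto":
            band = data[..., idx[0]] ** 2
            scale = std[idx[0]] ** 2
        elif tag == "cross":
            k, l = idx
            band = data[..., k] * data[..., l]
            scale = std[k] * std[l]
        elif tag == "cube":
            band = data[..., idx[0]] ** 3
            scale = std[idx[0]] ** 3
        elif tag == "cross2":
            k, l = idx
            band = data[..., k] ** 2 * data[..., l]
            scale = std[k] ** 2 * std[l]
        elif tag == "cross3":
            k, l, m = idx
            band = data[..., k] * data[..., l] * data[..., m]
            scale = std[k] * std[l] * std[m]
        elif tag == "sqrt":
            band = np.sqrt(data[..., idx[0]])
            scale = 1.0
        elif tag == "log":
            band = np.log1p(data[..., idx[0]]) if log_offset else np.log(data[..., idx[0]])
            scale = 1.0
        out[..., j] = band / scale if (normalize and scale != 1.0) else band
    return BandCube(data=out, manifest=manifest, normalized=normalize)
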