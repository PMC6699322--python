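"""Convert real-valued detection maps into binary lesion masks.

Two automatic thresholders over a quantized gray-level image:

* **Local entropy**: builds the symmetric gray-level co-occurrence matrix
  over horizontal and vertical 4-neighbor pairs; for a candidate threshold t
  the matrix splits into quadrants, and the criterion is the Shannon entropy
  of the background-background quadrant plus that of the
  foreground-foreground quadrant, each renormalized to a probability mass of
  one.  The threshold maximizing this within-class co-occurrence entropy is
  returned.
* **Otsu**: maximizes the between-class variance of the gray-level histogram.

Foreground is values strictly above the threshold (lesions have high
detector response); argmax ties break toward the smaller threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantizedImage",
    "quantize",
    "cooccurrence_matrix",
    "local_entropy_threshold",
    "otsu_threshold",
]


@dataclass
class QuantizedImage:
    """Integer gray levels in [0, G-1] plus the source range for inverse
    mapping of a chosen level back to detector units."""

    levels: np.ndarray
    G: int
    source_min: float
    source_max: float

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError("need at least two gray levels")
        if self.levels.min() < 0 or self.levels.max() > self.G - 1:
            raise ValueError("levels out of range")

    def level_to_value(self, level: float) -> float:
        return self.source_min + (self.source_max - self.source_min) * level / (self.G - 1)


def quantize(detection_map: np.ndarray, G: int = 256) -> QuantizedImage:
    """Linear min-max quantization of a real-valued map to {0..G-1}.

    Order-preserving; a constant map has no histogram structure and is an
    error.
    """
    arr = np.asarray(detection_map, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("degenerate histogram: constant map cannot be quantized")
    levels = np.floor((arr - lo) / (hi - lo) * (G - 1) + 0.5).astype(np.int64)
    return QuantizedImage(levels=levels, G=G, source_min=lo, source_max=hi)


def _as_quantized(img) -> QuantizedImage:
    if isinstance(img, QuantizedImage):
        return img
    arr = np.asarray(img)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError("expected a QuantizedImage or an integer array")
    return QuantizedImage(levels=arr, G=int(arr.max()) + 1 if arr.max() > 0 else 2,
                          source_min=float(arr.min()), source_max=float(arr.max()))


def cooccurrence_matrix(img) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts over horizontal and vertical
    neighbor pairs, pooled across slices for 3-D input."""
    q = _as_quantized(img)
    lv = q.levels
    if lv.ndim == 2:
        lv = lv[:, :, None]
    if lv.ndim != 3:
        raise ValueError("expected a 2-D or 3-D image")
    G = q.G
    C = np.zeros((G, G), dtype=np.int64)
    for a, b in [(lv[:-1, :, :], lv[1:, :, :]), (lv[:, :-1, :], lv[:, 1:, :])]:
        np.add.at(C, (a.ravel(), b.ravel()), 1)
    return C + C.T  # count both directions


def _quadrant_entropy(C: np.ndarray, t: int) -> float:
    """Sum of renormalized Shannon entropies of the background (<= t) and
    foreground (> t) diagonal quadrants of a co-occurrence matrix."""
    h = 0.0
    for q in (C[: t + 1, : t + 1], C[t + 1 :, t + 1 :]):
        s = q.sum()
        if s > 0:
            p = q[q > 0] / s
            h += float(-(p * np.log2(p)).sum())
    return h


def local_entropy_threshold(img) -> tuple[int, np.ndarray]:
    """Co-occurrence local-entropy threshold.

    Returns ``(t, mask)`` where t maximizes the within-quadrant entropy sum
    (smallest t on ties) and ``mask = levels > t``.
    """
    q = _as_quantized(img)
    C = cooccurrence_matrix(q)
    if (C > 0).sum() <= 1:
        raise ValueError("degenerate co-occurrence matrix: a single occupied cell")
    lo, hi = int(q.levels.min()), int(q.levels.max())
    if lo == hi:
        raise ValueError("constant image has no threshold")
    ts = np.arange(lo, hi)  # t = hi would make foreground empty
    scores = np.array([_quadrant_entropy(C, t) for t in ts])
    t = int(ts[np.argmax(scores)])
    return t, q.levels > t


def otsu_threshold(img) -> tuple[int, np.ndarray]:
    """Otsu threshold maximizing between-class variance of the histogram.

    Returns ``(t, mask)`` with the smallest maximizing t and
    ``mask = levels > t``.
    """
    q = _as_quantized(img)
    lo, hi = int(q.levels.min()), int(q.levels.max())
    if lo == hi:
        raise ValueError("constant image has no threshold")
    hist = np.bincount(q.levels.ravel(), minlength=q.G).astype(float)
    p = hist / hist.sum()
    levels = np.arange(q.G, dtype=float)
    omega = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_total = mu[-1]
    ts = np.arange(lo, hi)
    w0 = omega[ts]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_total * w0 - mu[ts]) ** 2 / (w0 * w1)
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    t = int(ts[np.argmax(var_between)])
    return t, q.levels > t
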