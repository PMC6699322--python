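"""Automatic breast-region extraction from a single DWI slice.

The extraction chain: Laplacian high-pass sharpening to enhance the body
boundary, Sobel gradient for the contour, optional sternum/midline exclusion,
Otsu binarization, a 2x2 morphological opening to detach thin bridges,
retention of the largest 8-connected component, hole filling, and a final
Sobel edge pass to produce the silhouette contour.

Also provides integer-shift alignment across b-value volumes (maximizing
normalized cross-correlation over small shifts), a pragmatic stand-in for
full inter-volume registration.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from ivimhsi.ivim_model import IVIMCube
from ivimhsi.threshold import otsu_threshold, quantize

__all__ = ["extract_breast_region", "integer_align"]


def extract_breast_region(
    slice_image: np.ndarray,
    sternum_exclusion: np.ndarray | None = None,
    fill_holes: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the breast/body region of a 2-D slice.

    Returns ``(mask, contour)`` where mask is the largest 8-connected
    foreground component after sharpening, Otsu binarization and a 2x2
    opening, and contour is its Sobel edge image.

    ``sternum_exclusion`` is an optional boolean image of pixels to exclude
    before component analysis (e.g. a hit-or-miss localized sternum or a
    midline band); it is off by default since phantoms carry no sternum.
    """
    img = np.asarray(slice_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D slice")
    if img.max() == img.min():
        raise ValueError("no breast region found: constant slice")

    # Step 1: high-pass boundary enhancement (Laplacian sharpening)
    sharpened = img - ndimage.laplace(img)

    # Step 4: Otsu binarization of the enhanced image (min-max quantized,
    # hence invariant to a constant intensity offset)
    _, binary = otsu_threshold(quantize(sharpened, G=256))
    if sternum_exclusion is not None:
        binary = binary & ~np.asarray(sternum_exclusion, dtype=bool)

    # Step 5: 2x2 opening detaches components joined by 1-pixel bridges
    opened = morphology.opening(binary, footprint=np.ones((2, 2), dtype=bool))
    if not opened.any():
        raise ValueError("no breast region found: empty image after opening")

    # Step 6: keep the largest 8-connected component
    lab = measure.label(opened, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == int(np.argmax(counts))
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)

    # Step 7: silhouette contour
    contour = filters.sobel(mask.astype(float)) > 0
    return mask, contour


def integer_align(cube: IVIMCube, max_shift: int = 5, reference: int = 0) -> IVIMCube:
    """Align each b-value volume to a reference volume by the integer (row,
    col) shift maximizing normalized cross-correlation over +-max_shift."""
    ref = cube.data[..., reference]
    out = cube.data.copy()
    rn = ref - ref.mean()
    for j in range(cube.n_bands):
        if j == reference:
            continue
        vol = cube.data[..., j]
        best, best_shift = -np.inf, (0, 0)
        for dr in range(-max_shift, max_shift + 1):
            for dc in range(-max_shift, max_shift + 1):
                shifted = np.roll(vol, (dr, dc), axis=(0, 1))
                sn = shifted - shifted.mean()
                denom = np.linalg.norm(rn) * np.linalg.norm(sn)
                score = (rn * sn).sum() / denom if denom > 0 else -np.inf
                if score > best:
                    best, best_shift = score, (dr, dc)
        out[..., j] = np.roll(vol, best_shift, axis=(0, 1))
    return IVIMCube(data=out, bvals=cube.bvals.copy())
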