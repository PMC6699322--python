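"""Readers and writers: NIfTI images, b-value sidecars, masks, tables.

Conventions: 0-based indices in (row, col, slice) order; cubes are 4-D NIfTI
with the 4th axis indexing the b-value schedule stored in a JSON sidecar;
masks and label maps are integer 3-D NIfTI; parameter maps are one 3-D NIfTI
per parameter plus a tidy CSV; configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ivimhsi.ivim_model import IVIMCube, ParamMaps

__all__ = [
    "read_ivim_cube",
    "read_dicom_series",
    "write_ivim_cube",
    "read_mask",
    "write_mask",
    "write_label_map",
    "write_param_maps",
    "read_param_maps",
    "write_detection_map",
    "write_label_overlay_png",
]


def _sidecar_path(cube_path: Path, bvals_path=None) -> Path:
    if bvals_path is not None:
        return Path(bvals_path)
    name = cube_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return cube_path.with_name(name[: -len(suffix)] + "_bvals.json")
    return cube_path.with_suffix(".json")


def write_ivim_cube(cube: IVIMCube, path, bvals_path=None) -> None:
    """Write a cube as 4-D NIfTI with its b schedule in a JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(cube.data.astype(np.float64), np.eye(4)), str(path))
    sidecar = _sidecar_path(path, bvals_path)
    sidecar.write_text(json.dumps({"bvals": list(map(float, cube.bvals))}))


def read_ivim_cube(path, bvals_path=None) -> IVIMCube:
    """Read a 4-D NIfTI cube and its b-value sidecar.

    A schedule stored out of order is sorted in memory with the volumes
    permuted consistently; duplicate b-values or a volume-count mismatch are
    errors.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is {data.ndim}-D; expected a 4-D (rows, cols, slices, b) cube")
    sidecar = _sidecar_path(path, bvals_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing b-value sidecar {sidecar}")
    bvals = np.asarray(json.loads(sidecar.read_text())["bvals"], dtype=float)
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"schedule of {bvals.size} b-values for a {data.shape[3]}-volume file"
        )
    if np.unique(bvals).size != bvals.size:
        raise ValueError("duplicate b-values in schedule")
    order = np.argsort(bvals)
    return IVIMCube(data=data[..., order], bvals=bvals[order])


def read_dicom_series(directory) -> IVIMCube:
    """Read a DICOM directory into a cube, one volume per diffusion b-value.

    Files are grouped by their diffusion b-value tag (0018,9087) and, within
    a b-value, stacked by instance number (slice order).  Every b-value must
    contribute the same number of slices.
    """
    import pydicom

    directory = Path(directory)
    groups: dict[float, list] = {}
    for f in sorted(directory.iterdir()):
        if f.is_dir():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if "DiffusionBValue" not in ds:
            raise ValueError(f"{f.name} carries no diffusion b-value tag (0018,9087)")
        groups.setdefault(float(ds.DiffusionBValue), []).append(ds)
    if not groups:
        raise ValueError(f"no readable DICOM files in {directory}")
    bvals = np.array(sorted(groups))
    n_slices = {b: len(v) for b, v in groups.items()}
    if len(set(n_slices.values())) != 1:
        raise ValueError(f"unequal slice counts per b-value: {n_slices}")
    volumes = []
    for b in bvals:
        stack = sorted(groups[b], key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
        volumes.append(np.stack([ds.pixel_array.astype(float) for ds in stack], axis=-1))
    return IVIMCube(data=np.stack(volumes, axis=-1), bvals=bvals)


def write_mask(mask: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.eye(4)), str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_label_map(label_map: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(label_map, dtype=np.int16), np.eye(4)), str(path))


def write_detection_map(detection_map: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(detection_map, dtype=np.float64), np.eye(4)), str(path))


def write_param_maps(maps: ParamMaps, out_dir, label_map: np.ndarray | None = None) -> None:
    """Write each parameter as 3-D NIfTI plus a tidy per-pixel CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ParamMaps.PARAM_NAMES:
        nib.save(nib.Nifti1Image(maps[name].astype(np.float64), np.eye(4)), str(out_dir / f"{name}.nii.gz"))
    write_mask(maps.valid, out_dir / "valid.nii.gz")

    idx = np.argwhere(maps.valid)
    rows = {
        "row": idx[:, 0],
        "col": idx[:, 1],
        "slice": idx[:, 2],
    }
    if label_map is not None:
        rows["label"] = np.asarray(label_map)[tuple(idx.T)]
    for name in ParamMaps.PARAM_NAMES:
        rows[name] = maps[name][tuple(idx.T)]
    pd.DataFrame(rows).to_csv(out_dir / "params.csv", index=False)


#: RGBA overlay colors per label code: red = central tumor, green =
#: peripheral tumor, blue = cyst, yellow = other
_OVERLAY_COLORS = {
    3: (1.0, 0.0, 0.0, 0.9),
    4: (0.0, 0.8, 0.0, 0.9),
    2: (0.2, 0.4, 1.0, 0.7),
    5: (0.9, 0.9, 0.0, 0.5),
}


def write_label_overlay_png(background: np.ndarray, label_slice: np.ndarray, path) -> None:
    """Write one slice as a grayscale image with colored class overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bg = np.asarray(background, dtype=float)
    lo, hi = bg.min(), bg.max()
    gray = (bg - lo) / (hi - lo) if hi > lo else np.zeros_like(bg)
    rgba = np.repeat(gray[:, :, None], 4, axis=2)
    rgba[:, :, 3] = 1.0
    for code, color in _OVERLAY_COLORS.items():
        sel = np.asarray(label_slice) == code
        rgba[sel] = color
    fig, ax = plt.subplots(figsize=(4, 4), dpi=120)
    ax.imshow(rgba, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def read_param_maps(out_dir) -> ParamMaps:
    out_dir = Path(out_dir)
    arrays = {
        name: np.asarray(nib.load(str(out_dir / f"{name}.nii.gz")).dataobj, dtype=float)
        for name in ParamMaps.PARAM_NAMES
    }
    valid = read_mask(out_dir / "valid.nii.gz")
    return ParamMaps(valid=valid, **arrays)
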