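"""Volume and table I/O.

Volumes travel as TIFF stacks (ImageJ-style spacing metadata), NRRD or
MHA/MHD (spacing in the header, via SimpleITK).  Arrays are (z, y, x);
spacing must be isotropic and is stored/read in micrometres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .core import LabelVolume, Volume3D

_SITK_EXT = {".nrrd", ".mha", ".mhd", ".nii"}
_TIFF_EXT = {".tif", ".tiff"}


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume with its spacing metadata; format from the suffix."""
    path = Path(path)
    ext = path.suffix.lower()
    data = volume.data
    if ext in _TIFF_EXT:
        if data.dtype == bool:
            data = data.astype(np.uint8)
        res = 1.0 / volume.spacing
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(res, res),
            metadata={"spacing": volume.spacing, "unit": "um", "axes": "ZYX"},
        )
    elif ext in _SITK_EXT:
        if data.dtype == bool:
            data = data.astype(np.uint8)
        img = sitk.GetImageFromArray(data)
        img.SetSpacing((volume.spacing,) * 3)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format {ext!r}")
    return path


def read_volume(
    path: str | Path,
    expected_kind: str = "grayscale",
    spacing: float | None = None,
) -> Volume3D | LabelVolume:
    """Read a volume, attaching spacing from metadata (or the override).

    ``expected_kind`` is ``"grayscale"`` or ``"labels"``; a labels file must
    contain integral values.  Raises if no spacing can be determined or the
    file is not a clean 3D stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext in _TIFF_EXT:
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) > 1:
                raise ValueError(f"TIFF stack has inconsistent slice shapes: {sorted(shapes)}")
            data = tf.asarray()
            meta_spacing = None
            if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
                meta_spacing = float(tf.imagej_metadata["spacing"])
    elif ext in _SITK_EXT:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        sp = img.GetSpacing()
        if max(sp) - min(sp) > 1e-9 * max(sp):
            raise ValueError(f"anisotropic spacing {sp} is not supported")
        meta_spacing = float(sp[0])
    else:
        raise ValueError(f"unsupported volume format {ext!r}")

    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    final_spacing = spacing if spacing is not None else meta_spacing
    if final_spacing is None:
        raise ValueError(f"{path} carries no spacing metadata; pass spacing explicitly")

    if expected_kind == "labels":
        if not np.issubdtype(data.dtype, np.integer):
            if not np.equal(np.mod(data, 1), 0).all():
                raise ValueError(f"{path}: labels expected but values are not integers")
            data = data.astype(np.int32)
        return LabelVolume(data, final_spacing)
    if expected_kind == "grayscale":
        return Volume3D(data, final_spacing)
    raise ValueError(f"expected_kind must be 'grayscale' or 'labels', got {expected_kind!r}")


def write_json(obj: dict, path: str | Path) -> Path:
    """Deterministic JSON dump (sorted keys, fixed float formatting)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def write_vtk_structured_points(
    path: str | Path,
    spacing_um: float,
    scalars: dict[str, np.ndarray] | None = None,
    vectors: dict[str, np.ndarray] | None = None,
) -> Path:
    """Write fields on a voxel grid as a legacy ASCII VTK structured-points
    file (for ParaView-style visualization of Darcy solutions)."""
    scalars = scalars or {}
    vectors = vectors or {}
    arrays = list(scalars.values()) + [v[0] for v in vectors.values()]
    if not arrays:
        raise ValueError("nothing to write")
    shape = arrays[0].shape
    nz, ny, nx = shape
    path = Path(path)
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\nlcnpipe flow field\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write("ORIGIN 0 0 0\n")
        s = spacing_um
        f.write(f"SPACING {s} {s} {s}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in scalars.items():
            f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            vals = np.nan_to_num(arr, nan=0.0).ravel(order="C")
            np.savetxt(f, vals, fmt="%.6e")
        for name, vec in vectors.items():
            f.write(f"VECTORS {name} float\n")
            flat = np.stack([vec[0], vec[1], vec[2]], axis=-1).reshape(-1, 3)
            np.savetxt(f, np.nan_to_num(flat, nan=0.0), fmt="%.6e")
    return path
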