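"""File formats: NIfTI-1 for 3-D volumes and fields, ``.npz`` for 2-D data.

3-D images, label maps and displacement fields go through nibabel; voxel
spacing is carried in the affine/zooms.  2-D fixtures use a plain ``.npz``
container holding the array plus its spacing, so round-trips preserve both.
Displacement fields are stored with the vector components in the last axis
(NIfTI) or as a leading ``(d, *S)`` axis (``.npz``); units are voxels.
"""

from __future__ import annotations

import hashlib
import json
import subprocess
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import DeformationField, LabelMap, ScalarImage

__all__ = [
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
    "write_manifest",
]

_FIELD_DESCRIP = b"displacement field, voxel units"


def _is_nifti(path: Path) -> bool:
    name = path.name
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _load_nifti(path: Path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, spacing, img.header


def _save_nifti(path: Path, data: np.ndarray, spacing) -> None:
    affine = np.diag(list(spacing[:3]) + [1.0] * (4 - min(3, len(spacing))))
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(spacing) + (1.0,) * (data.ndim - len(spacing)))
    nib.save(img, str(path))


def write_image(path, image: ScalarImage) -> None:
    path = Path(path)
    if _is_nifti(path):
        if image.ndim != 3:
            raise ValueError("NIfTI output is for 3-D images; use .npz for 2-D")
        _save_nifti(path, image.values.astype(np.float64), image.spacing)
    elif path.suffix == ".npz":
        np.savez(path, kind="image", values=image.values, spacing=np.asarray(image.spacing))
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def read_image(path) -> ScalarImage:
    path = Path(path)
    if _is_nifti(path):
        data, spacing, _ = _load_nifti(path)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got {data.ndim}-D in {path.name}")
        return ScalarImage(np.asarray(data, dtype=float), spacing=spacing)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return ScalarImage(z["values"], spacing=tuple(z["spacing"]))
    raise ValueError(f"unsupported image format: {path.name}")


def write_labels(path, labels: LabelMap) -> None:
    path = Path(path)
    if _is_nifti(path):
        if labels.labels.ndim != 3:
            raise ValueError("NIfTI output is for 3-D label maps; use .npz for 2-D")
        _save_nifti(path, labels.labels.astype(np.int32), (1.0, 1.0, 1.0))
    elif path.suffix == ".npz":
        np.savez(path, kind="labels", values=labels.labels)
    else:
        raise ValueError(f"unsupported label format: {path.name}")


def read_labels(path) -> LabelMap:
    path = Path(path)
    if _is_nifti(path):
        data, _, _ = _load_nifti(path)
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            data = z["values"]
    else:
        raise ValueError(f"unsupported label format: {path.name}")
    if data.ndim not in (2, 3):
        raise ValueError(f"label map must be 2-D or 3-D, got {data.ndim}-D")
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=0):
            raise ValueError(f"{path.name} contains non-integer label values")
        arr = rounded.astype(np.int64)
    return LabelMap(arr)


def write_field(path, field: DeformationField) -> None:
    path = Path(path)
    disp = field.displacements
    if _is_nifti(path):
        if len(field.grid_shape) != 3:
            raise ValueError("NIfTI output is for 3-D fields; use .npz for 2-D")
        data = np.moveaxis(disp, 0, -1)  # (*S, d)
        affine = np.eye(4)
        img = nib.Nifti1Image(data.astype(np.float64), affine)
        img.header["descrip"] = _FIELD_DESCRIP
        nib.save(img, str(path))
    elif path.suffix == ".npz":
        np.savez(path, kind="field", field=disp)
    else:
        raise ValueError(f"unsupported field format: {path.name}")


def read_field(path) -> DeformationField:
    path = Path(path)
    if _is_nifti(path):
        data, _, _ = _load_nifti(path)
        if data.ndim != 4:
            raise ValueError(f"expected a 4-D (x,y,z,d) field file, got {data.ndim}-D")
        if data.shape[-1] != 3:
            raise ValueError(
                f"field has {data.shape[-1]} components for 3 spatial axes"
            )
        return DeformationField(np.moveaxis(np.asarray(data, float), -1, 0))
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return DeformationField(z["field"])
    raise ValueError(f"unsupported field format: {path.name}")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _version_string() -> str:
    from . import __version__

    try:
        desc = subprocess.run(
            ["git", "describe", "--always", "--dirty"],
            capture_output=True, text=True, timeout=5,
        )
        if desc.returncode == 0:
            return f"{__version__}+{desc.stdout.strip()}"
    except (OSError, subprocess.SubprocessError):
        pass
    return __version__


def write_manifest(path, config: dict, seed, inputs=()) -> None:
    """Record config, seed, version and input hashes so reruns are auditable."""
    manifest = {
        "config": config,
        "seed": seed,
        "version": _version_string(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
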