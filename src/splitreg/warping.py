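"""Spatial transformation: apply a displacement field to images and labels.

Backward warping: the output at voxel ``x`` samples the moving image at
``x + u(x)``.  Out-of-bounds positions are clamped to the border (replicate),
which avoids injecting zeros that would corrupt local cross-correlation
windows near edges.  The linear mode is differentiable with respect to the
field via :func:`splitreg._engine.grid_sample`.
"""

from __future__ import annotations

import numpy as np

from . import _engine
from .core import DeformationField, LabelMap, ScalarImage

__all__ = ["identity_grid", "warp_image", "warp_labels", "warp_array"]


def identity_grid(shape) -> np.ndarray:
    """Coordinate grid with ``grid[c, x] = x_c`` for every voxel ``x``."""
    shape = tuple(int(n) for n in shape)
    axes = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=0)


def _sample_positions(field: np.ndarray) -> np.ndarray:
    return identity_grid(field.shape[1:]) + field


def warp_array(moving: np.ndarray, field: np.ndarray, interpolation: str = "linear") -> np.ndarray:
    """Warp a plain array by a (d, *S) displacement field."""
    moving = np.asarray(moving, dtype=float)
    field = np.asarray(field, dtype=float)
    if field.shape[1:] != moving.shape:
        raise ValueError(
            f"field grid shape {field.shape[1:]} does not match image shape {moving.shape}"
        )
    if interpolation == "linear":
        out = _engine.grid_sample(moving[None], field[None])
        return out.data[0]
    if interpolation == "nearest":
        pos = _sample_positions(field)
        idx = tuple(
            np.clip(np.rint(pos[a]).astype(np.int64), 0, moving.shape[a] - 1)
            for a in range(moving.ndim)
        )
        return moving[idx]
    raise ValueError(f"unknown interpolation {interpolation!r}")


def warp_image(
    moving: ScalarImage, field: DeformationField, interpolation: str = "linear"
) -> ScalarImage:
    """Resample the moving image along ``x + u(x)`` (the ``I_m∘u`` operation)."""
    out = warp_array(moving.values, field.displacements, interpolation)
    return ScalarImage(out, spacing=moving.spacing)


def warp_labels(labels: LabelMap, field: DeformationField) -> LabelMap:
    """Warp a label map with nearest-neighbor sampling (preserves integrality)."""
    arr = labels.labels
    if field.grid_shape != arr.shape:
        raise ValueError(
            f"field grid shape {field.grid_shape} does not match label shape {arr.shape}"
        )
    pos = _sample_positions(field.displacements)
    idx = tuple(
        np.clip(np.rint(pos[a]).astype(np.int64), 0, arr.shape[a] - 1)
        for a in range(arr.ndim)
    )
    return LabelMap(arr[idx])
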