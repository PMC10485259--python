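"""Loss terms for registration: similarity, smoothness, coupling, composites.

The similarity term is the negative mean of the squared local normalized
cross-correlation (LCC) between the fixed image and the warped moving image,
computed over a centered ``window**d`` neighborhood per voxel.  Windows are
clipped at the image border (local statistics use the actual in-bounds
counts).  Squaring makes the loss invariant to the correlation sign and
bounds it in [-1, 0].

All penalties reduce by means (not sums) over voxels, axes and components so
that the balancing weights ``alpha``, ``beta`` and ``lambda_`` are
resolution-independent.

Every term is implemented on the autodiff engine; the public functions accept
domain types or arrays and return plain floats, while the ``*_t`` variants
operate on engine tensors with an explicit batch axis and are what the
trainer and the variational solver differentiate through.
"""

from __future__ import annotations

import numpy as np

from ._engine import (
    Tensor,
    astensor,
    add,
    box_sum,
    box_sum_array,
    forward_diff,
    grid_sample,
    mul,
    sub,
    tmean,
    tsum,
)
from .core import DeformationField, ScalarImage

__all__ = [
    "local_cross_correlation",
    "smoothness_penalty",
    "coupling_penalty",
    "similarity_subproblem_loss",
    "denoiser_subproblem_loss",
    "joint_objective",
    "lcc_loss_t",
    "smoothness_t",
    "coupling_t",
    "similarity_loss_t",
    "denoiser_loss_t",
]


def _image_array(x) -> np.ndarray:
    if isinstance(x, ScalarImage):
        return x.values
    return np.asarray(x, dtype=float)


def _field_array(x) -> np.ndarray:
    if isinstance(x, DeformationField):
        return x.displacements
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# tensor-level terms (batched: images (B, *S), fields (B, d, *S))
# ---------------------------------------------------------------------------


def lcc_loss_t(a, b, window: int, epsilon: float, spatial_ndim: int) -> Tensor:
    """Negative mean squared local NCC between ``a`` and ``b``."""
    a, b = astensor(a), astensor(b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    spatial = a.shape[a.ndim - spatial_ndim :]
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if any(window > n for n in spatial):
        raise ValueError(f"window {window} exceeds an image axis of shape {spatial}")
    counts = box_sum_array(
        np.ones(spatial, dtype=a.data.dtype), window, spatial_ndim
    )  # in-bounds samples per window
    sa = box_sum(a, window, spatial_ndim)
    sb = box_sum(b, window, spatial_ndim)
    saa = box_sum(mul(a, a), window, spatial_ndim)
    sbb = box_sum(mul(b, b), window, spatial_ndim)
    sab = box_sum(mul(a, b), window, spatial_ndim)
    inv_n = 1.0 / counts
    cross = sub(sab, mul(mul(sa, sb), inv_n))
    var_a = sub(saa, mul(mul(sa, sa), inv_n))
    var_b = sub(sbb, mul(mul(sb, sb), inv_n))
    cc2 = mul(mul(cross, cross), 1.0) / add(mul(var_a, var_b), epsilon)
    return mul(tmean(cc2), -1.0)


def smoothness_t(field, spatial_ndim: int) -> Tensor:
    """Mean squared forward difference over voxels, axes and components."""
    field = astensor(field)
    total = None
    for axis in range(field.ndim - spatial_ndim, field.ndim):
        df = forward_diff(field, axis)
        term = tsum(mul(df, df))
        total = term if total is None else add(total, term)
    return mul(total, 1.0 / (spatial_ndim * field.data.size))


def coupling_t(u, v) -> Tensor:
    u, v = astensor(u), astensor(v)
    if u.shape != v.shape:
        raise ValueError(f"field shapes differ: {u.shape} vs {v.shape}")
    diff = sub(u, v)
    return tmean(mul(diff, diff))


def similarity_loss_t(
    fixed: np.ndarray,
    moving: np.ndarray,
    u,
    v: np.ndarray,
    alpha: float,
    window: int,
    epsilon: float,
) -> Tensor:
    """Similarity sub-problem loss; ``v`` enters as a constant (no gradient)."""
    spatial_ndim = fixed.ndim - 1  # (B, *S)
    warped = grid_sample(moving, u)
    loss = lcc_loss_t(fixed, warped, window, epsilon, spatial_ndim)
    if alpha:
        loss = add(loss, mul(coupling_t(u, np.asarray(v)), alpha))
    return loss


def denoiser_loss_t(v, u: np.ndarray, beta: float, spatial_ndim: int) -> Tensor:
    """Denoising sub-problem loss; ``u`` enters as a constant (no gradient)."""
    loss = coupling_t(v, np.asarray(u))
    if beta:
        loss = add(loss, mul(smoothness_t(v, spatial_ndim), beta))
    return loss


# ---------------------------------------------------------------------------
# public scalar API
# ---------------------------------------------------------------------------


def local_cross_correlation(a, b, window: int = 9, epsilon: float = 1e-5) -> float:
    """L_sim: negative mean squared local NCC; value in [-1, 0]."""
    a, b = _image_array(a), _image_array(b)
    return lcc_loss_t(a, b, window, epsilon, a.ndim).item()


def smoothness_penalty(field) -> float:
    """Mean squared forward-difference magnitude of a displacement field."""
    arr = _field_array(field)
    return smoothness_t(arr, arr.ndim - 1).item()


def coupling_penalty(u, v) -> float:
    """Mean squared difference between two fields (the alpha-coupling term)."""
    return coupling_t(_field_array(u), _field_array(v)).item()


def similarity_subproblem_loss(
    fixed, moving, u, v, alpha: float, window: int = 9, epsilon: float = 1e-5
) -> float:
    fixed, moving = _image_array(fixed), _image_array(moving)
    u, v = _field_array(u), _field_array(v)
    return similarity_loss_t(
        fixed[None], moving[None], u[None], v[None], alpha, window, epsilon
    ).item()


def denoiser_subproblem_loss(u, v, beta: float) -> float:
    u, v = _field_array(u), _field_array(v)
    return denoiser_loss_t(v, u, beta, u.ndim - 1).item()


def joint_objective(
    fixed, moving, phi, lambda_: float, window: int = 9, epsilon: float = 1e-5
) -> float:
    """The monitoring objective L_sim(I_f, I_m∘phi) + lambda * ||grad phi||^2."""
    fixed, moving = _image_array(fixed), _image_array(moving)
    phi = _field_array(phi)
    warped = grid_sample(moving[None], phi[None])
    loss = lcc_loss_t(fixed[None], warped, window, epsilon, fixed.ndim)
    if lambda_:
        loss = add(loss, mul(smoothness_t(phi, phi.ndim - 1), lambda_))
    return loss.item()
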