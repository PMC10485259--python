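"""Network-free solvers for the two decoupled sub-problems.

The quadratic smoothing sub-problem ``min_v mean|v-u|^2 + beta*mean|grad v|^2``
has an exact minimizer per component: the screened-Poisson solve
``(I + beta' * L) v = u`` with the Neumann (zero end difference) graph
Laplacian ``L``.  Because both penalties are means — over ``d*N`` entries for
the coupling and ``d*d*N`` for the smoothness (voxels x axes x components) —
the effective coefficient is ``beta' = beta / d``.  The solve is performed by
DCT-II diagonalization (the Neumann eigenbasis), with a sparse direct solve
available as a cross-check on small grids.

``alternate_variational_solve`` realizes the alternating scheme without any
networks: gradient descent on the similarity sub-problem in ``u``, then the
closed-form smoothing for ``v``.  It serves as a classical mode and as the
oracle for what the learned operators approximate.
"""

from __future__ import annotations

import numpy as np
import scipy.fft
import scipy.sparse
import scipy.sparse.linalg

from ._engine import Tensor
from .core import DeformationField, Hyperparams
from .objectives import joint_objective, similarity_loss_t

__all__ = [
    "closed_form_smooth",
    "closed_form_smooth_direct",
    "alternate_variational_solve",
]


def _field_array(u):
    if isinstance(u, DeformationField):
        return u.displacements, True
    return np.asarray(u, dtype=float), False


def closed_form_smooth(u, beta: float):
    """Exact minimizer of ``coupling_penalty(v, u) + beta * smoothness_penalty(v)``."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    arr, wrap = _field_array(u)
    if beta == 0:
        return DeformationField(arr.copy()) if wrap else arr.copy()
    d = arr.shape[0]
    spatial = arr.shape[1:]
    beta_eff = beta / d
    lam = np.zeros(spatial)
    for a, n in enumerate(spatial):
        freq = 2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n)
        shape = [1] * len(spatial)
        shape[a] = n
        lam = lam + freq.reshape(shape)
    denom = 1.0 + beta_eff * lam
    out = np.empty_like(arr)
    for c in range(d):
        coef = scipy.fft.dctn(arr[c], type=2, norm="ortho")
        out[c] = scipy.fft.idctn(coef / denom, type=2, norm="ortho")
    return DeformationField(out) if wrap else out


def _neumann_laplacian_1d(n: int) -> scipy.sparse.spmatrix:
    main = np.full(n, 2.0)
    main[0] = main[-1] = 1.0
    off = np.full(n - 1, -1.0)
    return scipy.sparse.diags([off, main, off], [-1, 0, 1], format="csr")


def closed_form_smooth_direct(u, beta: float):
    """Sparse direct solve of the same screened-Poisson system (small grids)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    arr, wrap = _field_array(u)
    d = arr.shape[0]
    spatial = arr.shape[1:]
    n_vox = int(np.prod(spatial))
    lap = scipy.sparse.csr_matrix((n_vox, n_vox))
    for a in range(len(spatial)):
        mats = [scipy.sparse.identity(m, format="csr") for m in spatial]
        mats[a] = _neumann_laplacian_1d(spatial[a])
        term = mats[0]
        for m in mats[1:]:
            term = scipy.sparse.kron(term, m, format="csr")
        lap = lap + term
    system = scipy.sparse.identity(n_vox, format="csr") + (beta / d) * lap
    out = np.empty_like(arr)
    for c in range(d):
        out[c] = scipy.sparse.linalg.spsolve(
            system.tocsc(), arr[c].ravel()
        ).reshape(spatial)
    return DeformationField(out) if wrap else out


def alternate_variational_solve(
    fixed,
    moving,
    hyperparams: Hyperparams = None,
    n_outer: int = 10,
    n_inner: int = 20,
    step: float = 20.0,
):
    """Alternating minimization of the decoupled objective without networks.

    Each outer round performs ``n_inner`` gradient-descent steps on the
    similarity sub-problem in ``u`` (``v`` held fixed), then replaces ``v``
    with the closed-form smoothing of ``u``.  Returns ``(u, v, history)``
    where history is the joint-objective value after each outer round.
    """
    hp = hyperparams or Hyperparams()
    fixed_arr = fixed.values if hasattr(fixed, "values") else np.asarray(fixed, float)
    moving_arr = moving.values if hasattr(moving, "values") else np.asarray(moving, float)
    if fixed_arr.shape != moving_arr.shape:
        raise ValueError("fixed and moving shapes differ")
    d = fixed_arr.ndim
    u = np.zeros((1, d) + fixed_arr.shape)
    v = np.zeros_like(u)
    fb = fixed_arr[None]
    mb = moving_arr[None]
    history = []
    for outer in range(n_outer):
        for _ in range(n_inner):
            ut = Tensor(u, needs_grad=True)
            loss = similarity_loss_t(
                fb, mb, ut, v, hp.alpha, hp.lcc_window, hp.epsilon
            )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"similarity sub-problem diverged at outer iteration {outer}"
                )
            loss.backward()
            u = u - step * ut.grad
        v = closed_form_smooth(u[0], hp.beta)[None]
        obj = joint_objective(
            fixed_arr, moving_arr, u[0], hp.lambda_, hp.lcc_window, hp.epsilon
        )
        if not np.isfinite(obj):
            raise FloatingPointError(f"objective diverged at outer iteration {outer}")
        history.append(obj)
    return DeformationField(u[0]), DeformationField(v[0]), history
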