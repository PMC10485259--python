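"""Alternating unsupervised training of the two registration operators.

One outer iteration mirrors the decoupled algorithm: draw a random batch;
(a) freeze Denoiser-Net, predict ``u`` with Similarity-Net and ``v = D(u)``
with the frozen denoiser (``v`` detached), take one optimizer step on the
similarity sub-problem loss; (b) freeze Similarity-Net, recompute ``u``
(detached), take one optimizer step on the denoising sub-problem loss.  The
two sub-steps share the batch drawn at the top of the loop.

Baseline modes: ``s_net`` trains Similarity-Net on the similarity term alone;
``ss_net`` adds ``lambda * smoothness`` to the loss in a single step — the
standard ablations against which the decoupled scheme is compared.

Optimization uses adaptive moment estimation with one optimizer state per
network.  Training is seed-reproducible end to end.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._engine import Tensor, grid_sample
from .core import DeformationField, Hyperparams, ScalarImage
from .networks import DenoiserNet, DenoiserNetSpec, SimilarityNet, SimilarityNetSpec
from .objectives import denoiser_loss_t, lcc_loss_t, similarity_loss_t, smoothness_t
from .warping import warp_image

__all__ = [
    "TrainingConfig",
    "TrainState",
    "Adam",
    "train",
    "register",
    "save_checkpoint",
    "load_checkpoint",
    "save_history",
]

MODES = ("decoupled", "s_net", "ss_net")


@dataclass(frozen=True)
class TrainingConfig:
    mode: str = "decoupled"
    iterations: int = 1500
    learning_rate: float = 5e-4   # the reference training schedule's default
    batch_size: int = 4
    seed: int = 0
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    checkpoint_every: int = 100
    augment: bool = True

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.iterations < 0 or self.batch_size < 1 or self.checkpoint_every < 1:
            raise ValueError("iterations >= 0, batch_size >= 1, checkpoint_every >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class Adam:
    """Adaptive moment estimation over a dict of named parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            g = g.astype(params[k].dtype, copy=False)
            m = self.m.get(k)
            if m is None:
                m = np.zeros_like(params[k])
                self.m[k] = m
                self.v[k] = np.zeros_like(params[k])
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainState:
    sim_net: SimilarityNet
    sim_params: dict
    den_net: DenoiserNet | None
    den_params: dict | None
    sim_opt: Adam
    den_opt: Adam | None
    config: TrainingConfig
    iteration: int = 0


def _pair_arrays(pair):
    if hasattr(pair, "fixed") and hasattr(pair, "moving"):
        fixed, moving = pair.fixed, pair.moving
    else:
        fixed, moving = pair
    fa = fixed.values if isinstance(fixed, ScalarImage) else np.asarray(fixed, float)
    ma = moving.values if isinstance(moving, ScalarImage) else np.asarray(moving, float)
    return fa, ma


def _wrap_trainable(params: dict) -> dict:
    return {k: Tensor(v, needs_grad=True) for k, v in params.items()}


def _random_symmetry(fb: np.ndarray, mb: np.ndarray, rng: np.random.Generator):
    """Apply one random grid symmetry (axis flips, plus an axis permutation on
    cubic grids) identically to both batches.

    Registration is equivariant under these transforms, so they enlarge the
    effective training distribution without altering the dataset — with only
    20 pairs the networks otherwise memorize the training pairs and fail to
    generalize.
    """
    ndim = fb.ndim - 1
    axes = [a for a in range(1, ndim + 1) if rng.integers(2)]
    if axes:
        fb = np.flip(fb, axes)
        mb = np.flip(mb, axes)
    if len(set(fb.shape[1:])) == 1:
        perm = rng.permutation(ndim)
        order = (0, *(1 + perm))
        fb = fb.transpose(order)
        mb = mb.transpose(order)
    return np.ascontiguousarray(fb), np.ascontiguousarray(mb)


def init_state(
    config: TrainingConfig,
    ndim: int,
    sim_spec: SimilarityNetSpec | None = None,
    den_spec: DenoiserNetSpec | None = None,
    dtype=np.float32,
) -> TrainState:
    rng = np.random.default_rng(config.seed)
    sim_net = SimilarityNet(sim_spec or SimilarityNetSpec(), ndim)
    sim_params = sim_net.init_params(rng, dtype)
    den_net = den_params = den_opt = None
    if config.mode == "decoupled":
        den_net = DenoiserNet(den_spec or DenoiserNetSpec(), ndim)
        den_params = den_net.init_params(rng, dtype)
        den_opt = Adam(config.learning_rate)
    return TrainState(
        sim_net, sim_params, den_net, den_params,
        Adam(config.learning_rate), den_opt, config,
    )


def train(
    dataset,
    config: TrainingConfig,
    sim_spec: SimilarityNetSpec | None = None,
    den_spec: DenoiserNetSpec | None = None,
    dtype=np.float32,
):
    """Run the configured training mode; returns ``(state, history)``.

    ``history`` is a list of dicts with keys ``iteration``, ``sim_loss``,
    ``denoise_loss`` and ``joint_objective`` recorded every
    ``checkpoint_every`` iterations (batch-level values).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    pairs = [_pair_arrays(p) for p in dataset]
    fixed_all = np.stack([f for f, _ in pairs]).astype(dtype)
    moving_all = np.stack([m for _, m in pairs]).astype(dtype)
    ndim = fixed_all.ndim - 1
    hp = config.hyperparams
    state = init_state(config, ndim, sim_spec, den_spec, dtype)
    rng = np.random.default_rng(config.seed + 1)
    history: list[dict] = []

    for i in range(config.iterations):
        idx = rng.integers(0, len(pairs), config.batch_size)
        fb, mb = fixed_all[idx], moving_all[idx]
        if config.augment:
            fb, mb = _random_symmetry(fb, mb, rng)

        if config.mode == "decoupled":
            # (a) update Similarity-Net; Denoiser-Net frozen, v detached
            wp = _wrap_trainable(state.sim_params)
            u = state.sim_net.forward(wp, fb, mb)
            v = state.den_net.forward(state.den_params, u.data)
            loss_a = similarity_loss_t(
                fb, mb, u, v.data, hp.alpha, hp.lcc_window, hp.epsilon
            )
            sim_loss = loss_a.item()
            if not math.isfinite(sim_loss):
                raise FloatingPointError(f"similarity loss non-finite at iteration {i}")
            loss_a.backward()
            state.sim_opt.step(state.sim_params, {k: t.grad for k, t in wp.items()})

            # (b) update Denoiser-Net; Similarity-Net frozen, u detached
            u_det = state.sim_net.forward(state.sim_params, fb, mb).data
            wd = _wrap_trainable(state.den_params)
            v = state.den_net.forward(wd, u_det)
            loss_b = denoiser_loss_t(v, u_det, hp.beta, ndim)
            den_loss = loss_b.item()
            if not math.isfinite(den_loss):
                raise FloatingPointError(f"denoiser loss non-finite at iteration {i}")
            loss_b.backward()
            state.den_opt.step(state.den_params, {k: t.grad for k, t in wd.items()})
            u_mon = u_det
        else:
            wp = _wrap_trainable(state.sim_params)
            u = state.sim_net.forward(wp, fb, mb)
            warped = grid_sample(mb, u)
            loss = lcc_loss_t(fb, warped, hp.lcc_window, hp.epsilon, ndim)
            if config.mode == "ss_net" and hp.lambda_:
                loss = loss + hp.lambda_ * smoothness_t(u, ndim)
            sim_loss = loss.item()
            den_loss = float("nan")
            if not math.isfinite(sim_loss):
                raise FloatingPointError(f"loss non-finite at iteration {i}")
            loss.backward()
            state.sim_opt.step(state.sim_params, {k: t.grad for k, t in wp.items()})
            u_mon = u.data

        state.iteration = i + 1
        if (i + 1) % config.checkpoint_every == 0 or i == 0:
            lcc_val = lcc_loss_t(
                fb, grid_sample(mb, u_mon), hp.lcc_window, hp.epsilon, ndim
            ).item()
            joint = lcc_val + hp.lambda_ * smoothness_t(u_mon, ndim).item()
            history.append(
                {
                    "iteration": i + 1,
                    "sim_loss": sim_loss,
                    "denoise_loss": den_loss,
                    "joint_objective": joint,
                }
            )
    return state, history


def register(state: TrainState, fixed, moving):
    """Predict ``u``, the warped moving image, and the denoised field ``v``."""
    fa, ma = _pair_arrays((fixed, moving))
    dtype = next(iter(state.sim_params.values())).dtype
    fb = fa[None].astype(dtype)
    mb = ma[None].astype(dtype)
    u = state.sim_net.forward(state.sim_params, fb, mb).data[0].astype(float)
    field = DeformationField(u)
    moving_img = moving if isinstance(moving, ScalarImage) else ScalarImage(ma)
    warped = warp_image(moving_img, field, "linear")
    v = None
    if state.den_net is not None:
        v_arr = state.den_net.forward(state.den_params, u[None].astype(dtype)).data[0]
        v = DeformationField(v_arr.astype(float))
    return field, warped, v


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_checkpoint(path, state: TrainState) -> None:
    """Single-file archive: parameters keyed by layer name plus the config."""
    meta = {
        "config": {
            "mode": state.config.mode,
            "iterations": state.config.iterations,
            "learning_rate": state.config.learning_rate,
            "batch_size": state.config.batch_size,
            "seed": state.config.seed,
            "checkpoint_every": state.config.checkpoint_every,
            "augment": state.config.augment,
            "hyperparams": vars(state.config.hyperparams).copy(),
        },
        "iteration": state.iteration,
        "ndim": state.sim_net.ndim,
        "sim_spec": {
            "encoder_channels": state.sim_net.spec.encoder_channels,
            "decoder_channels": state.sim_net.spec.decoder_channels,
            "head_channels": state.sim_net.spec.head_channels,
            "kernel_size": state.sim_net.spec.kernel_size,
            "negative_slope": state.sim_net.spec.negative_slope,
        },
        "den_spec": None
        if state.den_net is None
        else {
            "stem_channels": state.den_net.spec.stem_channels,
            "dilation_rates": state.den_net.spec.dilation_rates,
            "branch_channels": state.den_net.spec.branch_channels,
            "fusion_channels": state.den_net.spec.fusion_channels,
            "kernel_size": state.den_net.spec.kernel_size,
            "negative_slope": state.den_net.spec.negative_slope,
        },
    }
    arrays = {f"sim:{k}": v for k, v in state.sim_params.items()}
    if state.den_params is not None:
        arrays.update({f"den:{k}": v for k, v in state.den_params.items()})
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainState:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["meta_json"]).decode("utf-8"))
        sim_params = {
            k[4:]: archive[k].copy() for k in archive.files if k.startswith("sim:")
        }
        den_params = {
            k[4:]: archive[k].copy() for k in archive.files if k.startswith("den:")
        }
    cfg_meta = meta["config"]
    hp = Hyperparams(**cfg_meta.pop("hyperparams"))
    config = TrainingConfig(hyperparams=hp, **cfg_meta)
    ndim = meta["ndim"]
    ss = meta["sim_spec"]
    sim_net = SimilarityNet(
        SimilarityNetSpec(
            tuple(ss["encoder_channels"]),
            tuple(ss["decoder_channels"]),
            tuple(ss["head_channels"]),
            ss["kernel_size"],
            ss["negative_slope"],
        ),
        ndim,
    )
    den_net = None
    if meta["den_spec"] is not None:
        ds = meta["den_spec"]
        den_net = DenoiserNet(
            DenoiserNetSpec(
                ds["stem_channels"],
                tuple(ds["dilation_rates"]),
                ds["branch_channels"],
                ds["fusion_channels"],
                ds["kernel_size"],
                ds["negative_slope"],
            ),
            ndim,
        )
    state = TrainState(
        sim_net,
        sim_params,
        den_net,
        den_params or None,
        Adam(config.learning_rate),
        Adam(config.learning_rate) if den_net is not None else None,
        config,
        meta["iteration"],
    )
    return state


def save_history(path, history: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["iteration", "sim_loss", "denoise_loss", "joint_objective"]
        )
        writer.writeheader()
        writer.writerows(history)
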