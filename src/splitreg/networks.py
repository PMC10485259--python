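"""The two learnable operators of the decoupled registration scheme.

Similarity-Net maps a (fixed, moving) image pair to a displacement field with
a light U-Net-style encoder-decoder: four stride-2 convolutions whose feature
maps are saved, a decoder that restores resolution with nearest-neighbor
upsampling and concatenates the saved features at each matching scale, and a
two-convolution head producing one output channel per spatial axis.

Denoiser-Net smooths a displacement field by residual learning,
``v = u + Residual(u)``: a stem convolution feeds parallel dilated
convolutions with multiple dilation rates (a small spatial pyramid), whose
concatenated outputs are fused back down to ``d`` channels.

Both operators work in 2-D and 3-D.  Parameters live in plain dicts of numpy
arrays keyed by layer name; the forward passes build autodiff graphs, so
gradients come from ``loss.backward()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import Tensor, astensor, concat, conv_nd, leaky_relu, upsample_nearest

__all__ = [
    "SimilarityNetSpec",
    "DenoiserNetSpec",
    "SimilarityNet",
    "DenoiserNet",
    "dilated_conv_1d",
]


def dilated_conv_1d(x, w, r: int) -> np.ndarray:
    """Valid-mode 1-D dilated convolution ``y[i] = sum_k x[i + r*k] w[k]``."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if r < 1:
        raise ValueError("dilation rate must be a positive integer")
    out_len = len(x) - r * (len(w) - 1)
    if out_len <= 0:
        raise ValueError(
            f"input of length {len(x)} shorter than dilated filter footprint "
            f"{r * (len(w) - 1) + 1}"
        )
    y = np.zeros(out_len)
    for k in range(len(w)):
        y += w[k] * x[r * k : r * k + out_len]
    return y


@dataclass(frozen=True)
class SimilarityNetSpec:
    encoder_channels: tuple = (16, 32, 32, 32)
    decoder_channels: tuple = (32, 32, 16, 16)
    head_channels: tuple = (16, 16)
    kernel_size: int = 3
    negative_slope: float = 0.2

    def __post_init__(self):
        if len(self.encoder_channels) != 4:
            raise ValueError("exactly 4 stride-2 encoder stages are required")
        if len(self.decoder_channels) != 4:
            raise ValueError("exactly 4 decoder stages are required")
        if len(self.head_channels) != 2:
            raise ValueError("the head has exactly 2 convolutions")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


@dataclass(frozen=True)
class DenoiserNetSpec:
    stem_channels: int = 16
    dilation_rates: tuple = (1, 2, 4, 8)
    branch_channels: int = 8
    fusion_channels: int = 16
    kernel_size: int = 3
    negative_slope: float = 0.2

    def __post_init__(self):
        rates = tuple(int(r) for r in self.dilation_rates)
        if len(rates) < 2 or len(set(rates)) != len(rates):
            raise ValueError("need >= 2 distinct dilation rates")
        if any(r < 1 for r in rates):
            raise ValueError("dilation rates must be positive")
        object.__setattr__(self, "dilation_rates", rates)
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")


def _he_init(rng, cout, cin, k, ndim, dtype, std=None):
    shape = (cout, cin) + (k,) * ndim
    fan_in = cin * k**ndim
    scale = std if std is not None else np.sqrt(2.0 / fan_in)
    w = rng.normal(0.0, scale, size=shape).astype(dtype)
    b = np.zeros(cout, dtype=dtype)
    return w, b


class _ConvNet:
    """Shared plumbing: a dict of named conv layers plus init bookkeeping."""

    def __init__(self, spec, ndim: int):
        if ndim not in (2, 3):
            raise ValueError("spatial dimensionality must be 2 or 3")
        self.spec = spec
        self.ndim = ndim
        self._layers: list[tuple[str, int, int, float | None]] = []
        self._build()

    def _add(self, name: str, cin: int, cout: int, std=None):
        self._layers.append((name, cin, cout, std))

    def init_params(self, rng: np.random.Generator, dtype=np.float32) -> dict:
        params = {}
        k = self.spec.kernel_size
        for name, cin, cout, std in self._layers:
            w, b = _he_init(rng, cout, cin, k, self.ndim, dtype, std)
            params[name + ".w"] = w
            params[name + ".b"] = b
        return params

    def param_count(self) -> int:
        k = self.spec.kernel_size
        return sum(cout * cin * k**self.ndim + cout for _, cin, cout, _ in self._layers)

    @staticmethod
    def _wrap(params: dict, trainable: bool) -> dict:
        return {
            k: v if isinstance(v, Tensor) else Tensor(v, needs_grad=trainable)
            for k, v in params.items()
        }


class SimilarityNet(_ConvNet):
    """Image pair -> displacement field (voxel units)."""

    def _build(self):
        s = self.spec
        cin = 2
        for i, ch in enumerate(s.encoder_channels):
            self._add(f"enc{i}", cin, ch)
            cin = ch
        skip_ch = [s.encoder_channels[2], s.encoder_channels[1], s.encoder_channels[0], 2]
        for j, ch in enumerate(s.decoder_channels):
            self._add(f"dec{j}", cin + skip_ch[j], ch)
            cin = ch
        self._add("head0", cin, s.head_channels[0])
        # near-zero head so the initial predicted field is ~identity
        self._add("head1", s.head_channels[1], self.ndim, std=1e-5)
        if s.head_channels[0] != s.head_channels[1]:
            raise ValueError("head_channels must chain: head0 out == head1 in")

    def forward(self, params: dict, fixed: np.ndarray, moving: np.ndarray, trainable: bool = True) -> Tensor:
        """``fixed``/``moving``: (B, *S) arrays; returns a (B, d, *S) tensor."""
        if fixed.shape != moving.shape:
            raise ValueError("fixed and moving shapes differ")
        spatial = fixed.shape[1:]
        if len(spatial) != self.ndim:
            raise ValueError(f"expected {self.ndim}-D inputs, got shape {spatial}")
        for a, n in enumerate(spatial):
            if n % 16:
                raise ValueError(
                    f"axis {a} has length {n}, not divisible by 16 "
                    "(four stride-2 stages)"
                )
        p = self._wrap(params, trainable)
        s = self.spec
        k = s.kernel_size
        pad = (k - 1) // 2
        slope = s.negative_slope

        x = concat([astensor(fixed[:, None]), astensor(moving[:, None])], axis=1)
        feats = []
        cur = x
        for i in range(4):
            cur = leaky_relu(
                conv_nd(cur, p[f"enc{i}.w"], p[f"enc{i}.b"], stride=2, padding=pad),
                slope,
            )
            feats.append(cur)
        skips = [feats[2], feats[1], feats[0], x]
        for j in range(4):
            cur = upsample_nearest(cur, 2)
            cur = concat([cur, skips[j]], axis=1)
            cur = leaky_relu(
                conv_nd(cur, p[f"dec{j}.w"], p[f"dec{j}.b"], padding=pad), slope
            )
        cur = leaky_relu(conv_nd(cur, p["head0.w"], p["head0.b"], padding=pad), slope)
        return conv_nd(cur, p["head1.w"], p["head1.b"], padding=pad)


class DenoiserNet(_ConvNet):
    """Displacement field -> smoothed field via ``v = u + Residual(u)``."""

    def _build(self):
        s = self.spec
        self._add("stem", self.ndim, s.stem_channels)
        for r in s.dilation_rates:
            self._add(f"branch_r{r}", s.stem_channels, s.branch_channels)
        cat = s.branch_channels * len(s.dilation_rates)
        self._add("fuse0", cat, s.fusion_channels)
        # small-init output conv: the initial residual is ~0, so v ~ u
        self._add("fuse1", s.fusion_channels, self.ndim, std=1e-5)

    def forward(self, params: dict, u, trainable: bool = True) -> Tensor:
        """``u``: (B, d, *S) array or tensor; returns v of the same shape."""
        u = astensor(u)
        if u.ndim - 2 != self.ndim or u.shape[1] != self.ndim:
            raise ValueError(
                f"expected (B, {self.ndim}, *spatial) field, got shape {u.shape}"
            )
        p = self._wrap(params, trainable)
        s = self.spec
        k = s.kernel_size
        pad = (k - 1) // 2
        slope = s.negative_slope

        cur = leaky_relu(conv_nd(u, p["stem.w"], p["stem.b"], padding=pad), slope)
        branches = [
            leaky_relu(
                conv_nd(
                    cur,
                    p[f"branch_r{r}.w"],
                    p[f"branch_r{r}.b"],
                    dilation=r,
                    padding=r * pad,
                ),
                slope,
            )
            for r in s.dilation_rates
        ]
        cat = concat(branches, axis=1)
        fused = leaky_relu(conv_nd(cat, p["fuse0.w"], p["fuse0.b"], padding=pad), slope)
        residual = conv_nd(fused, p["fuse1.w"], p["fuse1.b"], padding=pad)
        return u + residual
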