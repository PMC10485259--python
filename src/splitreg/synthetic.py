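"""Desk-scale registration problems with known ground truth.

The generator emulates the structure the registration model assumes: smooth
deformations relating topologically consistent "head-like" anatomies.  A
phantom is an ellipsoidal foreground partitioned into contiguous regions
(nearest-seed Voronoi cells clipped to the foreground), each with a distinct
mean intensity, lightly smoothed, overlaid with multi-scale random texture,
and corrupted by Gaussian noise.  The texture (smoothed noise at several
correlation lengths, covering the whole domain like intensity inhomogeneity
and parenchymal detail in real scans) is essential, not cosmetic: a
piecewise-constant image constrains the deformation only at region
boundaries, so the ground-truth field would be unobservable over most of the
domain and no method could recover it.  The moving image is synthesized FROM
the fixed image by backward-warping it with a random smooth displacement
field, so the field a registration method should recover is the numerical
INVERSE of the generating field; both are shipped with every pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .core import DeformationField, LabelMap, ScalarImage, normalize_image
from .warping import identity_grid, warp_array, warp_image, warp_labels

__all__ = [
    "SyntheticSpec",
    "SyntheticPair",
    "random_smooth_field",
    "make_phantom",
    "make_pair",
    "make_dataset",
    "invert_field",
]


@dataclass(frozen=True)
class SyntheticSpec:
    shape: tuple = (64, 64)
    n_pairs: int = 20
    max_displacement: float = 4.0
    smoothness_sigma: float = 4.0
    n_regions: int = 6
    noise_sigma: float = 0.02
    texture_amplitudes: tuple = (0.25, 0.2)
    texture_sigmas: tuple = (1.5, 3.0)
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError("shape must be 2-D or 3-D")
        if any(n % 16 for n in shape):
            raise ValueError("every axis must be divisible by 16")
        if self.max_displacement < 0:
            raise ValueError("max_displacement must be >= 0")
        if self.max_displacement >= min(shape) / 4:
            raise ValueError("max_displacement must stay below min(shape)/4")
        if self.smoothness_sigma < 1:
            raise ValueError("smoothness_sigma must be >= 1")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        amps = tuple(float(a) for a in self.texture_amplitudes)
        sigs = tuple(float(s) for s in self.texture_sigmas)
        object.__setattr__(self, "texture_amplitudes", amps)
        object.__setattr__(self, "texture_sigmas", sigs)
        if len(amps) != len(sigs):
            raise ValueError("texture_amplitudes and texture_sigmas differ in length")
        if any(a < 0 for a in amps) or any(s <= 0 for s in sigs):
            raise ValueError("texture amplitudes must be >= 0 and sigmas > 0")


@dataclass(frozen=True)
class SyntheticPair:
    fixed: ScalarImage
    moving: ScalarImage
    fixed_labels: LabelMap
    moving_labels: LabelMap
    truth_field: DeformationField       # generated moving from fixed
    inverse_field: DeformationField     # what registering moving->fixed recovers
    seed: int


def random_smooth_field(spec: SyntheticSpec, rng: np.random.Generator) -> DeformationField:
    """Gaussian-filtered white noise rescaled to a fixed peak magnitude."""
    d = len(spec.shape)
    noise = rng.standard_normal((d,) + spec.shape)
    if spec.max_displacement == 0:
        return DeformationField(np.zeros_like(noise))
    smooth = np.stack(
        [
            scipy.ndimage.gaussian_filter(noise[c], spec.smoothness_sigma, mode="reflect")
            for c in range(d)
        ]
    )
    mag = np.sqrt((smooth**2).sum(axis=0))
    peak = mag.max()
    if peak == 0:  # pragma: no cover - measure-zero draw
        return DeformationField(np.zeros_like(noise))
    return DeformationField(smooth * (spec.max_displacement / peak))


def make_phantom(
    spec: SyntheticSpec, rng: np.random.Generator, intensity_smoothing: float = 1.0
):
    """An ellipsoidal multi-region phantom image with its label map."""
    shape = spec.shape
    d = len(shape)
    grid = identity_grid(shape)
    center = np.array([(n - 1) / 2.0 for n in shape])
    radii = np.array([0.38 * n for n in shape]) * rng.uniform(0.92, 1.05, size=d)
    dist2 = np.zeros(shape)
    for a in range(d):
        dist2 += ((grid[a] - center[a]) / radii[a]) ** 2
    fg = dist2 <= 1.0

    fg_coords = np.argwhere(fg)
    seeds = fg_coords[rng.choice(len(fg_coords), size=spec.n_regions, replace=False)]
    # nearest-seed assignment: contiguous Voronoi cells clipped to the foreground
    diffs = fg_coords[None, :, :] - seeds[:, None, :]
    assign = np.argmin((diffs**2).sum(axis=2), axis=0)
    labels = np.zeros(shape, dtype=np.int64)
    labels[tuple(fg_coords.T)] = assign + 1

    means = np.linspace(0.25, 0.95, spec.n_regions)
    rng.shuffle(means)
    img = np.zeros(shape)
    for rid in range(1, spec.n_regions + 1):
        img[labels == rid] = means[rid - 1]
    if intensity_smoothing > 0:
        img = scipy.ndimage.gaussian_filter(img, intensity_smoothing, mode="nearest")
    # Multi-scale texture over the whole domain: without it the field would be
    # observable only at region boundaries (aperture problem).
    for amp, sig in zip(spec.texture_amplitudes, spec.texture_sigmas):
        if amp == 0:
            continue
        tex = scipy.ndimage.gaussian_filter(rng.standard_normal(shape), sig)
        std = tex.std()
        if std > 0:
            img = img + tex * (amp / std)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    return normalize_image(img), LabelMap(labels)


def invert_field(field: DeformationField, n_iter: int = 20) -> DeformationField:
    """Fixed-point inversion: find w with w(x) = -u(x + w(x))."""
    u = field.displacements
    d = u.shape[0]
    w = np.zeros_like(u)
    for _ in range(n_iter):
        w = -np.stack([warp_array(u[c], w, "linear") for c in range(d)])
    return DeformationField(w)


def inversion_residual(field: DeformationField, inverse: DeformationField) -> float:
    """Max |u(x + w(x)) + w(x)| over voxels, in voxels."""
    u = field.displacements
    w = inverse.displacements
    comp = np.stack([warp_array(u[c], w, "linear") for c in range(u.shape[0])]) + w
    return float(np.sqrt((comp**2).sum(axis=0)).max())


def make_pair(spec: SyntheticSpec, rng: np.random.Generator, max_retries: int = 5) -> SyntheticPair:
    """A (fixed, moving) pair with ground-truth and inverted fields."""
    seed_used = int(rng.integers(0, 2**31 - 1))
    for attempt in range(max_retries):
        local = np.random.default_rng(seed_used + attempt)
        fixed, fixed_labels = make_phantom(spec, local)
        truth = random_smooth_field(spec, local)
        inverse = invert_field(truth)
        if spec.max_displacement == 0 or inversion_residual(truth, inverse) <= 0.5:
            moving = warp_image(fixed, truth, "linear")
            moving_labels = warp_labels(fixed_labels, truth)
            return SyntheticPair(
                fixed, moving, fixed_labels, moving_labels, truth, inverse,
                seed_used + attempt,
            )
    raise RuntimeError(
        f"field inversion failed to reach 0.5 voxel residual in {max_retries} draws"
    )


def make_dataset(spec: SyntheticSpec) -> list[SyntheticPair]:
    """``spec.n_pairs`` independent pairs, fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    return [make_pair(spec, rng) for _ in range(spec.n_pairs)]
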