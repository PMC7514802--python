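"""Synthetic test images with controlled multimodal histograms.

Real thresholding benchmarks (natural photographs, satellite scenes, brain
MR slices) share one property that makes multilevel thresholding meaningful:
a multimodal gray-level histogram.  `generate_image` draws pixels i.i.d.
from a Gaussian mixture over [0, 255], which reproduces exactly that
property with known mode locations, and `add_gaussian_noise` applies the
additive Gaussian corruption used in noise-robustness protocols, with the
variance specified on the unit intensity scale (so variance 0.01 means a
noise standard deviation of 0.1 x 255 gray levels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "MixtureSpec",
    "NoiseSpec",
    "generate_image",
    "add_gaussian_noise",
    "random_mixture",
]

#: Noise-variance ladder used by the robustness protocol (unit intensity scale).
NOISE_VARIANCES = (0.00625, 0.0125, 0.025, 0.05, 0.1)


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian-mixture description of a synthetic image.

    ``modes`` is a sequence of (mean, sd, weight) triples with means in
    [0, 255]; weights are normalized internally.  ``sd = 0`` is the
    degenerate (constant-component) limit.
    """

    modes: Tuple[Tuple[float, float, float], ...]
    size: Tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.modes) == 0:
            raise ValueError("at least one mode is required")
        for mean, sd, w in self.modes:
            if not 0 <= mean <= 255:
                raise ValueError("mode mean must lie in [0, 255]")
            if sd < 0:
                raise ValueError("mode sd must be nonnegative")
            if w <= 0:
                raise ValueError("mode weight must be positive")
        if self.size[0] < 1 or self.size[1] < 1:
            raise ValueError("image size must be positive")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([m[2] for m in self.modes], dtype=float)
        return w / w.sum()


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise protocol: fixed mean, a ladder of variances."""

    mean: float = 0.0
    variances: Tuple[float, ...] = NOISE_VARIANCES

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.variances):
            raise ValueError("variances must be positive")


def _draw_channel(spec: MixtureSpec, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = spec.size[0] * spec.size[1]
    means = np.array([m[0] for m in spec.modes])
    sds = np.array([m[1] for m in spec.modes])
    comp = rng.choice(len(spec.modes), size=n, p=spec.weights)
    vals = rng.normal(means[comp], sds[comp])
    return np.clip(np.floor(vals + 0.5), 0, 255).astype(np.uint8).reshape(spec.size)


def generate_image(spec: MixtureSpec, channels: int = 1) -> np.ndarray:
    """Draw a synthetic 8-bit image from the mixture; reproducible from the seed.

    ``channels=3`` produces an RGB image with per-channel seeds
    ``seed, seed+1, seed+2``.
    """
    if channels not in (1, 3):
        raise ValueError("channels must be 1 or 3")
    if channels == 1:
        return _draw_channel(spec, spec.seed)
    return np.stack([_draw_channel(spec, spec.seed + c) for c in range(3)], axis=-1)


def add_gaussian_noise(image: np.ndarray, mean: float, variance: float, seed: int = 0) -> np.ndarray:
    """Corrupt an 8-bit image with additive Gaussian noise on the unit scale.

    ``pixel' = clip(round(pixel + 255 n), 0, 255)`` with
    ``n ~ Normal(mean, variance)``; variance 0 returns the input unchanged.
    """
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    arr = np.asarray(image)
    if variance == 0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(mean, np.sqrt(variance), size=arr.shape)
    noisy = np.floor(arr.astype(float) + 255.0 * noise + 0.5)
    return np.clip(noisy, 0, 255).astype(np.uint8)


def random_mixture(
    seed: int,
    n_modes: int = 3,
    size: Tuple[int, int] = (128, 128),
    sd_range: Tuple[float, float] = (8.0, 16.0),
) -> MixtureSpec:
    """A reproducible random mixture with well-spread modes.

    Mode means are drawn in [20, 235] at least 40 gray levels apart, sds
    uniform in ``sd_range`` and weights uniform in [0.5, 1.5] — a multimodal
    profile typical of natural-image histograms.
    """
    rng = np.random.default_rng(seed)
    while True:
        means = np.sort(rng.uniform(20, 235, size=n_modes))
        if n_modes == 1 or np.min(np.diff(means)) >= 40:
            break
    sds = rng.uniform(*sd_range, size=n_modes)
    weights = rng.uniform(0.5, 1.5, size=n_modes)
    modes = tuple((float(m), float(s), float(w)) for m, s, w in zip(means, sds, weights))
    return MixtureSpec(modes=modes, size=size, seed=seed)
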