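"""Segmentation quality measures: MSE/PSNR, SSIM, FSIM, fitness dispersion.

PSNR compares segmented to original on the 8-bit scale
(``10 log10(255^2 / MSE)``, squared errors pooled over channels for RGB).
SSIM follows the standard local-statistics formulation (11x11 Gaussian
window, sigma 1.5, K1=0.01, K2=0.03, L=255), averaged per channel for RGB;
a whole-image "global" variant of the same formula is available for
formula-exact checks.  FSIM weights the pointwise product of a
phase-congruency similarity and a gradient-magnitude similarity by the
maximum phase congruency of the two images; phase congruency is computed
from a log-Gabor filter bank (4 scales x 4 orientations) and gradients with
the Scharr operator, on the luminance channel for RGB.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = ["mse_psnr", "ssim", "fsim", "fitness_std", "phase_congruency"]

_L = 255.0


def _pair(original, segmented) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(original, dtype=float)
    b = np.asarray(segmented, dtype=float)
    if a.shape != b.shape:
        raise ValueError("image shapes do not match")
    if a.size == 0:
        raise ValueError("empty image")
    return a, b


def mse_psnr(original: np.ndarray, segmented: np.ndarray) -> Tuple[float, float]:
    """Mean squared error and peak signal-to-noise ratio (dB).

    MSE is averaged over all pixels (and channels); identical images give
    MSE 0 and PSNR ``+inf``.
    """
    a, b = _pair(original, segmented)
    mse = float(np.mean((a - b) ** 2))
    psnr = np.inf if mse == 0.0 else float(10.0 * np.log10(_L**2 / mse))
    return mse, psnr


def _global_ssim(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx**2 + my**2 + c1) * (vx + vy + c2))
    )


def ssim(original: np.ndarray, segmented: np.ndarray, mode: str = "windowed") -> float:
    """Structural similarity index in [-1, 1].

    ``mode="windowed"`` (default) uses Gaussian-weighted 11x11 local
    statistics averaged over the image; ``mode="global"`` evaluates the same
    formula once on whole-image statistics.  RGB inputs are scored per
    channel and averaged.
    """
    a, b = _pair(original, segmented)
    if mode not in ("windowed", "global"):
        raise ValueError(f"unknown ssim mode {mode!r}")
    chans = [(a, b)] if a.ndim == 2 else [(a[..., c], b[..., c]) for c in range(a.shape[2])]
    vals = []
    for x, y in chans:
        if mode == "windowed":
            vals.append(
                structural_similarity(
                    x, y, data_range=_L, gaussian_weights=True, sigma=1.5,
                    win_size=11, use_sample_covariance=False, K1=0.01, K2=0.03,
                )
            )
        else:
            vals.append(_global_ssim(x, y, (0.01 * _L) ** 2, (0.03 * _L) ** 2))
    return float(np.mean(vals))


def _log_gabor_bank(shape, n_scales=4, n_orient=4, min_wavelength=6.0,
                    mult=2.0, sigma_on_f=0.55, d_theta_on_sigma=1.2):
    """Frequency-domain log-Gabor filters: list (orientation) of lists (scale)."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    radius[0, 0] = 1.0  # avoid log(0) at DC; filter value there is zeroed below
    theta = np.arctan2(-fy, fx)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    theta_sigma = np.pi / n_orient / d_theta_on_sigma

    bank = []
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        scales = []
        for s in range(n_scales):
            f0 = 1.0 / (min_wavelength * mult**s)
            log_gabor = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_on_f) ** 2))
            log_gabor[0, 0] = 0.0
            scales.append(log_gabor * spread)
        bank.append(scales)
    return bank


def phase_congruency(image: np.ndarray) -> np.ndarray:
    """Phase congruency map from a 4-scale x 4-orientation log-Gabor bank.

    For each orientation the local energy (magnitude of the summed complex
    responses) is divided by the total response amplitude; contributions are
    summed over orientations:  ``PC = sum_o E_o / (eps + sum_o sum_s A_so)``.
    Values lie in [0, 1]; flat images give 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("phase_congruency expects a 2-D image")
    if min(img.shape) < 16:
        raise ValueError("image smaller than the log-Gabor filter bank support")
    eps = 1e-4
    F = np.fft.fft2(img)
    energy_sum = np.zeros_like(img)
    amplitude_sum = np.zeros_like(img)
    for scales in _log_gabor_bank(img.shape):
        sum_resp = np.zeros_like(img, dtype=complex)
        for filt in scales:
            resp = np.fft.ifft2(F * filt)
            sum_resp += resp
            amplitude_sum += np.abs(resp)
        energy_sum += np.abs(sum_resp)
    return energy_sum / (eps + amplitude_sum)


def _scharr_gradient(img: np.ndarray) -> np.ndarray:
    kx = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=float) / 16.0
    gx = ndimage.convolve(img, kx, mode="nearest")
    gy = ndimage.convolve(img, kx.T, mode="nearest")
    return np.sqrt(gx**2 + gy**2)


def _luminance(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def fsim(
    original: np.ndarray,
    segmented: np.ndarray,
    t1: float = 0.85,
    t2: float = 160.0,
    alpha: float = 1.0,
    beta: float = 1.0,
) -> float:
    """Feature similarity index in (0, 1].

    ``FSIM = sum_x S_L(x) PC_m(x) / sum_x PC_m(x)`` with
    ``S_L = S_PC^alpha * S_G^beta``, where ``S_PC`` and ``S_G`` are the
    ratio-style similarities of the phase-congruency maps (stabilized by
    ``t1``) and Scharr gradient magnitudes (stabilized by ``t2``), and
    ``PC_m = max(PC_1, PC_2)`` weights pixels by structural significance.
    RGB images are scored on luminance.
    """
    a, b = _pair(original, segmented)
    x = _luminance(a)
    y = _luminance(b)
    pc1 = phase_congruency(x)
    pc2 = phase_congruency(y)
    g1 = _scharr_gradient(x)
    g2 = _scharr_gradient(y)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    s_l = s_pc**alpha * s_g**beta
    pc_m = np.maximum(pc1, pc2)
    denom = float(pc_m.sum())
    if denom == 0.0:
        return 1.0 if np.array_equal(x, y) else float(np.mean(s_l))
    return float((s_l * pc_m).sum() / denom)


def fitness_std(values) -> float:
    """Sample standard deviation (n-1 denominator) of repeated-run fitness values."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least two values")
    return float(np.std(v, ddof=1))
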