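"""Map regularization: uniform ML (Wiener/SSNR) and non-uniform real-space ICM.

ML regularization divides the gridding accumulator by the CTF^2 weights plus
a per-shell term 1 / (tau * SSNR), with SSNR = FSC / (1 - FSC) estimated
from the even/odd half maps; tau (default 3) relaxes the damping.

ICM regularization models the map as a Gibbs random field over quantized
voxel values. Per-voxel noise standard deviations come from the even-odd
difference volume; a raster-scan iterated-conditional-modes sweep then
assigns each voxel the quantized level minimizing

    (v - observed)^2 / (2 sigma^2) + lambda * sum_{j in N6} (v - v_j)^2

which is deterministic and monotonically non-increasing in the global
energy. Applied to the even and odd maps independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from . import _kernels
from .fourier import DensityVolume, FourierVolume, shell_index_map


@dataclass
class RegularizerConfig:
    tau: float = 3.0  # ML fudge factor; higher = less smoothing
    lam: float = 1.0  # ICM smoothing weight
    levels: int = 64  # quantization levels
    icm_sweeps: int = 10

    def __post_init__(self):
        if self.tau <= 0 or self.lam < 0:
            raise ValueError("tau must be > 0 and lambda >= 0")


@dataclass
class SigmaMap:
    """Per-voxel noise standard deviation."""

    sigma: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma < 0) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma must be finite and non-negative")


@dataclass
class QuantizedLevels:
    levels: np.ndarray  # sorted representative values
    labels: np.ndarray | None = None


def ml_regularize(accum: FourierVolume, fsc: np.ndarray, tau: float = 3.0) -> DensityVolume:
    """Wiener-style division V = num / (weights + 1/(tau * SSNR(shell))).

    SSNR = max(FSC, 0) / (1 - min(FSC, 0.999)); shells with FSC <= 0 are
    fully damped. If no shell has positive FSC the plain floored division
    is used instead.
    """
    if accum.weight is None:
        raise ValueError("accumulator required")
    fsc = np.asarray(fsc, dtype=float)
    if np.all(fsc <= 0):
        return accum.normalize()
    ssnr = np.maximum(fsc, 0.0) / (1.0 - np.minimum(fsc, 0.999))
    with np.errstate(divide="ignore"):
        reg = np.where(ssnr > 0, 1.0 / (tau * ssnr), np.inf)
    shells = shell_index_map(accum.data.shape)
    # accumulator shells are oversampled: map back to original-box shells
    orig_shell = np.clip(
        np.round(shells / accum.scale).astype(int), 0, len(fsc) - 1
    )
    # keep the Wiener floor as a lower bound on the damping so empty cells
    # never blow up even when the FSC claims infinite SSNR
    floor = 1e-4 * float(accum.weight.max())
    denom = accum.weight + np.maximum(reg[orig_shell], floor)
    num = np.where(np.isfinite(denom), accum.data / np.where(np.isfinite(denom), denom, 1.0), 0.0)
    return accum._to_density(num.astype(np.complex64))


def noise_sigma_map(even: DensityVolume, odd: DensityVolume, window: int = 5) -> SigmaMap:
    """Local std of (odd - even) over a cubic window, scaled to one half map.

    The even-odd difference carries the noise of both halves; dividing by
    sqrt(2) refers sigma to a single half map.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    if even.grid.shape != odd.grid.shape:
        raise ValueError("grids differ")
    noise = (odd.grid - even.grid).astype(np.float64)
    mu = uniform_filter(noise, size=window, mode="nearest")
    mu2 = uniform_filter(noise * noise, size=window, mode="nearest")
    var = np.maximum(mu2 - mu * mu, 0.0)
    return SigmaMap(np.sqrt(var / 2.0).astype(np.float32))


def vector_quantize(vol: DensityVolume | np.ndarray, n_levels: int = 64) -> QuantizedLevels:
    """1-D Lloyd (k-means) quantization of voxel values, quantile-seeded."""
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    x = (vol.grid if isinstance(vol, DensityVolume) else np.asarray(vol)).ravel().astype(np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant volume: single quantization level replicated")
        levels = np.full(n_levels, lo)
        return QuantizedLevels(levels, np.zeros(x.shape, dtype=np.int32))
    # deterministic quantile initialization
    qs = (np.arange(n_levels) + 0.5) / n_levels
    levels = np.quantile(x, qs)
    levels = _strictly_increasing(levels, lo, hi)
    xs = np.sort(x)
    for _ in range(50):
        bounds = 0.5 * (levels[1:] + levels[:-1])
        idx = np.searchsorted(xs, bounds)
        new = levels.copy()
        start = 0
        csum = np.concatenate([[0.0], np.cumsum(xs)])
        for k in range(n_levels):
            end = idx[k] if k < n_levels - 1 else len(xs)
            if end > start:
                new[k] = (csum[end] - csum[start]) / (end - start)
            start = end
        new = _strictly_increasing(new, lo, hi)
        if np.max(np.abs(new - levels)) < 1e-10 * max(abs(hi - lo), 1e-30):
            levels = new
            break
        levels = new
    bounds = 0.5 * (levels[1:] + levels[:-1])
    labels = np.searchsorted(bounds, x).astype(np.int32)
    return QuantizedLevels(levels, labels)


def _strictly_increasing(levels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    eps = 1e-12 * max(abs(hi - lo), 1e-30)
    out = levels.copy()
    for i in range(1, len(out)):
        if out[i] <= out[i - 1]:
            out[i] = out[i - 1] + eps
    return out


def quantize_to_levels(x: np.ndarray, levels: np.ndarray) -> np.ndarray:
    bounds = 0.5 * (levels[1:] + levels[:-1])
    return levels[np.searchsorted(bounds, x)]


#: reference noise sd in the internal ICM units: lambda = 1 balances the
#: data and 6-neighbour smoothing terms when the noise sd maps to this value
#: (2 * lambda * 6 vs 1/sigma'^2 gives ~0.75 weight on the neighbour mean)
_ICM_NOISE_UNIT = 0.5


def icm_regularize(
    vol: DensityVolume,
    sigma: SigmaMap,
    cfg: RegularizerConfig | None = None,
    levels: np.ndarray | None = None,
    return_energies: bool = False,
):
    """Non-uniform ICM regularization of one (half-)map.

    Deterministic raster-scan sweeps over the quantized value set; stops when
    a sweep changes nothing or after ``cfg.icm_sweeps`` sweeps. The pairwise
    term is not scale-invariant, so the map is implicitly expressed in units
    of the mean noise sd (times 1/0.354): lambda = 1 then balances data
    fidelity against 6-neighbour smoothness regardless of the map's scale.
    """
    cfg = cfg or RegularizerConfig()
    obs = vol.grid.astype(np.float64)
    if levels is None:
        levels = vector_quantize(vol, cfg.levels).levels
    levels = np.ascontiguousarray(np.asarray(levels, dtype=np.float64))
    if len(np.unique(levels)) == 1:
        out = DensityVolume(np.full_like(vol.grid, levels[0]), vol.pixel_size)
        return (out, np.zeros(1)) if return_energies else out
    map_scale = max(float(np.std(vol.grid)), 1e-30)
    sigma_mean = float(np.mean(sigma.sigma))
    work = quantize_to_levels(obs, levels)
    if sigma_mean < 1e-6 * map_scale:
        # effectively noise-free: the data term pins every voxel
        out = DensityVolume(work.astype(np.float32), vol.pixel_size)
        return (out, np.zeros(1)) if return_energies else out
    lam_eff = cfg.lam * (_ICM_NOISE_UNIT / sigma_mean) ** 2
    s2 = np.maximum(sigma.sigma.astype(np.float64) ** 2, _sigma_floor(vol))
    energies, _ = _kernels.icm_sweeps(
        work, obs, np.ascontiguousarray(s2), levels, float(lam_eff), int(cfg.icm_sweeps)
    )
    out = DensityVolume(work.astype(np.float32), vol.pixel_size)
    return (out, energies) if return_energies else out


def _sigma_floor(vol: DensityVolume) -> float:
    scale = float(np.std(vol.grid))
    return max((1e-6 * scale) ** 2, 1e-30)
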