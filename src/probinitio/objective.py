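"""Noise-weighted normalized Euclidean objective and continuous shift search.

The cost of particle P against a CTF-affected reference R = H * P(V, o) is

    d = sum_k w_k sum_{h in ring k} |P~(h) - H(h) R(h)|^2
        -----------------------------------------------------
        2 * sum_k w_k sum_{h in ring k} (|P~(h)|^2 + |H(h) R(h)|^2)

with per-ring weights w_k = 1 / sigma2_k estimated from the data and
P~ the particle transform recentered by its origin shift. By the
parallelogram/Cauchy-Schwarz bound the ratio lies in [0, 1]: d = 0 iff
P~ = HR on every included ring, d = 1 iff P~ = -HR. The normalization makes
the cost dimensionless and independent of image size.

Shifts enter only through the phase ramp exp(-i c h . s) with
c = 2*pi/L, so the denominator is shift-invariant and the gradient of d
reduces to the gradient of the numerator; it is optimized with bounded
L-BFGS-B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize

from .fourier import shell_index_map, shift_image_ft

SIGMA2_FLOOR_FRAC = 1e-12


@dataclass
class NoiseSpectrum:
    """Per-ring noise power of one particle at its current orientation."""

    sigma2: np.ndarray  # per ring 1..kmax
    ring_counts: np.ndarray  # Fourier components per ring
    kmax: int
    phase_constant: float  # c = 2*pi/L, radians per pixel of shift per index

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.sigma2


@dataclass
class CostValue:
    d: float

    def __post_init__(self):
        if not 0.0 <= self.d <= 1.0 + 1e-9:
            raise ValueError(f"cost outside [0, 1]: {self.d}")
        self.d = float(min(max(self.d, 0.0), 1.0))


@lru_cache(maxsize=16)
def _ring_data(L: int, kmax: int):
    shells = shell_index_map((L, L))
    sel = (shells >= 1) & (shells <= kmax)
    lab = shells[sel] - 1
    counts = np.bincount(lab, minlength=kmax).astype(float)
    h = np.arange(L) - L // 2
    hx, hy = np.meshgrid(h, h, indexing="ij")
    return sel, lab, counts, hx[sel].astype(float), hy[sel].astype(float)


def _prep(particle_ft, reference_ft, ctf, shift, kmax):
    L = particle_ft.shape[0]
    if kmax is None:
        kmax = L // 2
    sel, lab, counts, hx, hy = _ring_data(L, kmax)
    p = particle_ft[sel]
    if shift is not None and np.any(np.asarray(shift) != 0):
        # recenter: undo a content translation by +shift
        c = 2.0 * np.pi / L
        p = p * np.exp(1j * c * (hx * shift[0] + hy * shift[1]))
    r = reference_ft[sel]
    if ctf is not None:
        r = r * ctf[sel]
    return L, sel, lab, counts, hx, hy, p, r


def estimate_noise_power(
    particle_ft: np.ndarray,
    reference_ft: np.ndarray,
    ctf: np.ndarray | None,
    shift=None,
    kmax: int | None = None,
) -> NoiseSpectrum:
    """Per-ring noise power sigma2_k = (1/N_k) sum_{h in k} |P~ - H R|^2.

    ``reference_ft`` is the raw reference section; the CTF (2D array on the
    same grid, or None) multiplies it inside. Rings beyond ``kmax`` are
    excluded; empty rings are excluded with a warning and floored.
    """
    L, sel, lab, counts, hx, hy, p, r = _prep(particle_ft, reference_ft, ctf, shift, kmax)
    kmax = kmax or L // 2
    resid = np.abs(p - r) ** 2
    sig = np.bincount(lab, resid, minlength=kmax)
    if np.any(counts == 0):
        warnings.warn("empty Fourier ring excluded from noise estimate")
    power = np.bincount(lab, np.abs(p) ** 2, minlength=kmax)
    floor = SIGMA2_FLOOR_FRAC * max(power.mean(), 1e-30)
    sigma2 = np.maximum(sig / np.maximum(counts, 1.0), floor)
    return NoiseSpectrum(sigma2, counts, kmax, 2.0 * np.pi / L)


def normalized_euclid_cost(
    particle_ft: np.ndarray,
    reference_ft: np.ndarray,
    ctf: np.ndarray | None,
    shift,
    noise: NoiseSpectrum,
) -> CostValue:
    """The [0, 1]-normalized noise-weighted Euclidean cost (see module doc)."""
    L, sel, lab, counts, hx, hy, p, r = _prep(
        particle_ft, reference_ft, ctf, shift, noise.kmax
    )
    if not np.any(np.abs(r) > 0):
        raise ValueError("degenerate all-zero reference")
    w = noise.weights[lab]
    num = np.sum(w * np.abs(p - r) ** 2)
    den = 2.0 * np.sum(w * (np.abs(p) ** 2 + np.abs(r) ** 2))
    if den <= 0:
        return CostValue(0.0)
    return CostValue(num / den)


def shift_gradient(
    particle_ft: np.ndarray,
    reference_ft: np.ndarray,
    ctf: np.ndarray | None,
    shift,
    noise: NoiseSpectrum,
) -> np.ndarray:
    """Analytic gradient of the cost with respect to the 2D shift.

    Uses dP~/ds_j = +i c h_j P~ (the recentering ramp is exp(+i c h . s));
    the denominator is shift-invariant since the ramp has unit modulus.
    """
    L, sel, lab, counts, hx, hy, p, r = _prep(
        particle_ft, reference_ft, ctf, shift, noise.kmax
    )
    w = noise.weights[lab]
    den = 2.0 * np.sum(w * (np.abs(p) ** 2 + np.abs(r) ** 2))
    c = noise.phase_constant
    diff = p - r
    # d num / d s_j = sum w * 2 Re( conj(diff) * (i c h_j p) )
    gx = 2.0 * np.sum(w * np.real(np.conj(diff) * (1j * c * hx * p)))
    gy = 2.0 * np.sum(w * np.real(np.conj(diff) * (1j * c * hy * p)))
    return np.array([gx, gy]) / den


def optimize_shift(
    particle_ft: np.ndarray,
    reference_ft: np.ndarray,
    ctf: np.ndarray | None,
    shift0,
    noise: NoiseSpectrum,
    bound: float,
) -> tuple[np.ndarray, CostValue]:
    """Bounded L-BFGS-B minimization of the cost over the origin shift.

    Returns (shift*, cost*) with cost* <= cost(shift0) and |shift*| within
    the per-axis bound box. Non-finite evaluations fall back to shift0.
    """
    shift0 = np.asarray(shift0, dtype=float)
    if bound <= 0:
        return np.zeros(2), normalized_euclid_cost(
            particle_ft, reference_ft, ctf, np.zeros(2), noise
        )

    def fun(s):
        d = normalized_euclid_cost(particle_ft, reference_ft, ctf, s, noise).d
        g = shift_gradient(particle_ft, reference_ft, ctf, s, noise)
        return d, g

    try:
        res = minimize(
            fun,
            shift0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-bound, bound)] * 2,
            options={"maxiter": 100, "gtol": 1e-6, "ftol": 1e-12},
        )
        cost0 = normalized_euclid_cost(particle_ft, reference_ft, ctf, shift0, noise).d
        if not np.isfinite(res.fun) or res.fun > cost0:
            return shift0, CostValue(cost0)
        return res.x, CostValue(float(res.fun))
    except (ValueError, FloatingPointError):
        return shift0, normalized_euclid_cost(particle_ft, reference_ft, ctf, shift0, noise)


# ---------------------------------------------------------------------------
# vectorized ring-weighted helpers used by the polar matching fast path
# ---------------------------------------------------------------------------


def polar_noise_spectra(
    particle_polar: np.ndarray,
    reference_polar: np.ndarray,
    ctf_polar: np.ndarray,
    ring_counts: np.ndarray,
) -> np.ndarray:
    """sigma2 per ring for a batch, from polar samples (N, R, A).

    The uniform angular samples estimate the same per-ring mean residual
    power as the Cartesian definition.
    """
    resid = np.abs(particle_polar - ctf_polar * reference_polar) ** 2
    sigma2 = resid.mean(axis=2)
    floor = SIGMA2_FLOOR_FRAC * max(float(np.mean(np.abs(particle_polar) ** 2)), 1e-30)
    return np.maximum(sigma2, floor)
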