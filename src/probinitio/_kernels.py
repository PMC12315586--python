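"""Numba-compiled inner loops: Kaiser-Bessel gridding and ICM sweeps.

All kernels operate on centered Fourier grids (origin at index ``G // 2``)
with float32/complex64 arrays. The Kaiser-Bessel window has full width
``W`` grid points; points are tapped over ``ceil(W)`` neighbours per axis.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Full window width in (oversampled) Fourier pixels.
KB_WIDTH = 3.0


_LUT_N = 8192


def make_kb_lut(beta: float) -> np.ndarray:
    """Tabulated KB window over offsets [-W/2, W/2] for fast interpolation."""
    half = KB_WIDTH / 2.0
    u = np.linspace(-half, half, _LUT_N)
    t = np.maximum(1.0 - (u / half) ** 2, 0.0)
    return (np.i0(beta * np.sqrt(t)) / np.i0(beta)).astype(np.float64)


@njit(cache=False, fastmath=True, inline="always")
def _kb(u: float, half: float, lut) -> float:
    # linear interpolation into the tabulated window
    if u <= -half or u >= half:
        return 0.0
    x = (u + half) * (_LUT_N - 1) / (2.0 * half)
    i = int(x)
    f = x - i
    return lut[i] * (1.0 - f) + lut[i + 1] * f


@njit(cache=False, fastmath=True)
def interpolate_points_3d(data, pts, lut):
    """KB-interpolate complex volume ``data`` (G^3, centered) at ``pts`` (N,3).

    Points are in centered grid coordinates (0 at the Fourier origin).
    Out-of-grid points give 0.
    """
    G = data.shape[0]
    c = G // 2
    half = KB_WIDTH / 2.0
    n = pts.shape[0]
    out = np.zeros(n, dtype=np.complex64)
    for i in range(n):
        x = pts[i, 0]
        y = pts[i, 1]
        z = pts[i, 2]
        ix0 = int(math.floor(x - half)) + 1
        iy0 = int(math.floor(y - half)) + 1
        iz0 = int(math.floor(z - half)) + 1
        acc_r = 0.0
        acc_i = 0.0
        for a in range(ix0, ix0 + 3):
            wx = _kb(a - x, half, lut)
            if wx == 0.0:
                continue
            ia = a + c
            if ia < 0 or ia >= G:
                continue
            for b in range(iy0, iy0 + 3):
                wy = _kb(b - y, half, lut)
                if wy == 0.0:
                    continue
                ib = b + c
                if ib < 0 or ib >= G:
                    continue
                wxy = wx * wy
                for d in range(iz0, iz0 + 3):
                    wz = _kb(d - z, half, lut)
                    if wz == 0.0:
                        continue
                    idd = d + c
                    if idd < 0 or idd >= G:
                        continue
                    w = wxy * wz
                    v = data[ia, ib, idd]
                    acc_r += w * v.real
                    acc_i += w * v.imag
        out[i] = acc_r + 1j * acc_i
    return out


@njit(cache=False, fastmath=True)
def interpolate_points_2d(data, pts, lut):
    """KB-interpolate complex image ``data`` (G^2, centered) at ``pts`` (N,2)."""
    G = data.shape[0]
    c = G // 2
    half = KB_WIDTH / 2.0
    n = pts.shape[0]
    out = np.zeros(n, dtype=np.complex64)
    for i in range(n):
        x = pts[i, 0]
        y = pts[i, 1]
        ix0 = int(math.floor(x - half)) + 1
        iy0 = int(math.floor(y - half)) + 1
        acc_r = 0.0
        acc_i = 0.0
        for a in range(ix0, ix0 + 3):
            wx = _kb(a - x, half, lut)
            if wx == 0.0:
                continue
            ia = a + c
            if ia < 0 or ia >= G:
                continue
            for b in range(iy0, iy0 + 3):
                wy = _kb(b - y, half, lut)
                if wy == 0.0:
                    continue
                ib = b + c
                if ib < 0 or ib >= G:
                    continue
                w = wx * wy
                v = data[ia, ib]
                acc_r += w * v.real
                acc_i += w * v.imag
        out[i] = acc_r + 1j * acc_i
    return out


@njit(cache=False, fastmath=True)
def insert_points_3d(data, wgt, pts, vals, vwgt, lut):
    """Adjoint of :func:`interpolate_points_3d`.

    Scatters ``vals[i] * w_tap`` into ``data`` and ``vwgt[i] * w_tap`` into
    ``wgt`` around each point. Returns the number of points clipped because
    they fell outside the grid entirely.
    """
    G = data.shape[0]
    c = G // 2
    half = KB_WIDTH / 2.0
    n = pts.shape[0]
    clipped = 0
    for i in range(n):
        x = pts[i, 0]
        y = pts[i, 1]
        z = pts[i, 2]
        wrote = False
        ix0 = int(math.floor(x - half)) + 1
        iy0 = int(math.floor(y - half)) + 1
        iz0 = int(math.floor(z - half)) + 1
        vr = vals[i].real
        vi = vals[i].imag
        vw = vwgt[i]
        for a in range(ix0, ix0 + 3):
            wx = _kb(a - x, half, lut)
            if wx == 0.0:
                continue
            ia = a + c
            if ia < 0 or ia >= G:
                continue
            for b in range(iy0, iy0 + 3):
                wy = _kb(b - y, half, lut)
                if wy == 0.0:
                    continue
                ib = b + c
                if ib < 0 or ib >= G:
                    continue
                wxy = wx * wy
                for d in range(iz0, iz0 + 3):
                    wz = _kb(d - z, half, lut)
                    if wz == 0.0:
                        continue
                    idd = d + c
                    if idd < 0 or idd >= G:
                        continue
                    w = wxy * wz
                    data[ia, ib, idd] += np.complex64((w * vr) + 1j * (w * vi))
                    wgt[ia, ib, idd] += np.float32(w * vw)
                    wrote = True
        if not wrote:
            clipped += 1
    return clipped


@njit(cache=False, fastmath=True)
def insert_slices_batch(data, wgt, rots, pts2d, vals, vwgt, lut):
    """Insert many CTF-premultiplied slices into a Fourier accumulator.

    rots : (N, 3, 3) rotation matrices (slice pixel h -> 3D point R @ h)
    pts2d : (P, 2) in-slice coordinates (already scaled by the oversampling)
    vals : (N, P) complex slice values, vwgt : (N, P) insertion weights
    """
    n = rots.shape[0]
    p = pts2d.shape[0]
    pts3 = np.empty((p, 3), dtype=np.float32)
    total_clipped = 0
    for i in range(n):
        r = rots[i]
        for j in range(p):
            hx = pts2d[j, 0]
            hy = pts2d[j, 1]
            pts3[j, 0] = r[0, 0] * hx + r[0, 1] * hy
            pts3[j, 1] = r[1, 0] * hx + r[1, 1] * hy
            pts3[j, 2] = r[2, 0] * hx + r[2, 1] * hy
        total_clipped += insert_points_3d(data, wgt, pts3, vals[i], vwgt[i], lut)
    return total_clipped


@njit(cache=False, fastmath=True)
def extract_sections_batch(data, rots, pts2d, lut):
    """Extract central sections at many rotations; returns (N, P) complex."""
    n = rots.shape[0]
    p = pts2d.shape[0]
    out = np.empty((n, p), dtype=np.complex64)
    pts3 = np.empty((p, 3), dtype=np.float32)
    for i in range(n):
        r = rots[i]
        for j in range(p):
            hx = pts2d[j, 0]
            hy = pts2d[j, 1]
            pts3[j, 0] = r[0, 0] * hx + r[0, 1] * hy
            pts3[j, 1] = r[1, 0] * hx + r[1, 1] * hy
            pts3[j, 2] = r[2, 0] * hx + r[2, 1] * hy
        out[i] = interpolate_points_3d(data, pts3, lut)
    return out


@njit(cache=False, fastmath=True)
def icm_sweeps(vol, obs, sigma2, levels, lam, max_sweeps):
    """Raster-scan ICM on a cubic map with 6-neighbour quadratic coupling.

    Each voxel is set to the quantized level nearest the conditional optimum
    of (v - obs)^2 / (2 sigma2) + lam * sum_j (v - v_j)^2. Returns the
    per-sweep global energies (pair terms counted once) and sweeps executed.
    """
    L = vol.shape[0]
    nl = levels.shape[0]
    energies = np.empty(max_sweeps, dtype=np.float64)
    nsw = 0
    for sweep in range(max_sweeps):
        changed = 0
        for i in range(L):
            for j in range(L):
                for k in range(L):
                    s = 0.0
                    n = 0
                    if i > 0:
                        s += vol[i - 1, j, k]
                        n += 1
                    if i < L - 1:
                        s += vol[i + 1, j, k]
                        n += 1
                    if j > 0:
                        s += vol[i, j - 1, k]
                        n += 1
                    if j < L - 1:
                        s += vol[i, j + 1, k]
                        n += 1
                    if k > 0:
                        s += vol[i, j, k - 1]
                        n += 1
                    if k < L - 1:
                        s += vol[i, j, k + 1]
                        n += 1
                    inv = 1.0 / sigma2[i, j, k]
                    vstar = (obs[i, j, k] * inv + 2.0 * lam * s) / (inv + 2.0 * lam * n)
                    # nearest level by binary search
                    lo = 0
                    hi = nl - 1
                    while hi - lo > 1:
                        mid = (lo + hi) // 2
                        if levels[mid] < vstar:
                            lo = mid
                        else:
                            hi = mid
                    if abs(levels[hi] - vstar) < abs(levels[lo] - vstar):
                        best = levels[hi]
                    else:
                        best = levels[lo]
                    if best != vol[i, j, k]:
                        changed += 1
                    vol[i, j, k] = best
        # global energy: data term + each unordered pair once (+x,+y,+z links)
        e = 0.0
        for i in range(L):
            for j in range(L):
                for k in range(L):
                    dv = vol[i, j, k] - obs[i, j, k]
                    e += dv * dv / (2.0 * sigma2[i, j, k])
                    if i < L - 1:
                        d = vol[i, j, k] - vol[i + 1, j, k]
                        e += lam * d * d
                    if j < L - 1:
                        d = vol[i, j, k] - vol[i, j + 1, k]
                        e += lam * d * d
                    if k < L - 1:
                        d = vol[i, j, k] - vol[i, j, k + 1]
                        e += lam * d * d
        energies[nsw] = e
        nsw += 1
        if changed == 0:
            break
    return energies[:nsw], nsw
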