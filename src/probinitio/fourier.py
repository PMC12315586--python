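"""FFT conventions, gridding slice extraction/insertion, CTF, FSC and masks.

FFT discipline (documented once, used everywhere): real-space and Fourier
arrays are both *centered* — the origin sits at index ``n // 2`` — and
transforms are taken as ``fftshift(fftn(ifftshift(x)))``. The forward
transform is unnormalized, the inverse carries ``1/N`` (numpy default).
Fourier coordinates are integer pixel indices ``h = i - n//2``.

Gridding uses a Kaiser-Bessel window of full width 3 on a grid internally
oversampled by ~1.5x; the real-space correction (division by the window
transform) is applied before the forward FFT for extraction and after the
inverse FFT for reconstruction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _kernels
from ._kernels import KB_WIDTH

#: default internal oversampling factor of gridding Fourier grids
OVERSAMPLING = 2.0


def kb_beta(osf: float = OVERSAMPLING, width: float = KB_WIDTH) -> float:
    """Kaiser-Bessel shape parameter (Beatty et al. optimal for gridding)."""
    return math.pi * math.sqrt((width / osf * (osf - 0.5)) ** 2 - 0.8)


def fft_friendly_size(n: int) -> int:
    """Smallest even 5-smooth integer >= n."""
    m = max(int(math.ceil(n)), 2)
    if m % 2:
        m += 1
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 2


def ftn(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))


def iftn(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x)))


def ft2(x: np.ndarray) -> np.ndarray:
    """Centered 2D FFT over the last two axes (stacks allowed)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1))), axes=(-2, -1)
    )


def ift2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1))), axes=(-2, -1)
    )


def kb_window_ft(x: np.ndarray, grid_size: int, beta: float | None = None) -> np.ndarray:
    """Continuous transform of the KB window at real-space coords ``x``.

    ``x`` in voxels of a grid of ``grid_size`` points:
    w_hat(x) = (W / I0(beta)) * sinh(z) / z, z = sqrt(beta^2 - (pi W x / G)^2)
    (sin for imaginary argument). This is the gridding correction divisor.
    """
    if beta is None:
        beta = kb_beta()
    half = KB_WIDTH / 2.0
    arg = beta**2 - (2.0 * np.pi * half * np.asarray(x, dtype=float) / grid_size) ** 2
    out = np.empty_like(arg)
    pos = arg > 0
    z = np.sqrt(np.abs(arg))
    out[pos] = np.sinh(z[pos]) / z[pos]
    out[~pos] = np.sinc(z[~pos] / np.pi)
    return out * (2.0 * half / np.i0(beta))


def _kb_correction_3d(L: int, G: int, beta: float) -> np.ndarray:
    x = np.arange(L) - L // 2
    c1 = kb_window_ft(x, G, beta)
    return c1[:, None, None] * c1[None, :, None] * c1[None, None, :]


def _kb_correction_2d(L: int, G: int, beta: float) -> np.ndarray:
    x = np.arange(L) - L // 2
    c1 = kb_window_ft(x, G, beta)
    return c1[:, None] * c1[None, :]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DensityVolume:
    """Real-space cubic density map."""

    grid: np.ndarray  # (L, L, L) float32
    pixel_size: float  # Angstrom / voxel

    def __post_init__(self):
        self.grid = np.ascontiguousarray(self.grid, dtype=np.float32)
        L = self.grid.shape[0]
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("volume must be cubic")
        if L % 2 or L < 16:
            raise ValueError(f"box must be even and >= 16, got {L}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("volume contains non-finite values")

    @property
    def box(self) -> int:
        return self.grid.shape[0]

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.pixel_size)


@dataclass
class CTFParams:
    """Standard weak-phase CTF model parameters."""

    defocus_u: float  # Angstrom, positive = underfocus
    defocus_v: float  # Angstrom
    astig_angle: float = 0.0  # degrees
    cs: float = 2.7  # mm
    voltage: float = 300.0  # kV
    amp_contrast: float = 0.1  # fraction in [0, 1]
    flip_sign: bool = False  # phase convention: True negates the value

    def __post_init__(self):
        if self.defocus_u <= 0 or self.defocus_v <= 0:
            raise ValueError("defocus must be positive")
        if not 0.0 <= self.amp_contrast <= 1.0:
            raise ValueError("amp_contrast must be in [0, 1]")

    @property
    def wavelength(self) -> float:
        """Relativistic electron wavelength in Angstrom."""
        u = self.voltage * 1e3
        return 12.2643247 / math.sqrt(u * (1.0 + u * 0.978476e-6))


def ctf_eval(params: CTFParams, freq, azimuth=0.0):
    """CTF value at spatial frequency ``freq`` (1/A) and azimuth (rad).

    Sign convention: value at freq 0 is ``-amp_contrast`` (so protein appears
    dark on a bright background in the simulated images); ``flip_sign``
    negates. Values always lie in [-1, 1].
    """
    freq = np.asarray(freq, dtype=float)
    if np.any(freq < 0):
        raise ValueError("freq must be >= 0")
    lam = params.wavelength
    dz = 0.5 * (
        params.defocus_u
        + params.defocus_v
        + (params.defocus_u - params.defocus_v)
        * np.cos(2.0 * (np.asarray(azimuth) - np.deg2rad(params.astig_angle)))
    )
    chi = np.pi * lam * freq**2 * dz - 0.5 * np.pi * params.cs * 1e7 * lam**3 * freq**4
    a = params.amp_contrast
    val = -(math.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))
    return -val if params.flip_sign else val


def ctf_image(params: CTFParams, box: int, pixel_size: float) -> np.ndarray:
    """CTF sampled on the centered Fourier grid of an LxL image."""
    h = np.arange(box) - box // 2
    hx, hy = np.meshgrid(h, h, indexing="ij")
    freq = np.sqrt(hx**2 + hy**2) / (box * pixel_size)
    az = np.arctan2(hy, hx)
    return ctf_eval(params, freq, az).astype(np.float32)


@dataclass
class Orientation:
    """Grid orientation: S2 direction index, in-plane index, origin shift."""

    m: int
    n: int
    shift: np.ndarray = field(default_factory=lambda: np.zeros(2))
    state: int = 0


@dataclass
class PolarSection:
    """Central Fourier section resampled on concentric rings."""

    values: np.ndarray  # (n_rings, n_angles) complex64
    ring_radii: np.ndarray  # Fourier pixels, strictly increasing
    ring_counts: np.ndarray  # Cartesian components per ring

    def __post_init__(self):
        if np.any(np.diff(self.ring_radii) <= 0):
            raise ValueError("ring radii must be strictly increasing")
        if np.any(self.ring_counts <= 0):
            raise ValueError("ring counts must be positive")


# ---------------------------------------------------------------------------
# Fourier volume with gridding accumulators
# ---------------------------------------------------------------------------


class FourierVolume:
    """Complex 3D Fourier grid supporting KB slice extraction and insertion.

    Holds either the oversampled transform of a density (for extraction) or
    numerator/weight accumulators (for reconstruction). ``scale`` converts
    original-box Fourier pixel coordinates into internal grid coordinates.
    """

    def __init__(self, data, weight, box, pixel_size, osf_grid):
        self.data = data  # (G, G, G) complex64, centered
        self.weight = weight  # (G, G, G) float32 or None
        self.box = int(box)
        self.pixel_size = float(pixel_size)
        self.grid_size = data.shape[0]
        self.scale = self.grid_size / float(box)
        self.beta = kb_beta(self.scale)
        self.kb_lut = _kernels.make_kb_lut(self.beta)
        del osf_grid

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_density(cls, vol: DensityVolume, osf: float = OVERSAMPLING) -> "FourierVolume":
        L = vol.box
        G = fft_friendly_size(L * osf)
        beta = kb_beta(G / L)
        corr = _kb_correction_3d(L, G, beta)
        padded = np.zeros((G, G, G), dtype=np.complex64)
        lo = G // 2 - L // 2
        padded[lo : lo + L, lo : lo + L, lo : lo + L] = vol.grid / corr
        data = ftn(padded).astype(np.complex64)
        return cls(data, None, L, vol.pixel_size, osf)

    @classmethod
    def zeros(cls, box: int, pixel_size: float, osf: float = OVERSAMPLING) -> "FourierVolume":
        G = fft_friendly_size(box * osf)
        return cls(
            np.zeros((G, G, G), dtype=np.complex64),
            np.zeros((G, G, G), dtype=np.float32),
            box,
            pixel_size,
            osf,
        )

    # -- extraction ---------------------------------------------------------

    def _check_rotation(self, rot: np.ndarray):
        rot = np.asarray(rot, dtype=float)
        if rot.shape != (3, 3) or not np.allclose(rot @ rot.T, np.eye(3), atol=1e-5):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        return rot

    def extract_central_slice(self, rot: np.ndarray) -> np.ndarray:
        """Gridding-interpolated central section; (box, box) complex64.

        Slice pixel (i, j) holds the transform at ``rot @ (hx, hy, 0)`` with
        ``hx = i - box//2`` etc., matching the centered FT of an image.
        """
        rot = self._check_rotation(rot)
        pts = _slice_grid(self.box) * self.scale
        out = _kernels.extract_sections_batch(
            self.data, np.ascontiguousarray(rot[None].astype(np.float32)), pts, self.kb_lut
        )
        return out[0].reshape(self.box, self.box)

    def extract_slices(self, rots: np.ndarray, pts2d: np.ndarray | None = None) -> np.ndarray:
        """Batch extraction at (N,3,3) rotations; (N, P) complex64."""
        if pts2d is None:
            pts2d = _slice_grid(self.box)
        return _kernels.extract_sections_batch(
            self.data,
            np.ascontiguousarray(np.asarray(rots, dtype=np.float32)),
            np.ascontiguousarray(pts2d * self.scale, dtype=np.float32),
            self.kb_lut,
        )

    def extract_polar_sections(
        self, dir_rots: np.ndarray, ring_radii: np.ndarray, n_angles: int
    ) -> np.ndarray:
        """Polar sections for many S2 directions; (M, n_rings, n_angles).

        In-plane rotation by ``k * 360/n_angles`` degrees of a section equals
        a cyclic shift by ``k`` along the angular axis.
        """
        ring_radii = np.asarray(ring_radii, dtype=float)
        if np.any(ring_radii > self.box // 2):
            raise ValueError("ring radius beyond Nyquist")
        pts = _polar_grid(tuple(np.round(ring_radii, 6)), n_angles)
        out = self.extract_slices(np.asarray(dir_rots), pts)
        return out.reshape(len(dir_rots), len(ring_radii), n_angles)

    # -- insertion ----------------------------------------------------------

    def insert_slice(
        self,
        particle_ft: np.ndarray,
        ctf: np.ndarray | None,
        rot: np.ndarray,
        shift: np.ndarray | None = None,
        weight: float = 1.0,
        max_radius: float | None = None,
    ) -> int:
        """Insert one CTF-premultiplied slice; adjoint of extraction.

        Accumulates ``kernel * H * P_shifted`` into the numerator and
        ``kernel * H^2 * weight`` into the weight field. The particle FT is
        phase-shifted by ``-shift`` before insertion. Returns the number of
        silently clipped out-of-grid samples.
        """
        if weight < 0:
            raise ValueError("weight must be >= 0")
        rot = self._check_rotation(rot)
        return self.insert_slices(
            particle_ft[None],
            None if ctf is None else ctf[None],
            rot[None],
            None if shift is None else np.asarray(shift, dtype=float)[None],
            np.array([weight]),
            max_radius,
        )

    def insert_slices(self, particle_fts, ctfs, rots, shifts, weights, max_radius=None):
        """Batch slice insertion (see :meth:`insert_slice`)."""
        L = self.box
        n = len(particle_fts)
        if max_radius is None:
            max_radius = L // 2
        pts, sel = _slice_grid_disc(L, float(max_radius))
        vals = np.ascontiguousarray(
            particle_fts.reshape(n, -1)[:, sel], dtype=np.complex64
        )
        if shifts is not None:
            vals = vals * phase_ramp(pts, -np.asarray(shifts), L)
        w = np.asarray(weights, dtype=np.float32)
        if ctfs is not None:
            h = np.ascontiguousarray(ctfs.reshape(n, -1)[:, sel], dtype=np.float32)
            vals = vals * h
            vwgt = (h * h) * w[:, None]
        else:
            vwgt = np.broadcast_to(w[:, None], vals.shape).copy()
        vals = vals * w[:, None]
        return _kernels.insert_slices_batch(
            self.data,
            self.weight,
            np.ascontiguousarray(np.asarray(rots, dtype=np.float32)),
            np.ascontiguousarray(pts * self.scale, dtype=np.float32),
            np.ascontiguousarray(vals, dtype=np.complex64),
            np.ascontiguousarray(vwgt, dtype=np.float32),
            self.kb_lut,
        )

    def normalize(self, floor_frac: float = 1e-4) -> DensityVolume:
        """Weighted division, inverse FT, gridding correction and crop."""
        if self.weight is None:
            raise ValueError("not an accumulator volume")
        wmax = float(self.weight.max())
        if wmax <= 0:
            raise ValueError("empty accumulator")
        num = self.data / (self.weight + floor_frac * wmax)
        return self._to_density(num)

    def _to_density(self, num: np.ndarray) -> DensityVolume:
        G = self.grid_size
        L = self.box
        vol = np.real(iftn(num))
        lo = G // 2 - L // 2
        vol = vol[lo : lo + L, lo : lo + L, lo : lo + L]
        # weight division already normalizes the kernel mass; deconvolve only
        # the shape of the window transform
        corr = _kb_correction_3d(L, G, self.beta)
        vol = vol / (corr / corr[L // 2, L // 2, L // 2])
        return DensityVolume(vol.astype(np.float32), self.pixel_size)

    def hermitian_error(self) -> float:
        """Max relative deviation from F(-h) = conj(F(h))."""
        d = self.data
        flipped = d[::-1, ::-1, ::-1] if d.shape[0] % 2 else d
        if d.shape[0] % 2 == 0:
            flipped = np.roll(d[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
        scale = np.abs(d).max() or 1.0
        return float(np.abs(flipped.conj() - d).max() / scale)


@lru_cache(maxsize=8)
def _slice_grid(L: int) -> np.ndarray:
    h = np.arange(L, dtype=np.float32) - L // 2
    hx, hy = np.meshgrid(h, h, indexing="ij")
    return np.ascontiguousarray(np.stack([hx.ravel(), hy.ravel()], axis=1))


@lru_cache(maxsize=32)
def _slice_grid_disc(L: int, rmax: float):
    pts = _slice_grid(L)
    sel = np.flatnonzero(np.hypot(pts[:, 0], pts[:, 1]) <= rmax + 1e-6)
    return np.ascontiguousarray(pts[sel]), sel


@lru_cache(maxsize=64)
def _polar_grid(radii: tuple, n_angles: int) -> np.ndarray:
    th = np.arange(n_angles) * (2 * np.pi / n_angles)
    r = np.asarray(radii, dtype=np.float64)
    x = r[:, None] * np.cos(th)[None, :]
    y = r[:, None] * np.sin(th)[None, :]
    return np.ascontiguousarray(
        np.stack([x.ravel(), y.ravel()], axis=1), dtype=np.float32
    )


def phase_ramp(pts: np.ndarray, shifts: np.ndarray, box: int) -> np.ndarray:
    """Translation factor exp(-i * c * h . s), c = 2*pi/box.

    Multiplying a centered FT by ``phase_ramp(pts, s)`` translates the image
    content by ``+s`` pixels; recentering a particle whose content sits at
    ``+s`` therefore uses ``phase_ramp(pts, -s)``.
    """
    c = 2.0 * np.pi / box
    shifts = np.atleast_2d(shifts)
    phase = c * (pts[:, 0] * shifts[:, 0:1] + pts[:, 1] * shifts[:, 1:2])
    return np.exp(-1j * phase).astype(np.complex64)


def shift_image_ft(img_ft: np.ndarray, shift, box: int | None = None) -> np.ndarray:
    """Translate a centered image FT by ``+shift`` pixels."""
    L = box or img_ft.shape[-1]
    pts = _slice_grid(L)
    ramp = phase_ramp(pts, np.asarray(shift, dtype=float), L)[0].reshape(L, L)
    return img_ft * ramp


# ---------------------------------------------------------------------------
# polar resampling of particle images
# ---------------------------------------------------------------------------


def image_polar_sections(
    images: np.ndarray, ring_radii: np.ndarray, n_angles: int, osf: float = OVERSAMPLING
) -> np.ndarray:
    """Polar Fourier sections of real images; (N, n_rings, n_angles).

    Images are gridding-precorrected, zero-padded by ``osf`` and transformed,
    then KB-resampled at the polar points, consistent with volume sections.
    """
    images = np.atleast_3d(images)
    if images.ndim == 2:
        images = images[None]
    n, L, _ = images.shape
    G = fft_friendly_size(L * osf)
    beta = kb_beta(G / L)
    lut = _kernels.make_kb_lut(beta)
    corr = _kb_correction_2d(L, G, beta)
    scale = G / L
    pts = np.ascontiguousarray(
        _polar_grid(tuple(np.round(np.asarray(ring_radii, float), 6)), n_angles) * scale
    )
    lo = G // 2 - L // 2
    out = np.empty((n, len(ring_radii), n_angles), dtype=np.complex64)
    padded = np.zeros((G, G), dtype=np.complex64)
    for i in range(n):
        padded[:] = 0
        padded[lo : lo + L, lo : lo + L] = images[i] / corr
        ft = ft2(padded).astype(np.complex64)
        out[i] = _kernels.interpolate_points_2d(ft, pts, lut).reshape(
            len(ring_radii), n_angles
        )
    return out


def cartesian_slice_to_polar(
    slice_ft: np.ndarray, ring_radii: np.ndarray, n_angles: int
) -> np.ndarray:
    """Bilinear polar readout of a centered Cartesian 2D section."""
    L = slice_ft.shape[0]
    pts = _polar_grid(tuple(np.round(np.asarray(ring_radii, float), 6)), n_angles)
    from scipy.ndimage import map_coordinates

    coords = (pts + L // 2).T  # rows index axis 0, matching the ij grid
    re = map_coordinates(slice_ft.real, coords, order=1, mode="constant")
    im = map_coordinates(slice_ft.imag, coords, order=1, mode="constant")
    return (re + 1j * im).reshape(len(ring_radii), n_angles).astype(np.complex64)


# ---------------------------------------------------------------------------
# FSC / FRC and masking
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def shell_index_map(shape: tuple) -> np.ndarray:
    axes = [np.arange(n) - n // 2 for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(sum(g.astype(float) ** 2 for g in grids))
    return np.round(r).astype(np.int32)


def fsc_curve(a, b) -> np.ndarray:
    """Fourier shell (3D) / ring (2D) correlation per integer shell.

    Accepts DensityVolume or ndarray; returns shells 0..L//2 inclusive.
    Empty-power shells give 0.
    """
    ga = a.grid if isinstance(a, DensityVolume) else np.asarray(a)
    gb = b.grid if isinstance(b, DensityVolume) else np.asarray(b)
    if ga.shape != gb.shape:
        raise ValueError("mismatched array shapes")
    if isinstance(a, DensityVolume) and isinstance(b, DensityVolume):
        if abs(a.pixel_size - b.pixel_size) > 1e-6:
            raise ValueError("mismatched pixel sizes")
    fa = ftn(ga)
    fb = ftn(gb)
    shells = shell_index_map(ga.shape)
    nshell = ga.shape[0] // 2 + 1
    sel = shells < nshell
    lab = shells[sel]
    cross = np.bincount(lab.ravel(), np.real(fa[sel] * np.conj(fb[sel])).ravel(), minlength=nshell)
    pa = np.bincount(lab.ravel(), np.abs(fa[sel]).ravel() ** 2, minlength=nshell)
    pb = np.bincount(lab.ravel(), np.abs(fb[sel]).ravel() ** 2, minlength=nshell)
    denom = np.sqrt(pa * pb)
    out = np.zeros(nshell)
    ok = denom > 0
    out[ok] = cross[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def resolution_at_threshold(curve: np.ndarray, threshold: float, box: int, pixel_size: float) -> float:
    """Resolution (A) where the curve first crosses ``threshold``.

    Linear interpolation between shells; if the curve never drops below the
    threshold the Nyquist resolution (2 * pixel size) is returned.
    """
    for k in range(1, len(curve)):
        if curve[k] < threshold:
            c0, c1 = curve[k - 1], curve[k]
            frac = (c0 - threshold) / (c0 - c1) if c0 != c1 else 0.0
            shell = (k - 1) + frac
            if shell <= 0:
                shell = 1e-3
            return float(box * pixel_size / shell)
    return 2.0 * pixel_size


def apply_spherical_mask(vol: DensityVolume, radius: float, edge: float = 4.0) -> DensityVolume:
    """Soft-edged spherical mask: 1 inside ``radius``, cosine ramp of width
    ``edge``, 0 beyond ``radius + edge``."""
    L = vol.box
    if radius + edge > L / 2:
        raise ValueError("mask radius + edge exceeds half box")
    m = spherical_mask(L, radius, edge)
    return DensityVolume(vol.grid * m, vol.pixel_size)


@lru_cache(maxsize=32)
def spherical_mask(L: int, radius: float, edge: float) -> np.ndarray:
    x = np.arange(L) - L // 2
    r = np.sqrt(
        x[:, None, None] ** 2.0 + x[None, :, None] ** 2.0 + x[None, None, :] ** 2.0
    )
    m = np.zeros((L, L, L), dtype=np.float32)
    m[r <= radius] = 1.0
    if edge > 0:
        band = (r > radius) & (r < radius + edge)
        m[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - radius) / edge))
    return m


def resample_volume(vol: DensityVolume, new_box: int) -> DensityVolume:
    """Fourier crop/pad to ``new_box``; pixel size rescales accordingly."""
    L = vol.box
    if new_box == L:
        return vol.copy()
    F = ftn(vol.grid)
    out = np.zeros((new_box,) * 3, dtype=complex)
    s = min(L, new_box)
    lo_o, lo_n = L // 2 - s // 2, new_box // 2 - s // 2
    sl_o = slice(lo_o, lo_o + s)
    sl_n = slice(lo_n, lo_n + s)
    out[sl_n, sl_n, sl_n] = F[sl_o, sl_o, sl_o]
    grid = np.real(iftn(out)) * (new_box**3 / L**3)
    return DensityVolume(grid.astype(np.float32), vol.pixel_size * L / new_box)


def fourier_crop_stack(fts: np.ndarray, new_box: int) -> np.ndarray:
    """Center-crop a stack of centered 2D FTs to ``new_box``."""
    L = fts.shape[-1]
    if new_box == L:
        return fts
    lo = L // 2 - new_box // 2
    return np.ascontiguousarray(fts[..., lo : lo + new_box, lo : lo + new_box])


def warn_clipped(n: int, context: str = ""):
    if n:
        warnings.warn(f"{n} Fourier samples clipped outside the grid {context}")
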