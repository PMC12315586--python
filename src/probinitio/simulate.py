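"""Synthetic single-particle data: phantoms, projections, CTF, noise, classes.

The generator emulates the inputs an ab initio reconstruction consumes:
a particle stack with known ("ground truth") orientations, shifts, defoci
and structural states, plus 2D-class metadata (class assignments, per-member
match scores and twofold cross-validated class FRC curves). Phantoms are
sums of 3D Gaussian blobs; multi-state variants share most of their blobs
and delete or displace the rest. Noise is additive white Gaussian, scaled so
the empirical signal-to-noise ratio (signal power / noise power inside the
particle mask) hits the requested SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._oracle import project_oracle
from .fourier import (
    CTFParams,
    DensityVolume,
    FourierVolume,
    _slice_grid,
    ctf_image,
    fsc_curve,
    ift2,
    phase_ramp,
    spherical_mask,
)
from .geometry import (
    fibonacci_sphere,
    geodesic_s2,
    matrix_to_euler_zyz,
    random_rotations,
    rot_z,
    symmetry_ops,
)
from .schedule import ClassInfo


@dataclass
class PhantomSpec:
    """Blob-phantom recipe; everything reproducible from the seed."""

    box: int = 48
    pixel_size: float = 2.0
    n_blobs: int = 22
    sigma_range: tuple = (1.2, 3.0)  # blob sigmas, voxels
    seed: int = 0
    symmetry: str | None = None  # impose a point group by symmetrization
    n_states: int = 1
    state_altered_frac: float = 0.3  # fraction of blobs deleted/moved per state


@dataclass
class GroundTruth:
    """Per-particle generating parameters."""

    rotations: np.ndarray  # (N, 3, 3)
    shifts: np.ndarray  # (N, 2) px
    states: np.ndarray  # (N,)
    ctf_params: list  # CTFParams per particle
    snr: float
    noise_sigma: float


def make_phantom(spec: PhantomSpec) -> list[DensityVolume]:
    """Sum-of-Gaussians phantom(s); returns one volume per structural state.

    State variants share at least ``1 - state_altered_frac`` of the blobs.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.box
    rmax = 0.8 * (L / 2) * 0.75  # keep blobs well inside the mask
    centers = rng.uniform(-rmax, rmax, size=(spec.n_blobs, 3))
    # reject blob centers outside the allowed sphere
    for i in range(spec.n_blobs):
        while np.linalg.norm(centers[i]) > rmax:
            centers[i] = rng.uniform(-rmax, rmax, size=3)
    sigmas = rng.uniform(*spec.sigma_range, size=spec.n_blobs)
    # equalize the blobs' zero-frequency contributions (a * sigma^3 ~ const)
    # so small sharp blobs keep measurable high-frequency power
    amps = rng.uniform(0.5, 1.0, size=spec.n_blobs) * (2.0 / sigmas) ** 3

    n_alter = int(round(spec.state_altered_frac * spec.n_blobs))
    vols = []
    for state in range(spec.n_states):
        c, s, a = centers.copy(), sigmas.copy(), amps.copy()
        if state > 0 and n_alter > 0:
            # delete a spatially coherent cluster of blobs (a "domain"), the
            # kind of compositional difference discrete states separate;
            # anchored at the most massive blob so the missing domain is a
            # major structural unit rather than scattered detail
            anchor = int(np.argmax(amps * sigmas**3))
            order = np.argsort(np.linalg.norm(centers - centers[anchor], axis=1))
            a[order[:n_alter]] = 0.0
        grid = _blob_grid(L, c, s, a)
        if spec.symmetry:
            grid = _symmetrize(grid, spec.symmetry)
        vols.append(DensityVolume(grid.astype(np.float32), spec.pixel_size))
    return vols


def _blob_grid(L, centers, sigmas, amps) -> np.ndarray:
    x = np.arange(L) - L // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    grid = np.zeros((L, L, L))
    for c, s, a in zip(centers, sigmas, amps):
        if a == 0:
            continue
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        grid += a * np.exp(-r2 / (2 * s * s))
    return grid


def _symmetrize(grid: np.ndarray, symmetry: str) -> np.ndarray:
    from scipy import ndimage

    ops = symmetry_ops(symmetry)
    L = grid.shape[0]
    c = L // 2
    center = np.array([c, c, c], dtype=float)
    out = np.zeros_like(grid)
    for op in ops:
        out += ndimage.affine_transform(
            grid, op, offset=center - op @ center, order=1, mode="constant"
        )
    return out / len(ops)


def simulate_particles(
    phantoms: list[DensityVolume],
    n: int,
    snr: float = np.inf,
    shift_sigma: float = 0.0,
    defocus_range: tuple = (8000.0, 20000.0),
    orientation_law: str = "uniform",
    seed: int = 0,
    state_fractions: np.ndarray | None = None,
    ctf_template: CTFParams | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """CTF-affected noisy projections with complete ground truth.

    Images are central-slice projections of the phantom transform, CTF
    multiplied, translated by a random Gaussian shift and degraded with
    white Gaussian noise calibrated against the measured signal power.
    """
    if not (snr > 0):
        raise ValueError("SNR must be > 0 (use inf for noise-free)")
    rng = np.random.default_rng(seed)
    L = phantoms[0].box
    apix = phantoms[0].pixel_size
    k = len(phantoms)
    if state_fractions is None:
        states = rng.integers(0, k, size=n)
    else:
        states = rng.choice(k, size=n, p=state_fractions)
    if orientation_law == "uniform":
        rots = random_rotations(n, rng)
    elif orientation_law == "preferred-axis":
        # cluster directions around z with in-plane uniform
        rots = random_rotations(n, rng)
        tilt = np.abs(rng.normal(0.0, 20.0, size=n))
        from .geometry import euler_zyz_to_matrix

        rots = np.stack(
            [
                euler_zyz_to_matrix(
                    rng.uniform(0, 360), t, rng.uniform(0, 360)
                )
                for t in tilt
            ]
        )
    else:
        raise ValueError(f"unknown orientation law: {orientation_law}")
    shifts = (
        rng.normal(0.0, shift_sigma, size=(n, 2)) if shift_sigma > 0 else np.zeros((n, 2))
    )

    base = ctf_template or CTFParams(defocus_u=15000, defocus_v=15000)
    defoci = rng.uniform(*defocus_range, size=n)
    astig = rng.uniform(0.0, 0.1 * defoci)
    angles = rng.uniform(0.0, 180.0, size=n)
    ctfs = [
        CTFParams(
            defocus_u=defoci[i] + astig[i] / 2,
            defocus_v=defoci[i] - astig[i] / 2,
            astig_angle=angles[i],
            cs=base.cs,
            voltage=base.voltage,
            amp_contrast=base.amp_contrast,
        )
        for i in range(n)
    ]

    fvols = [FourierVolume.from_density(p) for p in phantoms]
    pts = _slice_grid(L)
    clean = np.empty((n, L, L), dtype=np.float32)
    for i in range(n):
        sl = fvols[states[i]].extract_slices(rots[i][None])[0]
        h = ctf_image(ctfs[i], L, apix).ravel()
        sl = sl * h
        if np.any(shifts[i] != 0):
            sl = sl * phase_ramp(pts, shifts[i], L)[0]
        clean[i] = np.real(ift2(sl.reshape(L, L)))

    mask = spherical_mask(L, 0.45 * L, max(2.0, 0.05 * L))[:, :, L // 2] > 0.5
    signal_power = float(np.mean(clean[:, mask] ** 2))
    if np.isinf(snr):
        noise_sigma = 0.0
        stack = clean.copy()
    else:
        noise_sigma = float(np.sqrt(signal_power / snr))
        stack = clean + rng.normal(0.0, noise_sigma, size=clean.shape).astype(np.float32)
    truth = GroundTruth(rots, shifts, states, ctfs, snr, noise_sigma)
    return stack, truth


def measured_snr(stack: np.ndarray, clean: np.ndarray) -> float:
    """Empirical SNR from a noisy stack and its noise-free twin."""
    L = stack.shape[-1]
    mask = spherical_mask(L, 0.45 * L, max(2.0, 0.05 * L))[:, :, L // 2] > 0.5
    sig = float(np.mean(clean[:, mask] ** 2))
    noi = float(np.mean((stack - clean)[:, mask] ** 2))
    return sig / noi


def make_class_metadata(
    stack: np.ndarray,
    truth: GroundTruth,
    n_classes: int,
    seed: int = 0,
    phantoms: list[DensityVolume] | None = None,
    register_psi_sigma: float = 0.0,
    register_shift_sigma: float = 0.0,
) -> list[ClassInfo]:
    """Synthetic 2D-class metadata emulating upstream 2D analysis.

    Particles are grouped by nearest of ``n_classes`` template projection
    directions. The 2D classifier is assumed converged: each member is
    registered onto the class's central view, so a member's aligned image is
    the template projection plus that member's own noise realization,
    degraded by residual registration errors (Gaussian in-plane rotation
    ``register_psi_sigma`` deg and shift ``register_shift_sigma`` px, the
    accuracy a 2D alignment at this noise level achieves). The class score
    is the masked correlation of the aligned member with the noise-free
    class average, and the class FRC is the ring correlation of the
    even/odd half averages — noise-, size- and alignment-limited, like the
    twofold cross-validated curves a converged 2D analysis reports.
    """
    n, L, _ = stack.shape
    if n_classes > n:
        raise ValueError("more classes than particles")
    if phantoms is None:
        raise ValueError("phantoms required to render class template views")
    templates = fibonacci_sphere(n_classes)
    proj_dirs = truth.rotations[:, :, 2]  # R @ z_hat
    ang = geodesic_s2(proj_dirs[:, None, :], templates[None, :, :])
    labels = np.argmin(ang, axis=1)

    # noise realizations, independent of alignment
    fvols = [FourierVolume.from_density(p) for p in phantoms]
    pts = _slice_grid(L)
    noise = np.empty_like(stack, dtype=np.float64)
    for i in range(n):
        sl = fvols[truth.states[i]].extract_slices(truth.rotations[i][None])[0]
        h = ctf_image(truth.ctf_params[i], L, phantoms[0].pixel_size).ravel()
        sl = sl * h
        if np.any(truth.shifts[i] != 0):
            sl = sl * phase_ramp(pts, truth.shifts[i], L)[0]
        noise[i] = stack[i] - np.real(ift2(sl.reshape(L, L)))

    from scipy import ndimage

    from .geometry import direction_to_matrix

    rng = np.random.default_rng(seed)
    mask = spherical_mask(L, 0.4 * L, max(2.0, 0.05 * L))[:, :, L // 2] > 0.5
    classes = []
    for cid in range(n_classes):
        members = np.flatnonzero(labels == cid)
        if len(members) == 0:
            continue
        rot = direction_to_matrix(templates[cid])
        views = []
        for k in fvols:
            sl = k.extract_slices(rot[None])[0].reshape(L, L)
            views.append(np.real(ift2(sl)))
        # aligned member = its state's template view, mis-registered by the
        # residual 2D alignment error, plus the member's own noise
        mis = []
        for i in members:
            v = views[truth.states[i]]
            if register_psi_sigma > 0:
                v = ndimage.rotate(
                    v, rng.normal(0.0, register_psi_sigma), reshape=False, order=1
                )
            if register_shift_sigma > 0:
                v = ndimage.shift(v, rng.normal(0.0, register_shift_sigma, 2), order=1)
            mis.append(v)
        aligned = np.stack([m_ + noise[i] for m_, i in zip(mis, members)])
        clean_avg = np.mean(mis, axis=0)
        scores = np.array([_masked_corr(a[mask], clean_avg[mask]) for a in aligned])
        even = aligned[0::2].mean(axis=0)
        odd = aligned[1::2].mean(axis=0) if len(members) > 1 else even
        frc = fsc_curve(even, odd)
        classes.append(ClassInfo(cid, members, scores, frc))
    return classes


def _masked_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt(np.sum(a * a) * np.sum(b * b))
    return float(np.sum(a * b) / den) if den > 0 else 0.0


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground truth as a particle-table-like DataFrame (degrees / pixels)."""
    eul = np.array([matrix_to_euler_zyz(r) for r in truth.rotations])
    return pd.DataFrame(
        {
            "phi": eul[:, 0],
            "theta": eul[:, 1],
            "psi": eul[:, 2],
            "shift_x": truth.shifts[:, 0],
            "shift_y": truth.shifts[:, 1],
            "state": truth.states,
        }
    )
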