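"""Ensemble volume analysis: pairwise docking, similarity matrix, medoid.

Ab initio maps come out in arbitrary orientations and with arbitrary hand.
Each pair of volumes is docked by an exhaustive coarse rotation search over
both hands (mirror = z-flip), followed by deterministic pattern-search
refinement of the rotation vector; the similarity score is the masked
real-space correlation at the aligned pose, symmetrized over the two
application directions so score(a, b) == score(b, a). The ensemble medoid
is the member with the largest similarity row sum; members scoring far
below the rest against the medoid are flagged as outliers
(score < median - 2 * MAD). Volumes are never averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fourier import DensityVolume, ftn, iftn, shell_index_map, spherical_mask
from .geometry import (
    build_so3_grid,
    matrix_to_rotvec,
    rot_z,
    rotvec_to_matrix,
)


@dataclass
class DockResult:
    rotation: np.ndarray  # applies to b: aligned_b(x) = b(R x)
    flipped: bool
    score: float


@dataclass
class SimilarityMatrix:
    scores: np.ndarray  # (n, n), diagonal 1
    rotations: list  # per-pair best rotation
    flips: np.ndarray  # (n, n) bool


def _lowpass_downsample(vol: DensityVolume, lp: float, box: int) -> np.ndarray:
    """Low-pass to lp (A) and Fourier-crop to a small working box."""
    F = ftn(vol.grid)
    L = vol.box
    cutoff = L * vol.pixel_size / lp
    r = shell_index_map(vol.grid.shape).astype(float)
    F = F / np.sqrt(1.0 + (r / max(cutoff, 1.0)) ** 16)
    lo = L // 2 - box // 2
    sl = slice(lo, lo + box)
    small = np.real(iftn(F[sl, sl, sl]))
    return small.astype(np.float64)


def _masked_values(grid: np.ndarray, mask_sel: np.ndarray) -> np.ndarray:
    v = grid[mask_sel]
    return v - v.mean()


def _rotate_grid(grid: np.ndarray, rot: np.ndarray) -> np.ndarray:
    L = grid.shape[0]
    c = L // 2
    center = np.array([c, c, c], dtype=float)
    return ndimage.affine_transform(
        grid, rot, offset=center - rot @ center, order=1, mode="constant"
    )


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    den = np.sqrt(np.sum(a * a) * np.sum(b * b))
    return float(np.sum(a * b) / den) if den > 0 else 0.0


def _sym_corr(ga: np.ndarray, gb: np.ndarray, rot: np.ndarray, sel: np.ndarray) -> float:
    """Correlation symmetrized over the two application directions."""
    c1 = _corr(_masked_values(ga, sel), _masked_values(_rotate_grid(gb, rot), sel))
    c2 = _corr(_masked_values(_rotate_grid(ga, rot.T), sel), _masked_values(gb, sel))
    return 0.5 * (c1 + c2)


def _coarse_rotations(spacing_deg: float = 15.0) -> np.ndarray:
    n_dirs = max(8, int(round(4 * np.pi / np.deg2rad(spacing_deg) ** 2)))
    n_inp = max(4, int(round(360.0 / spacing_deg)))
    grid = build_so3_grid(n_dirs, n_inp, "C1")
    rots = [
        grid.dir_rots[m] @ rot_z(np.deg2rad(p))
        for m in range(grid.n_dirs)
        for p in grid.inplane_deg
    ]
    rots = np.stack(rots)
    # close the candidate set under inversion so dock(a,b) and dock(b,a)
    # explore exactly mirrored hypotheses
    return np.concatenate([rots, np.transpose(rots, (0, 2, 1))])


def dock_pair(
    a: DensityVolume,
    b: DensityVolume,
    lp: float = 10.0,
    coarse_spacing: float = 15.0,
    work_box: int = 16,
    refine_stop_deg: float = 0.5,
) -> DockResult:
    """Rigid rotational docking of b onto a with hand determination.

    Exhaustive coarse search over an SO(3) grid (<= ``coarse_spacing`` deg)
    for both hands of b, then pattern-search refinement of the rotation
    vector with a sign-symmetric stencil. Volumes must share box and pixel
    size and are compared after low-pass filtering and masking.
    """
    if a.box != b.box or abs(a.pixel_size - b.pixel_size) > 1e-6:
        raise ValueError("volumes must share box and pixel size")
    work_box = min(work_box, a.box)
    ga = _lowpass_downsample(a, lp, work_box)
    sel = spherical_mask(work_box, 0.45 * work_box, 1.0) > 0.05
    cands = _coarse_rotations(coarse_spacing)

    best = None
    for flipped in (False, True):
        gb0 = b.grid[:, :, ::-1].astype(np.float32) if flipped else b.grid
        gb = _lowpass_downsample(DensityVolume(gb0, b.pixel_size), lp, work_box)
        # vectorized coarse scan: trilinear readout of gb at rotated coords,
        # batched over candidate rotations; a subsample of mask points is
        # plenty at the coarse stage (refinement uses every point)
        coords = np.argwhere(sel).T.astype(np.float32)  # (3, P)
        step = max(1, coords.shape[1] // 800)
        coords = coords[:, ::step]
        c = work_box // 2
        rel = coords - c
        n_pts = rel.shape[1]
        av_g = ga[tuple(coords.astype(int))]
        av = av_g - av_g.mean()
        scores = np.empty(len(cands))
        cands32 = cands.astype(np.float32)
        gb32 = gb.astype(np.float32)
        chunk = max(1, 4_000_000 // max(n_pts, 1))
        for lo in range(0, len(cands), chunk):
            hi = min(lo + chunk, len(cands))
            pts = np.einsum("nij,jp->nip", cands32[lo:hi], rel) + c  # (n,3,P)
            flat = np.ascontiguousarray(pts.transpose(1, 0, 2)).reshape(3, -1)
            bv = ndimage.map_coordinates(gb32, flat, order=1, mode="constant")
            bv = bv.reshape(hi - lo, n_pts).astype(np.float64)
            bv = bv - bv.mean(axis=1, keepdims=True)
            num = bv @ av
            den = np.linalg.norm(bv, axis=1) * np.linalg.norm(av)
            scores[lo:hi] = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
        order = int(np.argmax(scores))
        R0 = cands[order]
        # deterministic pattern search on the rotation vector
        v = matrix_to_rotvec(R0)
        step = np.deg2rad(coarse_spacing) / 2.0
        fbest = _sym_corr(ga, gb, rotvec_to_matrix(v), sel)
        while step > np.deg2rad(refine_stop_deg):
            improved = False
            for axis in range(3):
                for sgn in (1.0, -1.0):
                    vv = v.copy()
                    vv[axis] += sgn * step
                    f = _sym_corr(ga, gb, rotvec_to_matrix(vv), sel)
                    if f > fbest + 1e-12:
                        fbest, v = f, vv
                        improved = True
            if not improved:
                step /= 2.0
        if best is None or fbest > best.score:
            best = DockResult(rotvec_to_matrix(v), flipped, fbest)
    return best


def apply_dock(b: DensityVolume, dock: DockResult) -> DensityVolume:
    """Return b aligned into a's frame per the docking result."""
    g = b.grid[:, :, ::-1].astype(np.float64) if dock.flipped else b.grid.astype(np.float64)
    return DensityVolume(_rotate_grid(g, dock.rotation).astype(np.float32), b.pixel_size)


def similarity_matrix(vols: list[DensityVolume], lp: float = 10.0, **kw) -> SimilarityMatrix:
    n = len(vols)
    S = np.eye(n)
    flips = np.zeros((n, n), dtype=bool)
    rotations = [[None] * n for _ in range(n)]
    for i in range(n):
        rotations[i][i] = np.eye(3)
        for j in range(i + 1, n):
            d = dock_pair(vols[i], vols[j], lp=lp, **kw)
            S[i, j] = S[j, i] = d.score
            flips[i, j] = flips[j, i] = d.flipped
            rotations[i][j] = d.rotation
            rotations[j][i] = d.rotation.T
    return SimilarityMatrix(S, rotations, flips)


def medoid_analysis(
    vols: list[DensityVolume], lp: float = 10.0, sim: SimilarityMatrix | None = None, **kw
) -> tuple[int, np.ndarray, np.ndarray, SimilarityMatrix]:
    """Medoid volume, scores to the medoid, and outlier flags.

    The medoid maximizes the similarity row sum. A member is an outlier if
    its score to the medoid falls below median - 2 * MAD of the other
    members' scores. No averaging of volumes is performed.
    """
    n = len(vols)
    if n == 1:
        return 0, np.array([1.0]), np.array([False]), SimilarityMatrix(
            np.ones((1, 1)), [[np.eye(3)]], np.zeros((1, 1), dtype=bool)
        )
    if sim is None:
        sim = similarity_matrix(vols, lp=lp, **kw)
    medoid = int(np.argmax(sim.scores.sum(axis=1)))
    scores = sim.scores[medoid].copy()
    others = np.delete(scores, medoid)
    med = np.median(others)
    mad = np.median(np.abs(others - med))
    thr = med - 2.0 * max(mad, 1e-6)
    flags = scores < thr
    flags[medoid] = False
    return medoid, scores, flags, sim
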