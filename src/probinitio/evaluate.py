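"""Evaluation helpers against known ground truth (synthetic benchmarks)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .ensemble import dock_pair, apply_dock
from .fourier import DensityVolume, fsc_curve, resolution_at_threshold, spherical_mask
from .geometry import align_orientations
from .multistate import best_permutation_accuracy


def angular_errors(
    est_rots: np.ndarray, true_rots: np.ndarray, symmetry: str = "C1"
) -> np.ndarray:
    """Per-particle SO(3) geodesic errors after global alignment (hand free)."""
    _, _, errors = align_orientations(est_rots, true_rots, symmetry)
    return errors


def center_volume(vol: DensityVolume) -> DensityVolume:
    """Translate the density's center of mass onto the box center."""
    g = np.maximum(vol.grid.astype(np.float64), 0.0)
    total = g.sum()
    if total <= 0:
        return vol.copy()
    c = vol.box // 2
    com = np.array(ndimage.center_of_mass(g))
    out = ndimage.shift(vol.grid.astype(np.float64), c - com, order=3, mode="constant")
    return DensityVolume(out.astype(np.float32), vol.pixel_size)


def fsc_to_reference(
    vol: DensityVolume, reference: DensityVolume, lp_dock: float = 10.0
) -> np.ndarray:
    """FSC of a reconstructed map against a reference after rigid docking.

    The map is in an arbitrary frame (rotation + hand + residual origin
    offset); it is docked onto the reference and brought into register with
    a single cubic-spline resampling (rotation and recentering combined, so
    interpolation attenuates the high shells only once).
    """
    a = reference
    b = vol
    if b.box != a.box:
        from .fourier import resample_volume

        b = resample_volume(b, a.box)
    ac = center_volume(a)
    bc = center_volume(b)
    dock = dock_pair(ac, bc, lp=lp_dock, work_box=min(24, a.box), refine_stop_deg=0.25)
    g = b.grid[:, :, ::-1].astype(np.float64) if dock.flipped else b.grid.astype(np.float64)
    c = a.box // 2
    ga = np.maximum(a.grid.astype(np.float64), 0)
    gb = np.maximum(g, 0)
    com_a = np.array(ndimage.center_of_mass(ga)) if ga.sum() > 0 else np.full(3, c)
    com_b = np.array(ndimage.center_of_mass(gb)) if gb.sum() > 0 else np.full(3, c)
    rot = dock.rotation
    # single affine: sample b at rot @ (x - com_a) + com_b
    aligned = ndimage.affine_transform(
        g, rot, offset=com_b - rot @ com_a, order=3, mode="constant"
    )
    mask = spherical_mask(a.box, 0.4 * a.box, max(3.0, a.box / 12))
    return fsc_curve(
        DensityVolume(a.grid * mask, a.pixel_size),
        DensityVolume((aligned * mask).astype(np.float32), a.pixel_size),
    )


def map_resolution_vs_reference(
    vol: DensityVolume, reference: DensityVolume, threshold: float = 0.5
) -> float:
    c = fsc_to_reference(vol, reference)
    return resolution_at_threshold(c, threshold, reference.box, reference.pixel_size)


def state_accuracy(est_labels, true_labels, n_states: int) -> float:
    acc, _ = best_permutation_accuracy(
        np.asarray(est_labels), np.asarray(true_labels), n_states
    )
    return acc
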