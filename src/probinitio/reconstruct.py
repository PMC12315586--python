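"""Even/odd half-set gridding reconstruction and final map assembly."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import (
    DensityVolume,
    FourierVolume,
    apply_spherical_mask,
    fsc_curve,
)
from .regularize import (
    RegularizerConfig,
    SigmaMap,
    icm_regularize,
    ml_regularize,
    noise_sigma_map,
    vector_quantize,
)


@dataclass
class HalfSetReconstruction:
    """Even/odd accumulators, their normalized maps and the half-map FSC."""

    even: FourierVolume
    odd: FourierVolume
    even_map: DensityVolume
    odd_map: DensityVolume
    fsc: np.ndarray

    @property
    def box(self) -> int:
        return self.even.box


def reconstruct_halfmaps(
    particle_fts: np.ndarray,
    ctfs: np.ndarray | None,
    rots: np.ndarray,
    shifts: np.ndarray | None,
    weights: np.ndarray | None,
    pixel_size: float,
    max_radius: float | None = None,
    half_ids: np.ndarray | None = None,
) -> HalfSetReconstruction:
    """CTF-weighted insertion of particles into even/odd halves by index parity.

    Numerator accumulates kernel * H * P (particles recentered by their
    shifts), weights accumulate kernel * H^2 * w. Frequencies beyond
    ``max_radius`` (original-box Fourier pixels) are excluded. The halves are
    normalized independently and their FSC computed.
    """
    n = len(particle_fts)
    box = particle_fts.shape[-1]
    if weights is None:
        weights = np.ones(n)
    if np.any(np.asarray(weights) < 0):
        raise ValueError("weights must be >= 0")
    if half_ids is None:
        half_ids = np.arange(n) % 2
    halves = []
    for h in (0, 1):
        sel = np.flatnonzero(half_ids == h)
        if len(sel) == 0:
            raise ValueError(f"half {h} is empty")
        acc = FourierVolume.zeros(box, pixel_size)
        acc.insert_slices(
            particle_fts[sel],
            None if ctfs is None else ctfs[sel],
            rots[sel],
            None if shifts is None else shifts[sel],
            np.asarray(weights)[sel],
            max_radius,
        )
        halves.append(acc)
    even_map = halves[0].normalize()
    odd_map = halves[1].normalize()
    return HalfSetReconstruction(
        halves[0], halves[1], even_map, odd_map, fsc_curve(even_map, odd_map)
    )


def combine_accumulators(recon: HalfSetReconstruction) -> FourierVolume:
    comb = FourierVolume.zeros(recon.box, recon.even.pixel_size)
    comb.data = recon.even.data + recon.odd.data
    comb.weight = recon.even.weight + recon.odd.weight
    return comb


def finalize_map(
    recon: HalfSetReconstruction,
    mode: str = "none",
    mask_radius: float | None = None,
    mask_edge: float = 4.0,
    reg_cfg: RegularizerConfig | None = None,
    sigma: SigmaMap | None = None,
) -> DensityVolume:
    """Combine halves, apply stage regularization and the soft spherical mask.

    mode "none": plain floored weighted division of the combined accumulator.
    mode "ml": SSNR-regularized division using the half-map FSC.
    mode "icm": ICM-regularize the even and odd maps independently with a
    shared quantizer, then average. No B-factor sharpening is ever applied.
    """
    reg_cfg = reg_cfg or RegularizerConfig()
    comb = combine_accumulators(recon)
    if mode == "none":
        vol = comb.normalize()
    elif mode == "ml":
        vol = ml_regularize(comb, recon.fsc, reg_cfg.tau)
    elif mode == "icm":
        if sigma is None:
            sigma = noise_sigma_map(recon.even_map, recon.odd_map)
        mean_map = 0.5 * (recon.even_map.grid + recon.odd_map.grid)
        levels = vector_quantize(mean_map, reg_cfg.levels).levels
        e = icm_regularize(recon.even_map, sigma, reg_cfg, levels)
        o = icm_regularize(recon.odd_map, sigma, reg_cfg, levels)
        vol = DensityVolume(
            (0.5 * (e.grid + o.grid)).astype(np.float32), recon.even_map.pixel_size
        )
    else:
        raise ValueError(f"unknown regularization mode: {mode}")
    if mask_radius is None:
        mask_radius = recon.box // 2 - mask_edge - 1
    return apply_spherical_mask(vol, mask_radius, mask_edge)
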