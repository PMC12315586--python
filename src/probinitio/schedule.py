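"""Stage controller, class-balanced importance sampling and frequency marching.

The ab initio search runs in eight stages. Early stages use the hybrid
SHC/probabilistic orientation search on heavily downscaled data with no or
uniform (ML) regularization; later stages switch to the global probabilistic
search with non-uniform (ICM) regularization, progressively admitting
noisier particles and finer frequencies. Per-stage defaults:

    stage  search          regularization  selection    shifts  max dirs  iters
    1      hybrid SHC      none            top ranking  no      500       20
    2      hybrid SHC      none            top ranking  no      500       20
    3      hybrid SHC      ML              top ranking  yes     1000      17
    4      hybrid SHC      ML              top 50%      yes     1000      17
    5      probabilistic   ICM             top 50%      yes     1000      17
    6      probabilistic   ICM             top 50%      yes     1000      17
    7      probabilistic   ICM             top 85%      yes     2500      15
    8      probabilistic   ICM             top 85%      yes     2500      30

The frequency march derives the per-stage low-pass limits from the 2D class
FRC curves: the start limit is where the all-class mean FRC crosses 0.8, the
final limit where the mean FRC of the three best resolved classes crosses
0.143 (clamped into [4.5, 6.0] A unless the user asks for coarser), and the
six intermediate limits step linearly along the mean-FRC values in between.
Each stage is downscaled so the pixel size is one third of its limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .fourier import (
    DensityVolume,
    fft_friendly_size,
    ftn,
    iftn,
    resolution_at_threshold,
    shell_index_map,
    spherical_mask,
)

FINAL_LP_CLAMP = (4.5, 6.0)
DEFAULT_START_LP = 30.0
FRC_START_LEVEL = 0.8
FRC_FINAL_LEVEL = 0.143


@dataclass(frozen=True)
class StageConfig:
    """One row of the eight-stage controller."""

    stage: int
    search: str  # "shc_hybrid" | "probabilistic"
    regularization: str  # "none" | "ml" | "icm"
    selection_phase: int  # 1 = top ranking, 2 = top 50%, 3 = top 85%
    shift_search: bool
    max_directions: int
    max_iterations: int


_TABLE = [
    StageConfig(1, "shc_hybrid", "none", 1, False, 500, 20),
    StageConfig(2, "shc_hybrid", "none", 1, False, 500, 20),
    StageConfig(3, "shc_hybrid", "ml", 1, True, 1000, 17),
    StageConfig(4, "shc_hybrid", "ml", 2, True, 1000, 17),
    StageConfig(5, "probabilistic", "icm", 2, True, 1000, 17),
    StageConfig(6, "probabilistic", "icm", 2, True, 1000, 17),
    StageConfig(7, "probabilistic", "icm", 3, True, 2500, 15),
    StageConfig(8, "probabilistic", "icm", 3, True, 2500, 30),
]


def stage_config(stage: int) -> StageConfig:
    """Default controller row for stage 1..8."""
    if not 1 <= stage <= 8:
        raise ValueError(f"stage must be 1..8, got {stage}")
    return _TABLE[stage - 1]


# ---------------------------------------------------------------------------
# class-restrained balanced particle selection
# ---------------------------------------------------------------------------


@dataclass
class ClassInfo:
    """One 2D class: member particles, their match scores and the class FRC."""

    class_id: int
    members: np.ndarray  # particle indices
    scores: np.ndarray  # 2D match score, higher = better agreement
    frc: np.ndarray | None = None  # per-shell curve

    def __post_init__(self):
        if self.frc is not None and (np.any(self.frc > 1 + 1e-9) or np.any(self.frc < -1 - 1e-9)):
            raise ValueError("FRC values must lie in [-1, 1]")


_PHASE_FRACTION = {1: None, 2: 0.50, 3: 0.85}


def select_balanced(
    classes: list[ClassInfo],
    nsample: int,
    phase: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balanced selection of ``nsample`` particles evenly across classes.

    Phase 1 takes each class's best-scoring particles deterministically;
    phases 2 and 3 sample uniformly among each class's top 50% / top 85% by
    score. Per-class quotas differ by at most one whenever pool sizes allow;
    shortfalls are redistributed round-robin over classes with particles
    remaining.
    """
    if phase not in _PHASE_FRACTION:
        raise ValueError("phase must be 1, 2 or 3")
    pools = []
    for ci in classes:
        order = np.argsort(-ci.scores, kind="stable")
        frac = _PHASE_FRACTION[phase]
        if frac is not None:
            order = order[: max(1, math.ceil(frac * len(order)))]
        pools.append(ci.members[order])
    capacity = sum(len(p) for p in pools)
    if nsample > capacity:
        warnings.warn(
            f"nsample {nsample} exceeds eligible pool {capacity}; taking everything"
        )
        nsample = capacity
    # round-robin quota assignment respecting availability
    quotas = np.zeros(len(pools), dtype=int)
    remaining = nsample
    while remaining > 0:
        progressed = False
        for i, p in enumerate(pools):
            if remaining == 0:
                break
            if quotas[i] < len(p):
                quotas[i] += 1
                remaining -= 1
                progressed = True
        if not progressed:
            break
    out = []
    for p, q, ci in zip(pools, quotas, classes):
        if q == 0:
            continue
        if phase == 1:
            out.append(p[:q])  # already score-ordered: greedy best
        else:
            out.append(rng.choice(p, size=q, replace=False))
    return np.concatenate(out) if out else np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# frequency marching
# ---------------------------------------------------------------------------


@dataclass
class MarchPlan:
    """Eight per-stage low-pass limits with matched downscaled boxes."""

    lowpass: np.ndarray  # (8,) A, non-increasing
    boxes: np.ndarray  # (8,) downscaled box sizes
    pixel_sizes: np.ndarray  # (8,) A/px after downscaling

    def __post_init__(self):
        if np.any(np.diff(self.lowpass) > 1e-9):
            raise ValueError("low-pass limits must be non-increasing")

    def describe(self) -> str:
        lines = ["stage  lowpass(A)  box  pixel(A)"]
        for i in range(8):
            lines.append(
                f"{i + 1:>5}  {self.lowpass[i]:>9.2f}  {self.boxes[i]:>3d}  "
                f"{self.pixel_sizes[i]:>7.3f}"
            )
        return "\n".join(lines)


def _mean_curve(curves: list[np.ndarray]) -> np.ndarray:
    n = min(len(c) for c in curves)
    return np.mean([c[:n] for c in curves], axis=0)


def _monotone(curve: np.ndarray) -> np.ndarray:
    return np.minimum.accumulate(curve)


def _res_at_level(curve: np.ndarray, level: float, box: int, apix: float) -> float:
    return resolution_at_threshold(_monotone(curve), level, box, apix)


def plan_frequency_march(
    classes: list[ClassInfo],
    box: int,
    pixel_size: float,
    user_final_lp: float | None = None,
) -> MarchPlan:
    """Derive the 8-stage low-pass limits and downscale factors (module doc)."""
    curves = [ci.frc for ci in classes if ci.frc is not None]
    if len(curves) < 3:
        raise ValueError("need FRC curves for at least 3 classes")
    mean_all = _monotone(_mean_curve(curves))
    nyq = 2.0 * pixel_size

    if mean_all[1] < FRC_START_LEVEL:
        warnings.warn("mean class FRC never reaches 0.8; starting at 30 A")
        start = DEFAULT_START_LP
    else:
        start = _res_at_level(mean_all, FRC_START_LEVEL, box, pixel_size)
        start = max(start, nyq)

    res143 = [_res_at_level(c, FRC_FINAL_LEVEL, box, pixel_size) for c in curves]
    best3 = [curves[i] for i in np.argsort(res143)[:3]]
    final = _res_at_level(_monotone(_mean_curve(best3)), FRC_FINAL_LEVEL, box, pixel_size)
    final = min(max(final, FINAL_LP_CLAMP[0]), FINAL_LP_CLAMP[1])
    if user_final_lp is not None and user_final_lp > final:
        final = float(user_final_lp)
    final = max(final, nyq)
    start = max(start, final)

    # FRC levels stepped linearly between the start and final levels
    shells = np.arange(len(mean_all), dtype=float)
    d_total = box * pixel_size
    start_shell = min(d_total / start, box / 2)
    final_shell = min(d_total / final, box / 2)
    f_start = float(np.interp(start_shell, shells, mean_all))
    f_end = float(np.interp(final_shell, shells, mean_all))
    levels = np.linspace(f_start, f_end, 8)
    limits = np.empty(8)
    limits[0] = start
    limits[7] = final
    for i in range(1, 7):
        limits[i] = _res_at_level(mean_all, levels[i], box, pixel_size)
    limits = np.maximum.accumulate(limits[::-1])[::-1]  # enforce non-increasing
    limits = np.clip(limits, final, max(start, final))

    boxes = np.empty(8, dtype=int)
    pixels = np.empty(8)
    for i in range(8):
        target_pixel = limits[i] / 3.0  # downscaled sampling = limit / 3
        b = fft_friendly_size(d_total / target_pixel)
        b = int(min(max(b, 16), box))
        boxes[i] = b
        pixels[i] = d_total / b
    boxes = np.maximum.accumulate(boxes)
    pixels = d_total / boxes
    return MarchPlan(limits, boxes, pixels)


# ---------------------------------------------------------------------------
# automatic low-pass limit from the even/odd pair
# ---------------------------------------------------------------------------


def butterworth_lowpass(vol: DensityVolume, cutoff_shell: float, order: int = 8) -> DensityVolume:
    """Uniform Butterworth low-pass; cutoff in Fourier shells."""
    F = ftn(vol.grid)
    r = shell_index_map(vol.grid.shape).astype(float)
    H = 1.0 / np.sqrt(1.0 + (r / max(cutoff_shell, 1e-6)) ** (2 * order))
    out = np.real(iftn(F * H))
    return DensityVolume(out.astype(np.float32), vol.pixel_size)


def estimate_lowpass_auto(
    even: DensityVolume,
    odd: DensityVolume,
    mask_radius: float,
    order: int = 8,
    previous: float | None = None,
) -> float:
    """Butterworth cutoff minimizing the masked distance of filtered even to odd.

    Sweeps the cutoff over integer shells (including Nyquist, i.e. in effect
    no filtering) and returns the minimizing limit in Angstrom.
    """
    if even.grid.shape != odd.grid.shape:
        raise ValueError("even/odd grids differ")
    L = even.box
    mask = spherical_mask(L, mask_radius, max(2.0, L * 0.05)) > 0.5
    Fe = ftn(even.grid)
    r = shell_index_map(even.grid.shape).astype(float)
    o = odd.grid
    best, best_shell = None, None
    shells = np.arange(2, L // 2 + 1)
    scores = np.empty(len(shells))
    for i, s in enumerate(shells):
        H = 1.0 / np.sqrt(1.0 + (r / s) ** (2 * order))
        f = np.real(iftn(Fe * H))
        scores[i] = float(np.sum((f[mask] - o[mask]) ** 2))
        if best is None or scores[i] < best:
            best, best_shell = scores[i], s
    spread = scores.max() - scores.min()
    if previous is not None and spread <= 1e-12 * max(scores.max(), 1e-30):
        return previous
    return float(L * even.pixel_size / best_shell)
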