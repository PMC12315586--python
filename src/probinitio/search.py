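"""Probability-table construction, epsilon-neighborhood sampling and SHC.

The probabilistic assignment works on an affinity matrix ``A`` with one row
per sampled particle and one column per orientation cell (S2 direction x
in-plane angle, times the number of structural states when K > 1). Each
entry is ``1 - d`` (d the normalized Euclidean cost). Rows are normalized by
their sums, then a single global min-max normalization maps the whole table
into [0, 1]. Per particle the sampling neighborhood is the set of top-Q
affinity cells, Q being the expected number of grid cells inside a geodesic
cap of radius epsilon (the angular threshold); one cell is drawn
multinomially from the renormalized neighborhood probabilities. The table
is coupled sequentially: every assignment increments a per-direction
occupancy that damps the effective probability of crowded directions for
all subsequent particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SO3Grid


@dataclass
class AngularThreshold:
    """Adaptive angular search radius epsilon, degrees."""

    epsilon: float = 10.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ProbabilityTable:
    """Normalized particle x orientation-cell probabilities plus coupling state."""

    probs: np.ndarray  # (n_sampled, n_cells) in [0, 1]
    occupancy: np.ndarray  # per-direction assignment counts
    expected_per_direction: float = 1.0

    def coupling_multipliers(self) -> np.ndarray:
        """Damping factor per direction: 1 / (1 + occupancy / expected)."""
        return 1.0 / (1.0 + self.occupancy / self.expected_per_direction)


def build_probability_table(
    costs: np.ndarray, n_dirs: int | None = None, expected_per_direction: float | None = None
) -> ProbabilityTable:
    """Affinity = 1 - cost; row-normalize by row sums; global min-max to [0,1]."""
    costs = np.asarray(costs, dtype=np.float64)
    if np.any(~np.isfinite(costs)) or costs.min() < -1e-9 or costs.max() > 1 + 1e-9:
        raise ValueError("costs must be finite and within [0, 1]")
    aff = 1.0 - costs
    rows = aff.sum(axis=1, keepdims=True)
    uniform = rows[:, 0] <= 0
    rows[uniform] = 1.0
    aff = aff / rows
    aff[uniform] = 1.0 / costs.shape[1]
    lo, hi = aff.min(), aff.max()
    probs = np.ones_like(aff) if hi == lo else (aff - lo) / (hi - lo)
    if n_dirs is None:
        n_dirs = costs.shape[1]
    occ = np.zeros(n_dirs, dtype=np.int64)
    if expected_per_direction is None:
        expected_per_direction = max(costs.shape[0] / n_dirs, 1e-9)
    return ProbabilityTable(probs, occ, expected_per_direction)


@dataclass
class SamplingNeighborhood:
    """Top-affinity cells forming a particle's epsilon-neighborhood."""

    cells: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        if len(self.cells) == 0:
            raise ValueError("empty sampling neighborhood")
        s = self.probs.sum()
        if s <= 0:
            self.probs = np.full(len(self.cells), 1.0 / len(self.cells))
        else:
            self.probs = self.probs / s


def neighborhood_size(grid: SO3Grid, eps_deg: float, n_states: int = 1) -> int:
    """Expected number of grid cells inside a geodesic cap of radius eps.

    Directions: N_m_total * (1 - cos eps) / 2 referred to the full sphere
    (the Fibonacci density before asymmetric-unit filtering); in-plane:
    fraction 2*eps/360 of the circle. At least one cell per state.
    """
    cap_frac = 0.5 * (1.0 - np.cos(np.deg2rad(min(eps_deg, 180.0))))
    # grid density per unit area is uniform; use the retained count directly
    # scaled by the cap solid angle over the asymmetric-unit solid angle
    q_dir = max(1, int(round(grid.n_dirs * cap_frac * 4 * np.pi / _unit_area(grid))))
    q_dir = min(q_dir, grid.n_dirs)
    q_inp = max(1, min(grid.n_inplane, int(round(grid.n_inplane * 2.0 * eps_deg / 360.0))))
    return max(n_states, n_states * q_dir * q_inp)


def _unit_area(grid: SO3Grid) -> float:
    from .geometry import parse_symmetry

    family, n = parse_symmetry(grid.symmetry)
    area = 4 * np.pi / n
    if family == "D":
        area /= 2
    return area


def select_neighborhood(
    row: np.ndarray, q: int, multipliers: np.ndarray | None = None
) -> SamplingNeighborhood:
    """Top-q cells of a probability row (ties to lowest index)."""
    q = min(q, len(row))
    if q >= len(row):
        cells = np.arange(len(row))
    else:
        # stable sort: ties broken toward the lowest index
        cells = np.sort(np.argsort(-row, kind="stable")[:q])
    probs = row[cells].astype(np.float64).copy()
    if multipliers is not None:
        probs = probs * multipliers[cells]
    return SamplingNeighborhood(cells, probs)


def sample_assignment(
    row: np.ndarray,
    grid: SO3Grid,
    eps: AngularThreshold,
    rng: np.random.Generator,
    multipliers: np.ndarray | None = None,
    n_states: int = 1,
) -> int:
    """Draw one orientation cell multinomially from the eps-neighborhood.

    Returns the flat cell index (state * N_m * N_n + m * N_n + n). Falls back
    to the global best cell if the neighborhood degenerates.
    """
    q = neighborhood_size(grid, eps.epsilon, n_states)
    try:
        hood = select_neighborhood(row, q, multipliers)
    except ValueError:
        return int(np.argmax(row))
    if not np.all(np.isfinite(hood.probs)):
        return int(np.argmax(row))
    return int(rng.choice(hood.cells, p=hood.probs))


def update_after_assignment(table: ProbabilityTable, direction: int):
    """Sequential coupling: count the assignment for occupancy damping."""
    table.occupancy[direction] += 1


def shc_assign(
    cost_of_dir,
    n_dirs: int,
    prev_cost: float,
    rng: np.random.Generator,
):
    """First-improvement stochastic hill climbing over projection directions.

    ``cost_of_dir(m)`` returns the best cost over in-plane angles for
    direction m. Directions are visited in a fresh random order and the first
    one improving on ``prev_cost`` is returned; if a full pass finds no
    improvement, the best encountered is returned. Also returns the number
    of evaluations spent.
    """
    order = rng.permutation(n_dirs)
    best_m = -1
    best_c = np.inf
    for k, m in enumerate(order):
        c = cost_of_dir(int(m))
        if c < best_c:
            best_c, best_m = c, int(m)
        if c < prev_cost:
            return int(m), float(c), k + 1
    return best_m, float(best_c), n_dirs


def shc_pick_batch(
    dir_costs: np.ndarray, prev_costs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized SHC decision for many particles.

    ``dir_costs[p, m]`` is the best in-plane cost of particle p at direction
    m; each particle visits directions in an independent random order and
    takes the first improving one (global best if none improves). Same
    first-improvement law as :func:`shc_assign`.
    """
    n_p, n_m = dir_costs.shape
    out = np.empty(n_p, dtype=np.int64)
    for p in range(n_p):
        order = rng.permutation(n_m)
        c = dir_costs[p, order]
        hits = np.flatnonzero(c < prev_costs[p])
        if len(hits):
            out[p] = order[hits[0]]
        else:
            out[p] = np.argmin(dir_costs[p])
    return out


def sample_inplane(
    inplane_costs: np.ndarray,
    eps_deg: float,
    rng: np.random.Generator,
) -> int:
    """Sample an in-plane angle within the in-plane eps-neighborhood.

    The neighborhood is the top-q affinity angles with
    q = round(N_n * 2 eps / 360) (at least 1); probabilities are the
    renormalized affinities 1 - d.
    """
    n = len(inplane_costs)
    q = max(1, min(n, int(round(n * 2.0 * eps_deg / 360.0))))
    aff = 1.0 - inplane_costs
    idx = np.argpartition(-aff, q - 1)[:q] if q < n else np.arange(n)
    p = aff[idx].astype(np.float64)
    p = p - min(p.min(), 0.0)
    s = p.sum()
    if s <= 0 or not np.isfinite(s):
        return int(idx[np.argmax(aff[idx])])
    return int(rng.choice(idx, p=p / s))


def update_angular_threshold(
    angular_changes_deg: np.ndarray,
    eps: AngularThreshold,
    grid_spacing_deg: float,
    min_updates: int = 10,
) -> AngularThreshold:
    """eps <- clamp(90th percentile of geodesic changes, spacing, prev eps)."""
    changes = np.asarray(angular_changes_deg, dtype=float)
    if len(changes) < min_updates:
        return eps
    p90 = float(np.percentile(changes, 90.0))
    new = min(max(p90, grid_spacing_deg), eps.epsilon)
    return AngularThreshold(new)
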