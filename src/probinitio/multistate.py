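"""Multi-volume bookkeeping: state initialization, rescue, evaluation."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np


@dataclass
class StateAssignment:
    """Per-particle discrete structural-state labels."""

    labels: np.ndarray
    n_states: int
    mode: str = "independent"  # or "docked"

    def __post_init__(self):
        if self.mode not in ("independent", "docked"):
            raise ValueError(f"unknown het mode: {self.mode}")
        if np.any(self.labels < 0) or np.any(self.labels >= self.n_states):
            raise ValueError("labels out of range")

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_states)


def init_states(
    n_particles: int, n_states: int, mode: str, rng: np.random.Generator
) -> StateAssignment:
    """Random uniform partition (independent) or all-one-state (docked).

    In docked mode all particles share one volume until just before the
    final stage, when :func:`split_docked` performs the random partition.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    if mode == "independent" and n_states > 1:
        labels = rng.integers(0, n_states, size=n_particles)
    else:
        labels = np.zeros(n_particles, dtype=np.int64)
    return StateAssignment(labels.astype(np.int64), n_states, mode)


def split_docked(assignment: StateAssignment, rng: np.random.Generator) -> StateAssignment:
    """Random split of a docked run into its states (final-stage entry)."""
    labels = rng.integers(0, assignment.n_states, size=len(assignment.labels))
    return StateAssignment(labels.astype(np.int64), assignment.n_states, assignment.mode)


def joint_assign(
    cost_row: np.ndarray,
    grid,
    eps,
    rng: np.random.Generator,
    n_states: int,
    multipliers: np.ndarray | None = None,
) -> tuple[int, int, int]:
    """Sample (state, direction, in-plane) from a joint K x N_m x N_n row.

    The row spans the K state blocks; normalization and the neighborhood are
    joint across states, so the drawn cell yields both the orientation and
    the state label.
    """
    from .search import sample_assignment

    cells_per_state = grid.size
    row = 1.0 - np.asarray(cost_row)
    s = row.sum()
    row = row / s if s > 0 else np.full_like(row, 1.0 / len(row))
    cell = sample_assignment(row, grid, eps, rng, multipliers, n_states)
    state, rest = divmod(cell, cells_per_state)
    m, n = divmod(rest, grid.n_inplane)
    return int(state), int(m), int(n)


def rescue_empty_states(
    labels: np.ndarray,
    n_states: int,
    quality: np.ndarray,
    rng: np.random.Generator,
    min_members: int = 2,
) -> tuple[np.ndarray, list[int]]:
    """Re-seed empty states from the largest state's worst-scoring particles.

    ``quality`` is a per-particle goodness (higher = better); the reassigned
    particles are those least consistent with their current volume. Returns
    the repaired labels and the list of rescued state ids.
    """
    labels = labels.copy()
    rescued = []
    for s in range(n_states):
        count = np.sum(labels == s)
        if count >= min_members:
            continue
        donor = int(np.argmax(np.bincount(labels, minlength=n_states)))
        pool = np.flatnonzero(labels == donor)
        need = min_members - int(count)
        if len(pool) <= need:
            continue
        worst = pool[np.argsort(quality[pool])[:need]]
        labels[worst] = s
        rescued.append(s)
    return labels, rescued


def best_permutation_accuracy(
    est: np.ndarray, true: np.ndarray, n_states: int
) -> tuple[float, tuple]:
    """Label accuracy maximized over permutations of the state labels."""
    best, best_perm = 0.0, tuple(range(n_states))
    for perm in permutations(range(n_states)):
        mapped = np.asarray(perm)[est]
        acc = float(np.mean(mapped == true))
        if acc > best:
            best, best_perm = acc, perm
    return best, best_perm
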