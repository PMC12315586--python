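import numpy as np
import pytest
from scipy.stats import chisquare

from probinitio.geometry import build_so3_grid
from probinitio.search import (
    AngularThreshold,
    build_probability_table,
    neighborhood_size,
    sample_assignment,
    sample_inplane,
    select_neighborhood,
    shc_assign,
    shc_pick_batch,
    update_after_assignment,
    update_angular_threshold,
)


# ---------------------------------------------------------------------------
# probability table
# ---------------------------------------------------------------------------


def test_probability_table_forced_by_normalization():
    t = build_probability_table(np.array([[0.0, 1.0], [1.0, 0.0]]))
    assert np.allclose(t.probs, [[1.0, 0.0], [0.0, 1.0]])


def test_min_max_bounds_exact(rng):
    costs = rng.uniform(0, 1, size=(11, 23))
    t = build_probability_table(costs)
    assert t.probs.min() == 0.0
    assert t.probs.max() == 1.0
    assert np.all((t.probs >= 0) & (t.probs <= 1))


def test_table_matches_stepwise_oracle(rng):
    """Spreadsheet-style recomputation of the two normalization steps."""
    costs = rng.uniform(0, 1, size=(5, 7))
    t = build_probability_table(costs)
    aff = 1.0 - costs
    rows = aff / aff.sum(axis=1, keepdims=True)
    expect = (rows - rows.min()) / (rows.max() - rows.min())
    assert np.allclose(t.probs, expect, atol=1e-12)


def test_pre_minmax_rows_sum_to_one(rng):
    costs = rng.uniform(0, 1, size=(4, 9))
    aff = 1.0 - costs
    rows = aff / aff.sum(axis=1, keepdims=True)
    assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-12)


def test_invalid_costs_rejected():
    with pytest.raises(ValueError):
        build_probability_table(np.array([[0.5, 1.7]]))
    with pytest.raises(ValueError):
        build_probability_table(np.array([[np.nan, 0.2]]))


# ---------------------------------------------------------------------------
# neighborhood sampling
# ---------------------------------------------------------------------------


def test_singleton_neighborhood_is_deterministic(rng):
    grid = build_so3_grid(40, 8, "C1")
    row = np.zeros(grid.size)
    row[17] = 1.0
    eps = AngularThreshold(0.5)  # tiny cap: Q = 1
    draws = {sample_assignment(row, grid, eps, rng) for _ in range(50)}
    assert draws == {17}


def test_multinomial_uniform_frequencies(rng):
    hood = select_neighborhood(np.array([0.5, 0.5, 0.5, 0.5, 0.0, 0.0]), 4)
    counts = np.zeros(4)
    cells = hood.cells
    for _ in range(100_000):
        counts[rng.choice(len(cells), p=hood.probs)] += 1
    assert np.allclose(counts / 100_000, 0.25, atol=0.01)


def test_multinomial_weighted_goodness_of_fit(rng):
    probs = np.array([0.7, 0.2, 0.1])
    counts = np.zeros(3)
    n = 100_000
    picks = rng.choice(3, size=n, p=probs)
    counts = np.bincount(picks, minlength=3)
    stat = chisquare(counts, probs * n)
    assert stat.pvalue > 0.001


def test_neighborhood_size_scales_with_cap(rng):
    grid = build_so3_grid(500, 36, "C1")
    small = neighborhood_size(grid, 5.0)
    big = neighborhood_size(grid, 20.0)
    assert small < big
    assert neighborhood_size(grid, 1e-3) >= 1


def test_ties_break_to_lowest_index():
    row = np.array([0.3, 0.9, 0.9, 0.9, 0.1])
    hood = select_neighborhood(row, 2)
    assert 1 in hood.cells and 2 in hood.cells  # lowest-index winners


# ---------------------------------------------------------------------------
# sequential coupling
# ---------------------------------------------------------------------------


def test_effective_probabilities_equal_raw_before_any_assignment():
    t = build_probability_table(np.array([[0.2, 0.4], [0.1, 0.6]]))
    assert np.allclose(t.coupling_multipliers(), 1.0)


def test_multiplier_halves_past_expected_occupancy():
    t = build_probability_table(np.random.default_rng(0).uniform(0, 1, (10, 4)), n_dirs=4)
    for _ in range(int(t.expected_per_direction) + 1):
        update_after_assignment(t, 0)
    assert t.coupling_multipliers()[0] < 0.5


def test_coupling_balances_equal_affinity_directions(rng):
    # two equally attractive directions: occupancy damping splits the load
    expected = 5_000.0
    occupancy = np.zeros(2)
    for _ in range(10_000):
        w = 1.0 / (1.0 + occupancy / expected)
        p = w / w.sum()
        k = rng.choice(2, p=p)
        occupancy[k] += 1
    assert abs(occupancy[0] - occupancy[1]) / 10_000 < 0.05


# ---------------------------------------------------------------------------
# stochastic hill climbing
# ---------------------------------------------------------------------------


def test_shc_accepts_first_direction_when_cost_infinite(rng):
    seen = []

    def cost(m):
        seen.append(m)
        return 0.9

    m, c, n_evals = shc_assign(cost, 20, np.inf, rng)
    assert n_evals == 1
    assert m == seen[0]


def test_shc_full_pass_returns_best_when_nothing_improves(rng):
    costs = np.linspace(0.5, 0.9, 10)
    m, c, n_evals = shc_assign(lambda i: costs[i], 10, 0.1, rng)
    assert n_evals == 10
    assert m == 0 and c == pytest.approx(0.5)


def test_shc_mean_evaluations_geometric_law(rng):
    # 50% improving directions: mean evaluations to acceptance < N/2
    n_m = 40
    evals = []
    for _ in range(300):
        improving = rng.random(n_m) < 0.5
        costs = np.where(improving, 0.1, 0.9)
        _, _, n = shc_assign(lambda i: costs[i], n_m, 0.5, rng)
        evals.append(n)
    assert np.mean(evals) < n_m / 2


def test_shc_batch_matches_first_improvement_law(rng):
    dir_costs = rng.uniform(0, 1, size=(200, 30))
    prev = np.full(200, 0.5)
    picks = shc_pick_batch(dir_costs, prev, np.random.default_rng(0))
    for p in (0, 50, 199):
        c = dir_costs[p, picks[p]]
        # accepted direction improves, or nothing improved and it is the best
        assert c < 0.5 or c == dir_costs[p].min()


def test_sample_inplane_prefers_low_cost(rng):
    costs = np.full(36, 0.9)
    costs[11] = 0.1
    picks = [sample_inplane(costs, 20.0, rng) for _ in range(200)]
    assert np.mean(np.asarray(picks) == 11) > 0.5


# ---------------------------------------------------------------------------
# angular threshold adaptation
# ---------------------------------------------------------------------------


def test_eps_lower_clamp_at_grid_spacing():
    eps = update_angular_threshold(np.zeros(50), AngularThreshold(10.0), 2.5)
    assert eps.epsilon == 2.5


def test_eps_tracks_90th_percentile_of_uniform_changes(rng):
    changes = rng.uniform(0, 20, size=5000)
    eps = update_angular_threshold(changes, AngularThreshold(30.0), 1.0)
    assert eps.epsilon == pytest.approx(18.0, abs=0.5)


def test_eps_never_exceeds_previous(rng):
    changes = rng.uniform(30, 50, size=100)
    eps = update_angular_threshold(changes, AngularThreshold(12.0), 1.0)
    assert eps.epsilon == 12.0


def test_eps_unchanged_with_too_few_updates():
    eps = update_angular_threshold(np.array([5.0, 4.0]), AngularThreshold(9.0), 1.0)
    assert eps.epsilon == 9.0
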