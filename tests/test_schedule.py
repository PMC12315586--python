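import numpy as np
import pytest

from probinitio.fourier import DensityVolume, ftn, iftn, shell_index_map, fsc_curve, resolution_at_threshold
from probinitio.schedule import (
    ClassInfo,
    butterworth_lowpass,
    estimate_lowpass_auto,
    plan_frequency_march,
    select_balanced,
    stage_config,
)

# the eight-stage controller, written out once as the reference table
EXPECTED = [
    # stage, search,          regularization, phase, shifts, dirs, iters
    (1, "shc_hybrid", "none", 1, False, 500, 20),
    (2, "shc_hybrid", "none", 1, False, 500, 20),
    (3, "shc_hybrid", "ml", 1, True, 1000, 17),
    (4, "shc_hybrid", "ml", 2, True, 1000, 17),
    (5, "probabilistic", "icm", 2, True, 1000, 17),
    (6, "probabilistic", "icm", 2, True, 1000, 17),
    (7, "probabilistic", "icm", 3, True, 2500, 15),
    (8, "probabilistic", "icm", 3, True, 2500, 30),
]


@pytest.mark.parametrize("row", EXPECTED, ids=[f"stage{r[0]}" for r in EXPECTED])
def test_stage_controller_defaults(row):
    cfg = stage_config(row[0])
    assert (
        cfg.stage,
        cfg.search,
        cfg.regularization,
        cfg.selection_phase,
        cfg.shift_search,
        cfg.max_directions,
        cfg.max_iterations,
    ) == row


def test_stage_out_of_range():
    with pytest.raises(ValueError):
        stage_config(0)
    with pytest.raises(ValueError):
        stage_config(9)


# ---------------------------------------------------------------------------
# balanced selection
# ---------------------------------------------------------------------------


def _classes(sizes, rng, frc=None):
    out = []
    start = 0
    for cid, n in enumerate(sizes):
        members = np.arange(start, start + n)
        out.append(ClassInfo(cid, members, rng.uniform(0, 1, n), frc))
        start += n
    return out


def test_phase1_takes_best_scoring_deterministically(rng):
    classes = _classes([100] * 4, rng)
    sel = select_balanced(classes, 40, 1, rng)
    assert len(sel) == 40
    for ci in classes:
        picked = np.intersect1d(sel, ci.members)
        assert len(picked) == 10
        top10 = ci.members[np.argsort(-ci.scores)[:10]]
        assert set(picked) == set(top10)
    # deterministic: identical on repeat
    sel2 = select_balanced(classes, 40, 1, np.random.default_rng(99))
    assert set(sel) == set(sel2)


def test_phase2_never_selects_below_median(rng):
    classes = _classes([30, 30], rng)
    bottom = set()
    for ci in classes:
        order = np.argsort(-ci.scores)
        bottom |= set(ci.members[order[15:]])
    for _ in range(200):
        sel = select_balanced(classes, 20, 2, rng)
        assert not (set(sel) & bottom)


def test_quota_redistribution_with_unbalanced_classes(rng):
    classes = _classes([5, 100], rng)
    sel = select_balanced(classes, 40, 1, rng)
    assert len(sel) == 40
    assert len(np.intersect1d(sel, classes[0].members)) == 5
    assert len(np.intersect1d(sel, classes[1].members)) == 35


def test_per_class_counts_differ_by_at_most_one(rng):
    classes = _classes([50, 50, 50], rng)
    sel = select_balanced(classes, 31, 3, rng)
    counts = [len(np.intersect1d(sel, c.members)) for c in classes]
    assert max(counts) - min(counts) <= 1


def test_oversized_request_takes_whole_pool(rng):
    classes = _classes([10, 10], rng)
    with pytest.warns(UserWarning, match="pool"):
        sel = select_balanced(classes, 500, 1, rng)
    assert len(sel) == 20


# ---------------------------------------------------------------------------
# frequency marching
# ---------------------------------------------------------------------------


def _frc_crossing_at(shell_cross, n_shells=25, sharp=3.0):
    s = np.arange(n_shells, dtype=float)
    return 1.0 / (1.0 + np.exp((s - shell_cross) * sharp))


def _march_classes(cross_all, cross_best):
    # 6 classes: three mediocre, three good
    classes = []
    for i in range(3):
        classes.append(ClassInfo(i, np.array([i]), np.array([1.0]), _frc_crossing_at(cross_all)))
    for i in range(3, 6):
        classes.append(ClassInfo(i, np.array([i]), np.array([1.0]), _frc_crossing_at(cross_best)))
    return classes


def test_final_limit_upper_clamp():
    # best-3 crossing at 8 A (shell 12 of box 48, 2 A/px): clamps to 6.0
    classes = _march_classes(6, 96 / 8.0)
    plan = plan_frequency_march(classes, 48, 2.0)
    assert plan.lowpass[7] == pytest.approx(6.0)


def test_final_limit_lower_clamp():
    # best-3 crossing at 3 A would be finer than allowed: clamps to 4.5
    classes = _march_classes(8, 23.0)
    plan = plan_frequency_march(classes, 48, 1.0)
    assert plan.lowpass[7] == pytest.approx(4.5)


def test_user_override_only_coarsens():
    classes = _march_classes(6, 12)
    plan = plan_frequency_march(classes, 48, 2.0, user_final_lp=8.0)
    assert plan.lowpass[7] == pytest.approx(8.0)
    plan2 = plan_frequency_march(classes, 48, 2.0, user_final_lp=5.0)
    assert plan2.lowpass[7] == pytest.approx(6.0)  # finer request ignored


def test_intermediate_limits_invert_the_mean_curve():
    # linear-ramp FRC: brute-force curve inversion oracle within one shell
    n = 25
    ramp = np.clip(1.0 - np.arange(n) / 20.0, 0.0, 1.0)
    classes = [ClassInfo(i, np.array([i]), np.array([1.0]), ramp.copy()) for i in range(4)]
    plan = plan_frequency_march(classes, 48, 2.0)
    d = 48 * 2.0
    start_shell = d / plan.lowpass[0]
    final_shell = d / plan.lowpass[7]
    levels = np.linspace(
        np.interp(start_shell, np.arange(n), ramp),
        np.interp(final_shell, np.arange(n), ramp),
        8,
    )
    for i in range(1, 7):
        # oracle: scan shells for the level crossing
        shell_oracle = np.interp(-levels[i], -ramp, np.arange(n))
        shell_ours = d / plan.lowpass[i]
        assert abs(shell_ours - shell_oracle) <= 1.0


def test_march_limits_non_increasing_and_boxes_non_decreasing():
    classes = _march_classes(5, 13)
    plan = plan_frequency_march(classes, 48, 2.0)
    assert np.all(np.diff(plan.lowpass) <= 1e-9)
    assert np.all(np.diff(plan.boxes) >= 0)
    # downscaled sampling matches one third of the limit (within box rounding)
    for lp, b, px in zip(plan.lowpass, plan.boxes, plan.pixel_sizes):
        if b < 48:
            assert px <= lp / 3.0 + 0.55


def test_no_08_crossing_starts_at_default():
    flat = np.full(25, 0.5)
    classes = [ClassInfo(i, np.array([i]), np.array([1.0]), flat.copy()) for i in range(3)]
    with pytest.warns(UserWarning, match="30 A"):
        plan = plan_frequency_march(classes, 48, 2.0)
    assert plan.lowpass[0] == pytest.approx(30.0)


# ---------------------------------------------------------------------------
# automatic low-pass estimation
# ---------------------------------------------------------------------------


def _bandlimited_pair(rng, L=32, cutoff=8, noise=1.0):
    F = np.zeros((L, L, L), dtype=complex)
    shells = shell_index_map((L, L, L))
    F[shells <= cutoff] = rng.normal(size=int(np.sum(shells <= cutoff))) + 1j * rng.normal(
        size=int(np.sum(shells <= cutoff))
    )
    common = np.real(iftn(F))
    common /= common.std()
    even = common + noise * rng.normal(size=(L, L, L))
    odd = common + noise * rng.normal(size=(L, L, L))
    return (
        DensityVolume(even.astype(np.float32), 2.0),
        DensityVolume(odd.astype(np.float32), 2.0),
    )


def test_identical_halves_give_nyquist():
    rng = np.random.default_rng(3)
    even, _ = _bandlimited_pair(rng, noise=0.0)
    lp = estimate_lowpass_auto(even, even, mask_radius=12)
    assert lp == pytest.approx(2 * 2.0 * 32 / 32, rel=0.01)  # Nyquist = 4 A


def test_recovers_bandlimit_of_constructed_pair():
    rng = np.random.default_rng(4)
    even, odd = _bandlimited_pair(rng, cutoff=8, noise=1.0)
    lp = estimate_lowpass_auto(even, odd, mask_radius=12)
    shell = 32 * 2.0 / lp
    assert abs(shell - 8) <= 2


def test_auto_limit_between_fsc_thresholds():
    # the estimate should land between the FSC=0.5 and FSC=0.143 resolutions
    rng = np.random.default_rng(5)
    even, odd = _bandlimited_pair(rng, cutoff=9, noise=0.8)
    lp = estimate_lowpass_auto(even, odd, mask_radius=12)
    fsc = fsc_curve(even, odd)
    r05 = resolution_at_threshold(fsc, 0.5, 32, 2.0)
    r0143 = resolution_at_threshold(fsc, 0.143, 32, 2.0)
    assert r0143 - 0.5 <= lp <= r05 + 0.5


def test_flat_objective_returns_previous():
    z = DensityVolume(np.zeros((32, 32, 32), dtype=np.float32), 2.0)
    lp = estimate_lowpass_auto(z, z, mask_radius=12, previous=9.0)
    assert lp == 9.0


def test_butterworth_preserves_low_and_kills_high(rng):
    vol = DensityVolume(rng.normal(size=(32, 32, 32)).astype(np.float32), 2.0)
    out = butterworth_lowpass(vol, cutoff_shell=6)
    Fi, Fo = ftn(vol.grid), ftn(out.grid)
    shells = shell_index_map((32, 32, 32))
    low = shells <= 3
    high = shells >= 12
    assert np.abs(Fo[low]).sum() / np.abs(Fi[low]).sum() > 0.95
    assert np.abs(Fo[high]).sum() / np.abs(Fi[high]).sum() < 0.05
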