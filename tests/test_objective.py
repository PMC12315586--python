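import numpy as np
import pytest

from probinitio.fourier import (
    CTFParams,
    FourierVolume,
    _slice_grid,
    ctf_image,
    phase_ramp,
    shell_index_map,
)
from probinitio.geometry import random_rotations, rotvec_to_matrix
from probinitio.objective import (
    NoiseSpectrum,
    estimate_noise_power,
    normalized_euclid_cost,
    optimize_shift,
    shift_gradient,
)
from probinitio.simulate import PhantomSpec, make_phantom

L = 32
KMAX = 12


@pytest.fixture(scope="module")
def reference():
    vol = make_phantom(PhantomSpec(box=L, pixel_size=2.0, seed=3))[0]
    fv = FourierVolume.from_density(vol)
    R = random_rotations(1, np.random.default_rng(0))[0]
    return fv.extract_central_slice(R)


def _flat_noise(kmax=KMAX):
    counts = np.array(
        [np.sum(shell_index_map((L, L)) == k) for k in range(1, kmax + 1)], dtype=float
    )
    return NoiseSpectrum(np.ones(kmax), counts, kmax, 2 * np.pi / L)


def _make_particle(reference, shift=(0.0, 0.0), ctf=None):
    p = reference.copy().reshape(-1)
    if ctf is not None:
        p = p * ctf.ravel()
    p = p * phase_ramp(_slice_grid(L), np.asarray(shift, dtype=float), L)[0]
    return p.reshape(L, L)


# ---------------------------------------------------------------------------
# noise power
# ---------------------------------------------------------------------------


def test_noiseless_particle_gives_zero_noise_power(reference):
    p = _make_particle(reference, shift=(1.2, -0.7))
    ns = estimate_noise_power(p, reference, None, (1.2, -0.7), kmax=KMAX)
    signal = np.mean(np.abs(reference) ** 2)
    assert np.all(ns.sigma2 < 1e-10 * signal)


def test_noise_power_estimates_complex_variance(reference, rng):
    # particle = reference + iid complex noise of per-component variance 2 tau^2
    tau = 3.0
    sig = []
    for _ in range(100):
        noise = rng.normal(0, tau, (L, L)) + 1j * rng.normal(0, tau, (L, L))
        ns = estimate_noise_power(reference + noise, reference, None, None, kmax=KMAX)
        sig.append(ns.sigma2)
    mean_sig = np.mean(sig, axis=0)
    big = _flat_noise().ring_counts >= 100
    assert np.allclose(mean_sig[big], 2 * tau**2, rtol=0.05)


def test_noise_power_scales_quadratically(reference, rng):
    taus = (2.0, 4.0)
    out = []
    for tau in taus:
        acc = []
        for _ in range(60):
            noise = rng.normal(0, tau, (L, L)) + 1j * rng.normal(0, tau, (L, L))
            acc.append(estimate_noise_power(reference + noise, reference, None, None, kmax=KMAX).sigma2)
        out.append(np.mean(acc, axis=0))
    assert np.allclose(out[1] / out[0], 4.0, rtol=0.15)


# ---------------------------------------------------------------------------
# normalized cost
# ---------------------------------------------------------------------------


def test_cost_zero_at_exact_match(reference):
    ctf = ctf_image(CTFParams(15000, 13000, astig_angle=20), L, 2.0)
    p = _make_particle(reference, ctf=ctf)
    d = normalized_euclid_cost(p, reference, ctf, None, _flat_noise())
    assert d.d < 1e-10


def test_cost_one_at_antipodal_match(reference):
    d = normalized_euclid_cost(-reference, reference, None, None, _flat_noise())
    assert d.d == pytest.approx(1.0, abs=1e-9)


def test_cost_matches_pixelwise_brute_force(reference, rng):
    """Independent oracle: plain python loop over Cartesian pixels."""
    ctf = ctf_image(CTFParams(15000, 13000, astig_angle=20), L, 2.0)
    p = reference + (rng.normal(size=(L, L)) + 1j * rng.normal(size=(L, L))) * 30
    noise = NoiseSpectrum(
        rng.uniform(0.5, 2.0, KMAX), _flat_noise().ring_counts, KMAX, 2 * np.pi / L
    )
    d = normalized_euclid_cost(p, reference, ctf, None, noise)
    num = den = 0.0
    for i in range(L):
        for j in range(L):
            k = int(round(np.hypot(i - L // 2, j - L // 2)))
            if not 1 <= k <= KMAX:
                continue
            w = 1.0 / noise.sigma2[k - 1]
            hr = ctf[i, j] * reference[i, j]
            num += w * abs(p[i, j] - hr) ** 2
            den += w * (abs(p[i, j]) ** 2 + abs(hr) ** 2)
    assert d.d == pytest.approx(num / (2 * den), rel=1e-6)


def test_cost_invariant_under_consistent_rescaling(reference, rng):
    p = reference + (rng.normal(size=(L, L)) + 1j * rng.normal(size=(L, L))) * 20
    ns = estimate_noise_power(p, reference, None, None, kmax=KMAX)
    d1 = normalized_euclid_cost(p, reference, None, None, ns)
    scaled = NoiseSpectrum(ns.sigma2 * 9.0, ns.ring_counts, KMAX, ns.phase_constant)
    d2 = normalized_euclid_cost(3.0 * p, reference * 3.0, None, None, scaled)
    assert abs(d1.d - d2.d) < 1e-6


def test_degenerate_reference_rejected():
    with pytest.raises(ValueError, match="reference"):
        normalized_euclid_cost(
            np.ones((L, L), dtype=complex),
            np.zeros((L, L), dtype=complex),
            None,
            None,
            _flat_noise(),
        )


def test_cost_increases_with_angular_error(rng):
    vol = make_phantom(PhantomSpec(box=L, pixel_size=2.0, seed=3))[0]
    fv = FourierVolume.from_density(vol)
    R0 = random_rotations(1, rng)[0]
    ref0 = fv.extract_central_slice(R0)
    sigma = 0.5 * np.sqrt(np.mean(np.abs(ref0) ** 2))
    means = []
    for ang in (0.0, 5.0, 15.0):
        Rerr = R0 @ rotvec_to_matrix(np.deg2rad(ang) * np.array([1.0, 0, 0]))
        ref = fv.extract_central_slice(Rerr)
        costs = []
        for _ in range(100):
            p = ref0 + sigma * (rng.normal(size=(L, L)) + 1j * rng.normal(size=(L, L)))
            ns = estimate_noise_power(p, ref, None, None, kmax=KMAX)
            costs.append(normalized_euclid_cost(p, ref, None, None, ns).d)
        means.append(np.mean(costs))
    assert means[0] < means[1] < means[2]


# ---------------------------------------------------------------------------
# shift gradient and optimization
# ---------------------------------------------------------------------------


def test_gradient_matches_finite_differences(reference, rng):
    ctf = ctf_image(CTFParams(15000, 13000, astig_angle=20), L, 2.0)
    ns = _flat_noise()
    for _ in range(50):
        p = reference + (rng.normal(size=(L, L)) + 1j * rng.normal(size=(L, L))) * 10
        s = rng.uniform(-2, 2, 2)
        g = shift_gradient(p, reference, ctf, s, ns)
        eps = 1e-3
        num = np.empty(2)
        for j in range(2):
            sp, sm = s.copy(), s.copy()
            sp[j] += eps
            sm[j] -= eps
            num[j] = (
                normalized_euclid_cost(p, reference, ctf, sp, ns).d
                - normalized_euclid_cost(p, reference, ctf, sm, ns).d
            ) / (2 * eps)
        assert np.linalg.norm(g - num) / max(np.linalg.norm(num), 1e-12) < 1e-4


def test_gradient_vanishes_at_generating_shift(reference):
    s_true = np.array([1.7, -0.9])
    p = _make_particle(reference, shift=s_true)
    g = shift_gradient(p, reference, None, s_true, _flat_noise())
    assert np.linalg.norm(g) < 1e-8


def test_gradient_stationary_point_translates_with_particle(reference):
    # translating the particle by delta moves the optimum by delta
    delta = np.array([1.0, 2.0])
    p = _make_particle(reference, shift=delta)
    g = shift_gradient(p, reference, None, delta, _flat_noise())
    assert np.linalg.norm(g) < 1e-8
    g_off = shift_gradient(p, reference, None, delta + 0.5, _flat_noise())
    assert np.linalg.norm(g_off) > 10 * np.linalg.norm(g)


def test_shift_recovery_from_origin(reference):
    s_true = np.array([2.3, -1.1])
    p = _make_particle(reference, shift=s_true)
    s, cost = optimize_shift(p, reference, None, np.zeros(2), _flat_noise(), bound=5.0)
    assert np.allclose(s, s_true, atol=0.05)
    assert cost.d < 1e-6


def test_optimal_start_returns_same_shift(reference):
    s_true = np.array([1.0, 0.5])
    p = _make_particle(reference, shift=s_true)
    s, _ = optimize_shift(p, reference, None, s_true, _flat_noise(), bound=5.0)
    assert np.allclose(s, s_true, atol=1e-5)


def test_zero_bound_returns_origin(reference):
    p = _make_particle(reference, shift=(2.0, 2.0))
    s, cost = optimize_shift(p, reference, None, np.array([1.0, 1.0]), _flat_noise(), bound=0.0)
    assert np.all(s == 0)
    ref_cost = normalized_euclid_cost(p, reference, None, np.zeros(2), _flat_noise())
    assert cost.d == pytest.approx(ref_cost.d)
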