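"""Microrheology analysis: MSD estimation, GSER conversion, gel points."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinagel import rheolab, synthgen
from retinagel.io import NoGelPointError, NoPlateauError, RetinagelError
from retinagel.rheolab import (GSERParams, ModulusTrace, MSDCurve, Track,
                               brute_force_msd, compute_msd, detect_gel_point,
                               fit_double_exponential, gpc_molecular_weight,
                               microrheology_gel_point, msd_to_moduli,
                               time_to_plateau, young_modulus)


# ------------------------------------------------------------------ MSD

def test_msd_hand_enumeration():
    """Displacement pairs of the 3-point path (0,0)->(1,0)->(1,1)."""
    tr = Track(0, t=[0.0, 1.0, 2.0], x=[0.0, 1.0, 1.0], y=[0.0, 0.0, 1.0])
    curve = compute_msd([tr], max_lag=2.0)
    np.testing.assert_allclose(curve.lag, [1.0, 2.0])
    np.testing.assert_allclose(curve.msd, [1.0, 2.0])


def test_constant_track_msd_zero():
    tr = Track(0, t=np.arange(10.0), x=np.full(10, 3.0), y=np.full(10, -1.0))
    curve = compute_msd([tr], max_lag=3.0)
    np.testing.assert_allclose(curve.msd, 0.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(5, 20), st.integers(0, 10_000))
def test_msd_equals_brute_force_enumeration(n_frames, seed):
    """Vectorized estimator == all-pairs oracle on short random tracks."""
    r = np.random.default_rng(seed)
    tracks = [Track(i, t=np.arange(n_frames, dtype=float),
                    x=r.normal(size=n_frames), y=r.normal(size=n_frames))
              for i in range(3)]
    lags_k = range(1, n_frames // 2 + 1)
    curve = compute_msd(tracks, max_lag=float(n_frames // 2))
    oracle = np.mean([brute_force_msd(tr, lags_k) for tr in tracks], axis=0)
    # per-lag pair counts are equal across tracks, so the plain mean works
    np.testing.assert_allclose(curve.msd, oracle, rtol=1e-12)


def test_brownian_msd_matches_diffusive_closed_form(rng):
    """2D Brownian motion: MSD(tau) = 4 D tau (D from the amplitude)."""
    amplitude = 0.4                       # µm²/s -> D = 0.1 µm²/s
    tracks = synthgen.simulate_tracks_constant_alpha(
        1.0, amplitude, n_beads=100, frame_interval=0.1, duration=20.0,
        rng=rng)
    curve = compute_msd(tracks, max_lag=1.0)
    expected = amplitude * curve.lag
    assert np.all(np.abs(curve.msd - expected) / expected < 0.05)


def test_windowed_msd_returns_curve_per_center():
    rng = np.random.default_rng(0)
    tracks = synthgen.simulate_tracks_constant_alpha(
        1.0, 0.4, n_beads=5, frame_interval=0.1, duration=60.0, rng=rng)
    curves = compute_msd(tracks, window=10.0, every=2.0)
    centers = [c.window_center for c in curves]
    assert centers[0] == pytest.approx(5.0)
    assert np.allclose(np.diff(centers), 2.0)


# ------------------------------------------------------- double exponential

def test_double_exponential_recovers_noiseless_parameters():
    t = np.linspace(0.0, 200.0, 80)
    y = 2.0 * np.exp(-t / 5.0) + 1.0 * np.exp(-t / 50.0) + 0.1
    fit = fit_double_exponential(t, y)
    assert fit.tau1 <= fit.tau2
    for got, want in [(fit.a1, 2.0), (fit.tau1, 5.0), (fit.a2, 1.0),
                      (fit.tau2, 50.0), (fit.c, 0.1)]:
        assert got == pytest.approx(want, rel=1e-4)


def test_double_exponential_constant_series():
    fit = fit_double_exponential(np.arange(10.0), np.full(10, 3.0))
    assert fit.c == pytest.approx(3.0, abs=1e-6)
    assert fit.a1 + fit.a2 == pytest.approx(0.0, abs=1e-6)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)


def test_double_exponential_degenerate_single_exponential():
    t = np.linspace(0.0, 100.0, 50)
    y = 3.0 * np.exp(-t / 20.0)
    fit = fit_double_exponential(t, y)
    assert fit.rss == pytest.approx(0.0, abs=1e-10)
    assert fit(t) == pytest.approx(y, abs=1e-5)


def test_double_exponential_rejects_tiny_series():
    with pytest.raises(ValueError):
        fit_double_exponential([0, 1, 2], [1, 2, 3])


# ----------------------------------------------------------------- GSER

def _power_law_curve(alpha, amplitude=0.1):
    lag = np.geomspace(0.1, 1.0, 10)
    return MSDCurve(lag=lag, msd=amplitude * lag ** alpha,
                    n_pairs=np.full(10, 100), window_center=0.0)


def test_gser_viscous_limit_alpha_one():
    pt = msd_to_moduli(_power_law_curve(1.0), GSERParams())
    assert pt.alpha == pytest.approx(1.0, abs=1e-6)
    assert pt.g_prime == pytest.approx(0.0, abs=1e-9 * pt.g_star)
    assert pt.g_double_prime == pytest.approx(pt.g_star, rel=1e-9)


def test_gser_elastic_limit_alpha_zero():
    pt = msd_to_moduli(_power_law_curve(0.0), GSERParams())
    assert pt.alpha == pytest.approx(0.0, abs=1e-6)
    assert pt.g_double_prime == pytest.approx(0.0, abs=1e-9 * pt.g_star)
    assert pt.g_prime == pytest.approx(pt.g_star, rel=1e-9)


def test_gser_gel_point_condition_alpha_half():
    pt = msd_to_moduli(_power_law_curve(0.5), GSERParams())
    assert pt.g_prime == pytest.approx(pt.g_double_prime, rel=1e-6)


def test_gser_magnitude_brownian_sanity():
    """A purely viscous medium gives G'' = eta * omega with
    eta = kB T / (6 pi a D) (Stokes-Einstein), evaluated at omega=1/tau."""
    amplitude = 0.1                         # MSD2D = amplitude * tau
    d_coeff = amplitude / 4.0 * 1e-12      # m²/s
    params = GSERParams()
    pt = msd_to_moduli(_power_law_curve(1.0, amplitude), params)
    a_m = params.bead_radius * 1e-6
    eta = rheolab.BOLTZMANN_J_PER_K * params.temperature / (6 * math.pi * a_m
                                                            * d_coeff)
    omega = 1.0 / pt.eval_lag
    assert pt.g_double_prime == pytest.approx(eta * omega, rel=1e-2)


# ------------------------------------------------------------- gel point

def test_gel_point_linear_interpolation_example():
    trace = ModulusTrace(t=[0.0, 10.0, 20.0], g_prime=[1.0, 2.0, 4.0],
                         g_double_prime=[3.0, 3.0, 3.0])
    assert detect_gel_point(trace).time == pytest.approx(15.0)


def test_gel_point_error_when_never_crossing():
    trace = ModulusTrace(t=[0.0, 1.0, 2.0], g_prime=[5.0, 6.0, 7.0],
                         g_double_prime=[1.0, 1.0, 1.0])
    with pytest.raises(NoGelPointError):
        detect_gel_point(trace)


def test_gel_point_invariant_to_uniform_modulus_rescaling():
    t = np.linspace(0, 100, 51)
    gp = 1 + t
    gpp = 60.0 - 0.4 * t
    base = detect_gel_point(ModulusTrace(t, gp, gpp)).time
    scaled = detect_gel_point(ModulusTrace(t, 7.3 * gp, 7.3 * gpp)).time
    assert scaled == pytest.approx(base, rel=1e-12)


def test_gel_point_pipeline_recovers_preset_crossover():
    """Full pipeline lands within 10% of the programmed 42 s gel point."""
    preset = synthgen.GELATION_PRESETS["gtn_hpa"]
    estimates = []
    for seed in range(5):
        tracks, truth = synthgen.simulate_gelation_tracks(preset, seed=seed)
        estimates.append(microrheology_gel_point(tracks).time)
    median = float(np.median(estimates))
    assert abs(median - preset.t_gel) / preset.t_gel < 0.10


# --------------------------------------------------------------- plateau

def test_plateau_constant_trace_returns_first_sample():
    t = np.linspace(0, 100, 51)
    trace = ModulusTrace(t, np.full_like(t, 5.0), np.full_like(t, 1.0))
    assert time_to_plateau(trace) == pytest.approx(t[0])


def test_plateau_exponential_rise_matches_closed_form():
    tau, plateau = 30.0, 100.0
    t = np.linspace(0, 300, 151)
    g = plateau * (1 - np.exp(-t / tau))
    trace = ModulusTrace(t, g, np.full_like(t, 1e-9))
    n_tail = max(1, int(np.ceil(0.1 * len(g))))
    p_hat = float(np.mean(g[-n_tail:]))
    # analytic first entry into the band [p_hat(1-eps), p_hat(1+eps)]
    t_star = -tau * np.log(1 - 0.98 * p_hat / plateau)
    result = time_to_plateau(trace, epsilon=0.02)
    assert abs(result - t_star) <= (t[1] - t[0]) + 1e-9


def test_plateau_error_when_always_rising():
    t = np.linspace(0, 100, 101)
    trace = ModulusTrace(t, t.copy(), np.zeros_like(t) + 1e-9)
    with pytest.raises(NoPlateauError):
        time_to_plateau(trace, epsilon=0.02, hold=20.0)


# ------------------------------------------------ compression and GPC

def test_young_modulus_exact_linear():
    strain = np.linspace(0, 0.06, 10)
    assert young_modulus(strain, 5.0 * strain) == pytest.approx(5.0)


def test_young_modulus_noisy_recovery(rng):
    strain = np.linspace(0, 0.07, 40)
    stress = 2532.0 * strain + rng.normal(0, 10.0, size=strain.size)
    from scipy.stats import linregress
    se = linregress(strain, stress).stderr
    assert abs(young_modulus(strain, stress) - 2532.0) < 3 * se


def test_young_modulus_requires_points_in_range():
    with pytest.raises(RetinagelError):
        young_modulus([0.2, 0.3, 0.4], [1.0, 2.0, 3.0])


@pytest.mark.parametrize("vp, expected", [
    (0.0, 10 ** 10.2086),
    (10.2086 / 0.7604, 1.0),
    (10.0, 10 ** (10.2086 - 7.604)),
])
def test_gpc_calibration_curve(vp, expected):
    assert gpc_molecular_weight(vp) == pytest.approx(expected, rel=1e-9)
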