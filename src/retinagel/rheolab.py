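"""Passive-microrheology and oscillatory-rheology analysis.

The module estimates mean square displacements (MSD) from bead tracks,
converts time-resolved MSD windows to complex shear moduli through the
generalized Stokes-Einstein relation (GSER), and locates the gel point
as the G' = G'' crossover.  Helpers cover the double-exponential fit of
MSD decay during gelation, plateau-time detection on oscillatory traces,
compression (Young's) modulus estimation, and the GPC calibration curve.

Model notes
-----------
For a bead of radius ``a`` at temperature ``T`` whose MSD scales locally
as a power law ``MSD(tau) ~ tau**alpha``, the Mason approximation of the
GSER gives, at frequency ``omega = 1/tau``,

    |G*| = d * kB * T / (3 * pi * a * MSD_d(tau) * Gamma(1 + alpha))

with ``d`` the dimensionality of the tracked MSD (2 for in-plane video
tracking), followed by ``G' = |G*| cos(pi alpha / 2)`` and
``G'' = |G*| sin(pi alpha / 2)``.  The crossover G' = G'' happens exactly
at ``alpha = 0.5``, so the gel point is independent of the prefactor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gammaln
from scipy.stats import linregress

from .io import FitError, NoGelPointError, NoPlateauError, RetinagelError, logger

BOLTZMANN_J_PER_K = 1.380649e-23

#: 37 degC, the temperature at which gelation was followed.
DEFAULT_TEMPERATURE_K = 310.15

#: Midpoint radius of 10-20 µm tracer microbeads.
DEFAULT_BEAD_RADIUS_UM = 7.5


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Track:
    """One bead's timestamped 2D trajectory in µm."""

    particle_id: int
    t: np.ndarray      # s, strictly increasing, uniform interval
    x: np.ndarray      # µm
    y: np.ndarray      # µm

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.size < 3:
            raise ValueError("track needs at least 3 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("track times must be strictly increasing")
        if dt.max() > dt.min() * 1.01:
            raise ValueError("track frame interval not uniform within 1%")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class MSDCurve:
    """Ensemble/time-averaged MSD versus lag time."""

    lag: np.ndarray            # s
    msd: np.ndarray            # µm²
    n_pairs: np.ndarray        # displacement pairs per lag
    window_center: float | None = None   # s, set for time-resolved MSD


@dataclass
class ModulusTrace:
    """Time-resolved storage and loss moduli (Pa)."""

    t: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray
    alpha: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.g_prime = np.asarray(self.g_prime, dtype=float)
        self.g_double_prime = np.asarray(self.g_double_prime, dtype=float)
        if not (len(self.t) == len(self.g_prime) == len(self.g_double_prime)):
            raise ValueError("trace vectors must share length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace times must increase")


@dataclass
class DoubleExpFit:
    """y(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2) + c, with tau1 <= tau2."""

    a1: float
    a2: float
    tau1: float
    tau2: float
    c: float
    rss: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (self.a1 * np.exp(-t / self.tau1)
                + self.a2 * np.exp(-t / self.tau2) + self.c)


@dataclass(frozen=True)
class GSERParams:
    """Bead radius (µm), temperature (K) and tracked dimensionality."""

    bead_radius: float = DEFAULT_BEAD_RADIUS_UM
    temperature: float = DEFAULT_TEMPERATURE_K
    dimensionality: int = 2

    def __post_init__(self):
        if self.bead_radius <= 0 or self.temperature <= 0:
            raise ValueError("bead radius and temperature must be positive")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")


@dataclass
class ModuliPoint:
    """GSER moduli evaluated at one lag within one MSD window."""

    g_prime: float
    g_double_prime: float
    alpha: float
    g_star: float
    eval_lag: float
    window_center: float | None = None
    reliable: bool = True


@dataclass
class GelPointResult:
    """Earliest G'=G'' crossover; count of all crossings found."""

    time: float
    n_crossings: int = 1

    def __float__(self) -> float:
        return self.time


# --------------------------------------------------------------------------
# MSD estimation
# --------------------------------------------------------------------------

def _stack_tracks(tracks) -> tuple[np.ndarray, np.ndarray, float]:
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks given")
    dt = tracks[0].frame_interval
    n = len(tracks[0].t)
    for tr in tracks:
        if abs(tr.frame_interval - dt) > 0.01 * dt or len(tr.t) != n:
            raise ValueError("tracks must share frame interval and length")
    xs = np.stack([tr.x for tr in tracks])   # (beads, frames)
    ys = np.stack([tr.y for tr in tracks])
    return xs, ys, dt


def compute_msd(tracks, max_lag: float | None = None,
                window: float | None = None,
                every: float = 2.0):
    """Mean square displacement from a set of synchronized tracks.

    Without ``window`` a single :class:`MSDCurve` is returned, averaging
    |r(t+tau) - r(t)|² over all ordered frame pairs of all beads.  With a
    ``window`` (seconds) the MSD is computed per sliding window of that
    width, centered every ``every`` seconds, and a list of curves is
    returned — the time-resolved form used for gelation analysis.
    """
    xs, ys, dt = _stack_tracks(tracks)
    n_frames = xs.shape[1]
    t0 = tracks[0].t[0]
    duration = (n_frames - 1) * dt
    if max_lag is None:
        max_lag = (window / 4.0) if window is not None else duration / 4.0
    if max_lag <= 0 or max_lag > duration + dt / 2:
        raise ValueError("max_lag leaves no displacement pairs")
    lags_k = np.arange(1, int(round(max_lag / dt)) + 1)

    # per-lag squared displacements for every start frame, all beads
    sq = {}
    for k in lags_k:
        d = (xs[:, k:] - xs[:, :-k]) ** 2 + (ys[:, k:] - ys[:, :-k]) ** 2
        sq[k] = d    # (beads, n_frames - k)

    def curve_for(idx0: int, idx1: int, center: float | None) -> MSDCurve | None:
        lag_list, msd_list, np_list = [], [], []
        for k in lags_k:
            hi = min(idx1 - k, sq[k].shape[1] - 1)
            if hi < idx0:
                continue
            block = sq[k][:, idx0:hi + 1]
            n_pairs = block.size
            if n_pairs == 0:
                logger.warning("lag %.3fs dropped: no pairs", k * dt)
                continue
            if n_pairs < 2:
                logger.warning("lag %.3fs rests on a single pair", k * dt)
            lag_list.append(k * dt)
            msd_list.append(float(block.mean()))
            np_list.append(n_pairs)
        if not lag_list:
            return None
        return MSDCurve(np.array(lag_list), np.array(msd_list),
                        np.array(np_list), window_center=center)

    if window is None:
        return curve_for(0, n_frames - 1, None)

    half = window / 2.0
    centers = np.arange(t0 + half, t0 + duration - half + 1e-9, every)
    curves = []
    for c in centers:
        i0 = int(math.ceil((c - half - t0) / dt))
        i1 = int(math.floor((c + half - t0) / dt))
        cv = curve_for(max(i0, 0), min(i1, n_frames - 1), float(c))
        if cv is not None:
            curves.append(cv)
    return curves


def brute_force_msd(track: Track, lags_k) -> np.ndarray:
    """Direct all-pairs MSD enumeration (oracle for small tracks)."""
    out = []
    for k in lags_k:
        acc = [(track.x[i + k] - track.x[i]) ** 2 +
               (track.y[i + k] - track.y[i]) ** 2
               for i in range(len(track.t) - k)]
        out.append(float(np.mean(acc)))
    return np.array(out)


# --------------------------------------------------------------------------
# Double-exponential decay fit
# --------------------------------------------------------------------------

def _double_exp(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def fit_double_exponential(t, y, n_starts: int = 5) -> DoubleExpFit:
    """Least-squares double-exponential decay with multi-start on the taus.

    Initial (tau1, tau2) pairs are log-spaced over the sampled time range;
    the best-RSS convergent fit wins, ties broken by the smaller tau1.
    Amplitudes and offset are constrained non-negative.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 points for a double-exponential fit")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    span = max(t.max() - t.min(), 1e-9)
    tmin = max(np.diff(np.sort(t)).min(), span * 1e-3)
    taus = np.geomspace(tmin, span * 2, n_starts)
    yspan = max(y.max() - y.min(), 1e-12)
    best: tuple[float, float, np.ndarray] | None = None
    for i, tau1 in enumerate(taus):
        for tau2 in taus[i:]:
            p0 = [yspan, tau1, yspan / 2, tau2, max(y.min(), 0.0)]
            try:
                popt, _ = curve_fit(
                    _double_exp, t, y, p0=p0,
                    bounds=([0, tmin * 1e-3, 0, tmin * 1e-3, 0],
                            [np.inf] * 5),
                    maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((_double_exp(t, *popt) - y) ** 2))
            key = (rss, popt[1])
            if best is None or key < (best[0], best[1]):
                best = (rss, popt[1], popt)
    if best is None:
        raise FitError("double-exponential fit did not converge", best_rss=None)
    rss, _, popt = best
    a1, tau1, a2, tau2, c = popt
    if tau1 > tau2:
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    return DoubleExpFit(a1=a1, a2=a2, tau1=tau1, tau2=tau2, c=c, rss=rss)


# --------------------------------------------------------------------------
# GSER conversion
# --------------------------------------------------------------------------

def msd_to_moduli(msd_window: MSDCurve, params: GSERParams,
                  eval_lag: float | None = None) -> ModuliPoint:
    """Convert one MSD window to (G', G'', alpha) at a single lag.

    ln MSD vs ln tau is fitted with a second-order polynomial; alpha is
    its first derivative at the evaluation lag (default: geometric mean
    of the window's lag range), clamped to [0, 1].  The smoothed MSD at
    that lag feeds the Mason GSER form documented in the module header.
    """
    lag = np.asarray(msd_window.lag, dtype=float)
    msd = np.asarray(msd_window.msd, dtype=float)
    if lag.size < 5:
        raise ValueError("need at least 5 lags in the window")
    if np.any(msd <= 0):
        raise ValueError("MSD must be positive at all fitted lags")
    if eval_lag is None:
        eval_lag = float(np.sqrt(lag[0] * lag[-1]))
    ln_tau = np.log(lag)
    ln_msd = np.log(msd)
    coeffs = np.polyfit(ln_tau, ln_msd, 2)      # c2, c1, c0
    lt = math.log(eval_lag)
    alpha_raw = 2 * coeffs[0] * lt + coeffs[1]
    reliable = -0.1 <= alpha_raw <= 1.1
    if not reliable:
        warnings.warn(
            f"alpha estimate {alpha_raw:.3f} outside [-0.1, 1.1]; clamped",
            RuntimeWarning, stacklevel=2)
    alpha = float(np.clip(alpha_raw, 0.0, 1.0))
    msd_at = math.exp(np.polyval(coeffs, lt))    # µm², smoothed

    a_m = params.bead_radius * 1e-6
    msd_m2 = msd_at * 1e-12
    if params.dimensionality == 2:
        msd_m2 *= 1.5   # isotropic in-plane MSD -> 3D MSD
    gamma = math.exp(gammaln(1.0 + alpha))
    g_star = BOLTZMANN_J_PER_K * params.temperature / (
        math.pi * a_m * msd_m2 * gamma)
    g_prime = g_star * math.cos(math.pi * alpha / 2.0)
    g_double_prime = g_star * math.sin(math.pi * alpha / 2.0)
    return ModuliPoint(g_prime=g_prime, g_double_prime=g_double_prime,
                       alpha=alpha, g_star=g_star, eval_lag=eval_lag,
                       window_center=msd_window.window_center,
                       reliable=reliable)


def moduli_trace(tracks, params: GSERParams | None = None,
                 window: float = 10.0, every: float = 2.0,
                 max_lag: float | None = None) -> ModulusTrace:
    """Time-resolved moduli from tracks: windowed MSD then GSER per window.

    ``max_lag`` defaults to a tenth of the window so the local power-law
    fit stays well inside the window.
    """
    params = params or GSERParams()
    if max_lag is None:
        max_lag = window / 10.0
    curves = compute_msd(tracks, max_lag=max_lag, window=window, every=every)
    pts = [msd_to_moduli(cv, params) for cv in curves]
    return ModulusTrace(
        t=np.array([p.window_center for p in pts]),
        g_prime=np.array([p.g_prime for p in pts]),
        g_double_prime=np.array([p.g_double_prime for p in pts]),
        alpha=np.array([p.alpha for p in pts]))


# --------------------------------------------------------------------------
# Gel point and plateau detection
# --------------------------------------------------------------------------

def detect_gel_point(trace: ModulusTrace) -> GelPointResult:
    """Earliest time where G' crosses G'', by linear interpolation.

    The crossover of the storage and loss moduli defines the gel point.
    Multiple crossings are counted; the earliest is returned.
    """
    diff = trace.g_prime - trace.g_double_prime
    crossings = []
    for i in range(len(diff) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            crossings.append(float(trace.t[i]))
        elif d0 * d1 < 0:
            frac = d0 / (d0 - d1)
            crossings.append(float(trace.t[i] + frac * (trace.t[i + 1] - trace.t[i])))
    if diff[-1] == 0.0:
        crossings.append(float(trace.t[-1]))
    if not crossings:
        raise NoGelPointError("G' and G'' never cross in this trace")
    if len(crossings) > 1:
        logger.info("multiple G'/G'' crossings (%d); earliest returned",
                    len(crossings))
    return GelPointResult(time=crossings[0], n_crossings=len(crossings))


def microrheology_gel_point(tracks, params: GSERParams | None = None,
                            window: float = 10.0, every: float = 2.0,
                            max_lag: float | None = None) -> GelPointResult:
    """Full pipeline: tracks -> windowed MSD -> GSER moduli -> crossover."""
    return detect_gel_point(moduli_trace(tracks, params, window=window,
                                         every=every, max_lag=max_lag))


def time_to_plateau(trace: ModulusTrace, epsilon: float = 0.02,
                    hold: float = 20.0) -> float:
    """Earliest time G' stays within ±epsilon (relative) of its plateau.

    The plateau value is the mean of the final 10% of G'; the trace must
    remain inside the band for at least ``hold`` seconds.
    """
    t, g = trace.t, trace.g_prime
    if t[-1] - t[0] < hold:
        raise ValueError("trace shorter than the hold period")
    n_tail = max(1, int(math.ceil(0.1 * len(g))))
    plateau = float(np.mean(g[-n_tail:]))
    band = epsilon * abs(plateau) if plateau != 0 else epsilon
    inside = np.abs(g - plateau) <= band
    for i in range(len(t)):
        if not inside[i]:
            continue
        j = i
        while j + 1 < len(t) and inside[j + 1]:
            j += 1
        if t[j] - t[i] >= hold or (j == len(t) - 1 and inside[i:].all()
                                   and t[j] - t[i] >= hold):
            return float(t[i])
        # skip past this run
    raise NoPlateauError("G' never stays within the plateau band long enough")


# --------------------------------------------------------------------------
# Compression and GPC helpers
# --------------------------------------------------------------------------

def young_modulus(strain, stress, strain_range=(0.0, 0.07)) -> float:
    """OLS slope of true stress vs strain inside the linear regime (~0-7%)."""
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    lo, hi = strain_range
    mask = (strain >= lo) & (strain <= hi)
    if mask.sum() < 3:
        raise RetinagelError("fewer than 3 points inside the strain range")
    res = linregress(strain[mask], stress[mask])
    return float(res.slope)


def gpc_molecular_weight(vp: float, a0: float = 10.2086,
                         a1: float = -0.7604) -> float:
    """GPC calibration: log10(Mn) = a0 + a1 * Vp, Mn in g/mol."""
    return float(10.0 ** (a0 + a1 * vp))
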