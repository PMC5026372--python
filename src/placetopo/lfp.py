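"""Synthetic local-field-potential surrogate and gamma-trough thermodynamics.

The hippocampal LFP carries two oscillatory components that matter for this
model: a theta wave (4-12 Hz, period T_theta ~= 125 ms) that paces phase
precession, and a broadband gamma wave (30-80 Hz) whose troughs gate spiking.
One theta period contains about seven gamma cycles.  Since the recordings the
model was originally driven by are not available, this module synthesizes a
statistical surrogate: a jittered 8 Hz sinusoid for theta and band-pass
filtered Gaussian noise for gamma, rescaled to unit standard deviation.

The gamma wave is treated as an inhibitory potential over the time axis.
Spiking is suppressed by a Boltzmann factor exp(-beta_gamma * A_gamma(t)), so
deep troughs (A far below the mean) are windows of opportunity.  Near the
i-th trough the wave looks locally like

    A(t) ~= A_0 - A_i cos(omega_i t),

which gives a Gaussian spread of spike times around the trough of

    Delta_i = 1 / sqrt(beta_gamma * A_i * omega_i**2).

Requiring the spread to be about one sixth of the instantaneous gamma period
calibrates the effective temperature to the mean trough amplitude,
1/beta_gamma ~= mean(A_i), i.e. beta = 1/mean(A_i) on the unit-SD scale.
The physiological range of the scaled inverse temperature is 0.5 <= beta <= 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

TWO_PI = 2.0 * math.pi

#: depth (in standard deviations below the mean) above which a trough is "deep"
DEEP_TROUGH_SD = 2.0
#: depth threshold for "very deep" troughs
VERY_DEEP_TROUGH_SD = 3.0


@dataclass(frozen=True)
class LFPSignal:
    """Uniformly sampled surrogate LFP.

    Attributes
    ----------
    t : array, seconds.
    theta : theta-band series (a.u.).
    gamma_raw : gamma-band series before rescaling (a.u.).
    gamma_scaled : A(t) = A_gamma(t)/sigma_gamma, zero mean and unit SD.
    theta_phase : instantaneous theta phase in [0, 2*pi), monotone modulo 2*pi.
    fs : sampling rate, Hz.
    theta_hz : nominal theta frequency, Hz.
    """

    t: np.ndarray
    theta: np.ndarray
    gamma_raw: np.ndarray
    gamma_scaled: np.ndarray
    theta_phase: np.ndarray
    fs: float
    theta_hz: float

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return 0.0 if self.n == 0 else float(self.t[-1])

    @property
    def theta_period(self) -> float:
        return 1.0 / self.theta_hz


class GammaTrough(NamedTuple):
    """A single local minimum of the (scaled) gamma wave.

    ``A_i`` is the instantaneous oscillation amplitude (mean minus trough
    value), ``omega_i`` the instantaneous angular frequency (rad/s), ``a_i``
    the trough offset A_0 - A_i, and ``depth_sd`` the trough depth below the
    mean in units of the signal's standard deviation.
    """

    t_i: float
    A_i: float
    omega_i: float
    a_i: float
    depth_sd: float


@dataclass(frozen=True)
class GammaCoupling:
    """Calibrated gamma-coupling (inverse effective temperature)."""

    beta_gamma: float
    sigma_gamma: float

    @property
    def beta(self) -> float:
        """Scaled inverse temperature beta = beta_gamma * sigma_gamma."""
        return self.beta_gamma * self.sigma_gamma


def synthesize_lfp(
    duration: float,
    fs: float = 1000.0,
    theta_freq: float = 8.0,
    gamma_band: tuple[float, float] = (30.0, 80.0),
    seed: int | None = None,
    theta_jitter: float = 0.10,
    gamma_burst_sigma: float = 0.25,
    gamma_burst_hz: float = 1.3,
) -> LFPSignal:
    """Generate a synthetic LFP with theta and gamma components.

    Theta is a sinusoid at ``theta_freq`` with uniform +/-``theta_jitter``
    cycle-to-cycle amplitude and frequency jitter; its phase is known in
    closed form (piecewise-linear through 2*pi per cycle).  Gamma is Gaussian
    white noise band-pass filtered to ``gamma_band`` (4th-order Butterworth,
    zero-phase), multiplied by a slow lognormal burst envelope
    ``exp(sigma*z - sigma^2/2)`` with ``z`` unit-SD noise low-passed at
    ``gamma_burst_hz`` — the amplitude intermittency of hippocampal gamma,
    whose bursts of a few theta cycles create the domains of high gamma
    amplitude within which the deep troughs cluster — and rescaled to unit
    standard deviation.

    Deterministic given ``seed``.  ``duration == 0`` returns an empty signal.
    """
    if gamma_burst_sigma < 0:
        raise ValueError("gamma_burst_sigma must be >= 0")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    lo, hi = gamma_band
    if not (20.0 <= lo < hi <= 120.0):
        raise ValueError(f"gamma_band {gamma_band} must lie within [20, 120] Hz")
    if not (4.0 <= theta_freq <= 12.0):
        raise ValueError(f"theta_freq {theta_freq} outside the theta band [4, 12] Hz")
    if fs < max(500.0, 4.0 * hi):
        raise ValueError(f"fs={fs} too low to resolve the gamma band (need >= {4 * hi} Hz)")

    if duration == 0:
        empty = np.empty(0)
        return LFPSignal(empty, empty, empty, empty, empty, fs, theta_freq)

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    # theta: jittered cycle durations/amplitudes, phase linear within cycles
    n_cyc = int(math.ceil(duration * theta_freq * (1.0 + 2 * theta_jitter))) + 2
    periods = (1.0 / theta_freq) * (1.0 + theta_jitter * rng.uniform(-1, 1, n_cyc))
    amps = 1.0 + theta_jitter * rng.uniform(-1, 1, n_cyc)
    edges = np.concatenate(([0.0], np.cumsum(periods)))
    phase_unwrapped = np.interp(t, edges, TWO_PI * np.arange(n_cyc + 1))
    cyc_idx = np.minimum(np.searchsorted(edges, t, side="right") - 1, n_cyc - 1)
    theta = amps[cyc_idx] * np.cos(phase_unwrapped)

    # gamma: band-limited Gaussian noise, unit-SD scaled
    white = rng.standard_normal(n)
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    gamma_raw = _sig.sosfiltfilt(sos, white)
    if gamma_burst_sigma > 0 and n > 30:
        # stationary AR(1)/OU log-envelope, correlation time 1/(2*pi*burst_hz)
        a = math.exp(-TWO_PI * gamma_burst_hz / fs)
        innov = rng.standard_normal(n) * math.sqrt(1.0 - a * a)
        innov[0] = rng.standard_normal()  # stationary start, unit variance
        z = _sig.lfilter([1.0], [1.0, -a], innov)
        gamma_raw = gamma_raw * np.exp(
            gamma_burst_sigma * z - gamma_burst_sigma**2 / 2.0
        )
    gamma_scaled = scale_gamma(gamma_raw)

    return LFPSignal(
        t=t,
        theta=theta,
        gamma_raw=gamma_raw,
        gamma_scaled=gamma_scaled,
        theta_phase=np.mod(phase_unwrapped, TWO_PI),
        fs=fs,
        theta_hz=theta_freq,
    )


def scale_gamma(gamma_raw: np.ndarray) -> np.ndarray:
    """Center and rescale the gamma wave to zero mean and unit SD.

    Raises ``ValueError`` on a constant series (sigma_gamma = 0).
    """
    x = np.asarray(gamma_raw, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("cannot scale a constant gamma series (sigma_gamma = 0)")
    return (x - np.mean(x)) / sd


def detect_troughs(gamma_scaled: np.ndarray, fs: float) -> list[GammaTrough]:
    """Find every local minimum of the gamma wave lying below the signal mean.

    Each trough is fitted with the local oscillation model
    ``A(t) ~= A_0 - A_i cos(omega_i (t - t_i))``: the trough time and value
    come from a three-point parabolic refinement of the sampled minimum, the
    amplitude is ``A_i = mean - A(t_i)``, and ``omega_i`` is solved exactly
    from the cosine identity at a probe lag of about one sixth of the local
    period (falling back to the discrete curvature at the array boundary).

    ``depth_sd`` is the depth below the mean divided by the signal SD, so on
    a unit-SD input it equals ``A_i``.  Troughs at depth >= 2 SD are "deep",
    >= 3 SD "very deep" (see :func:`deep_troughs`).
    """
    y = np.asarray(gamma_scaled, dtype=float)
    if y.size == 0:
        return []
    if y.size < 3:
        return []
    mean = float(np.mean(y))
    sd = float(np.std(y))
    if sd == 0.0:
        return []
    dt = 1.0 / fs

    interior = np.arange(1, y.size - 1)
    is_min = (y[interior] < y[interior - 1]) & (y[interior] <= y[interior + 1])
    idx = interior[is_min & (y[interior] < mean)]
    if idx.size == 0:
        return []

    # probe lag ~ one sixth of the typical trough spacing
    span = (idx[-1] - idx[0]) * dt if idx.size > 1 else dt
    mean_spacing = span / max(idx.size - 1, 1)
    k = max(1, int(round(mean_spacing / (6.0 * dt))))

    troughs: list[GammaTrough] = []
    for i in idx:
        ym1, y0, yp1 = y[i - 1], y[i], y[i + 1]
        denom = ym1 - 2.0 * y0 + yp1
        if denom > 0:
            delta = 0.5 * (ym1 - yp1) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        t_i = (i + delta) * dt
        y_min = y0 - 0.25 * (ym1 - yp1) * delta
        A_i = mean - y_min
        if A_i <= 0:
            continue

        if i - k >= 0 and i + k < y.size:
            # exact inversion of the local cosine model at lag k*dt
            c = 0.5 * ((mean - y[i - k]) + (mean - y[i + k])) / A_i
            c = float(np.clip(c, -0.999, 0.999))
            omega = math.acos(c) / (k * dt)
        else:
            curv = max(denom, 0.0) / dt**2
            omega = math.sqrt(curv / A_i) if curv > 0 else float("nan")

        troughs.append(
            GammaTrough(
                t_i=float(t_i),
                A_i=float(A_i),
                omega_i=float(omega),
                a_i=float(mean - A_i),
                depth_sd=float(A_i / sd),
            )
        )
    return troughs


def deep_troughs(
    troughs: Sequence[GammaTrough], min_depth_sd: float = DEEP_TROUGH_SD
) -> list[GammaTrough]:
    """Troughs deeper than ``min_depth_sd`` standard deviations below the mean."""
    return [g for g in troughs if g.depth_sd >= min_depth_sd]


def expected_spread(trough: GammaTrough, beta_gamma: float) -> float:
    """Gaussian spread Delta_i of spikes around one trough.

    Delta_i = 1/sqrt(beta_gamma * A_i * omega_i**2).  At beta_gamma = 0 the
    assembly is infinitely hot and the spread is unbounded (returns ``inf``).
    """
    if beta_gamma < 0:
        raise ValueError("beta_gamma must be >= 0")
    if trough.A_i <= 0:
        raise ValueError("trough amplitude must be positive")
    if beta_gamma == 0:
        return float("inf")
    return 1.0 / math.sqrt(beta_gamma * trough.A_i * trough.omega_i**2)


def calibrate_beta(
    troughs: Sequence[GammaTrough], sigma_gamma: float = 1.0
) -> GammaCoupling:
    """Calibrate the inverse effective temperature from the trough statistics.

    The spike spread at a trough matches the empirically typical one gamma
    period / 6 when 1/beta_gamma equals the mean trough amplitude, so on the
    unit-SD scale beta = 1/mean(A_i).
    """
    if len(troughs) == 0:
        raise ValueError("cannot calibrate beta from an empty trough list")
    mean_amp = float(np.mean([g.A_i for g in troughs]))
    beta = 1.0 / mean_amp
    return GammaCoupling(beta_gamma=beta / sigma_gamma, sigma_gamma=sigma_gamma)


def gamma_phase(lfp: LFPSignal) -> np.ndarray:
    """Instantaneous gamma phase via the analytic signal, in (-pi, pi].

    Troughs of the gamma wave sit at phase +/- pi.
    """
    return np.angle(_sig.hilbert(lfp.gamma_scaled))


# ---------------------------------------------------------------- CSV I/O

def lfp_to_csv(lfp: LFPSignal, path) -> None:
    """Write (t_s, theta, gamma_scaled) with a header."""
    pd.DataFrame(
        {"t_s": lfp.t, "theta": lfp.theta, "gamma_scaled": lfp.gamma_scaled}
    ).to_csv(path, index=False)


def lfp_from_csv(path, theta_hz: float = 8.0) -> LFPSignal:
    """Read an LFP written by :func:`lfp_to_csv`.

    The theta phase is recovered from the analytic signal of the theta
    column; the raw gamma column is taken equal to the scaled one.
    """
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    theta = df["theta"].to_numpy(float)
    g = df["gamma_scaled"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 0.0
    phase = np.mod(np.unwrap(np.angle(_sig.hilbert(theta))), TWO_PI) if t.size else np.empty(0)
    return LFPSignal(t, theta, g, g, phase, fs, theta_hz)
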