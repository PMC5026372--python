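"""Theta/gamma-modulated place-cell spike generation and spike statistics.

The net Poisson rate of a place cell is the product of three factors,

    lambda_net(t) = lambda_c(r(t)) * Lambda_theta(phi(t)) * Lambda_gamma(A(t)),

evaluated while the animal is inside the cell's place field (the disc of
diameter L_c = 3 s_c around the field center; outside, the rate is zero).

* ``lambda_c`` is the spatial Gaussian rate (:mod:`placetopo.ensemble`).
* ``Lambda_theta`` implements phase precession: as the animal travels a
  path length ``l(t)`` into the field, the preferred theta phase advances,
  phi_pref = 2*pi*(1 - l/L_c), and spiking is gated by a circular Gaussian
  of width epsilon = 2*pi*v / (L_c * omega_theta) around it.
* ``Lambda_gamma`` is the Boltzmann factor exp(-beta * A(t)) of the gamma
  wave viewed as an inhibitory potential: cooling (raising beta) confines
  spiking to the gamma troughs and, through the shared deep troughs of the
  gamma bursts, synchronizes the cells of an assembly.  It is applied
  unnormalized by default, so cooling also boosts firing at the troughs
  (assembly sizes grow with beta); mean-preserving per-cell or per-session
  normalizations are available as options.

The theta gate is divided by its average over uniform phase, so ``f_c``
sets the realized in-field rate scale (the ensemble's stated mean rate)
rather than being cut ~25-fold by the tuning width.  That width is the
fraction of the field crossed per theta cycle, eps = v*T_theta/L_c,
expressed as a phase width 2*pi*eps (~0.65 rad at the defaults, matching
measured CA1 phase locking).

Spike counts per bin are Poisson(lambda_net * dt) — several spikes in one
gamma trough model the burst discharge of a cell within a cycle; spikes
within a bin are spread evenly over the bin to keep times strictly
increasing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import Trajectory
from .ensemble import PlaceCell, PlaceMap
from .lfp import DEEP_TROUGH_SD, GammaTrough, LFPSignal, deep_troughs, gamma_phase

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SpikeTrain:
    cell_id: int
    times: np.ndarray  # strictly increasing spike times, s

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SpreadEstimate:
    """Temporal spread Delta_beta of assembly spiking around deep gamma troughs."""

    beta: float
    delta: float  # robust full width of spike offsets around deep troughs, s
    n_events: int  # number of coactivity episodes pooled

    @property
    def valid(self) -> bool:
        return self.n_events >= 1 and np.isfinite(self.delta)


# ------------------------------------------------------------- modulation

def path_cumlen(trajectory: Trajectory) -> np.ndarray:
    """Cumulative path length along the trajectory (shared across cells)."""
    n = trajectory.x.size
    steps = np.zeros(n)
    steps[1:] = np.hypot(np.diff(trajectory.x), np.diff(trajectory.y))
    return np.cumsum(steps)


def field_traversal(
    cell: PlaceCell, trajectory: Trajectory, cumlen: np.ndarray | None = None
) -> np.ndarray:
    """Path length traveled into the place field, per time sample.

    The field is the disc of radius L_c/2 around the center.  On each entry
    the counter resets to zero and accumulates the path length along the
    trajectory, capped at L_c; samples outside the field are NaN.  A
    precomputed :func:`path_cumlen` may be passed to amortize the arc-length
    sum over an ensemble.
    """
    x, y = trajectory.x, trajectory.y
    cx, cy = cell.r_c
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= (cell.L_c / 2.0) ** 2
    n = x.size
    l_t = np.full(n, np.nan)
    if n == 0 or not inside.any():
        return l_t

    if cumlen is None:
        cumlen = path_cumlen(trajectory)

    entry = inside.copy()
    entry[1:] = inside[1:] & ~inside[:-1]
    idx = np.arange(n)
    last_entry = np.maximum.accumulate(np.where(entry, idx, -1))
    valid = inside & (last_entry >= 0)
    l_t[valid] = cumlen[valid] - cumlen[last_entry[valid]]
    np.minimum(l_t, cell.L_c, out=l_t)
    return l_t


def preferred_phase(l, L_c: float) -> np.ndarray:
    """Preferred theta phase phi_pref = 2*pi*(1 - l/L_c), reduced mod 2*pi."""
    l = np.asarray(l, dtype=float)
    if np.any(l > L_c * (1 + 1e-9)):
        warnings.warn("l exceeds the field extent L_c; clamping", stacklevel=2)
        l = np.minimum(l, L_c)
    return np.mod(TWO_PI * (1.0 - l / L_c), TWO_PI)


def tuning_width(v: float, L_c: float, omega_theta: float) -> float:
    """Theta-tuning width epsilon = 2*pi*v / (L_c * omega_theta), radians.

    This is the mean distance traveled per theta cycle relative to the field
    extent; ``v`` is the session-mean speed.
    """
    return TWO_PI * v / (L_c * omega_theta)


def circular_diff(a, b):
    """Shortest signed angular distance a - b, in (-pi, pi]."""
    return np.mod(np.asarray(a) - np.asarray(b) + math.pi, TWO_PI) - math.pi


def theta_factor(phi, phi_pref, epsilon: float) -> np.ndarray:
    """Circular-Gaussian theta gate Lambda_theta in (0, 1]."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = circular_diff(phi, phi_pref)
    return np.exp(-(d**2) / (2.0 * epsilon**2))


def theta_gate_normalizer(epsilon: float) -> float:
    """Average of the theta gate over uniform phase.

    Z_theta = (1/2pi) * int_{-pi}^{pi} exp(-u^2 / (2 eps^2)) du
            = eps/sqrt(2pi) * erf(pi / (sqrt(2) eps)).

    Dividing the gate by Z_theta makes precession redistribute spikes
    within the theta cycle while preserving the mean in-field rate, exactly
    as the session normalization of the gamma gate does across the session.
    """
    from scipy.special import erf

    return float(
        epsilon / math.sqrt(TWO_PI) * erf(math.pi / (math.sqrt(2.0) * epsilon))
    )


def gamma_factor(A_t, beta: float, session_normalizer: float | None = None,
                 normalize: bool = True) -> np.ndarray:
    """Boltzmann gamma gate Lambda_gamma(t) = exp(-beta*A(t)) / Z.

    ``Z`` is the session time-average of exp(-beta*A) so that the
    time-average of the gate is one and the mean rate is beta-invariant; a
    precomputed ``session_normalizer`` may be supplied, or ``normalize=False``
    returns the raw (unnormalized) factor.  ``beta = 0`` gives the
    "infinitely hot" gate, identically one.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    A_t = np.asarray(A_t, dtype=float)
    if beta == 0:
        return np.ones_like(A_t)
    w = np.exp(-beta * A_t)
    if not normalize:
        return w
    Z = float(np.mean(w)) if session_normalizer is None else float(session_normalizer)
    return w / Z


# ------------------------------------------------------------- generation

def _check_grids(trajectory: Trajectory, lfp: LFPSignal) -> float:
    if trajectory.n != lfp.n:
        raise ValueError(
            f"trajectory grid ({trajectory.n}) and LFP grid ({lfp.n}) differ"
        )
    dt = trajectory.dt
    if not math.isclose(dt, 1.0 / lfp.fs, rel_tol=1e-9):
        raise ValueError("trajectory dt and LFP sampling rate are inconsistent")
    if dt > 0.002 + 1e-12:
        raise ValueError("dt must be <= 2 ms to resolve the gamma band")
    return dt


def generate_spikes(
    cell: PlaceCell,
    trajectory: Trajectory,
    lfp: LFPSignal,
    beta: float,
    seed=None,
    *,
    gamma_normalization: str = "raw",
    gamma_clip_sd: float | None = 3.0,
    theta_modulation: bool = True,
    lambda_theta_normalized: bool = True,
    rng: np.random.Generator | None = None,
    cumlen: np.ndarray | None = None,
) -> SpikeTrain:
    """Draw one cell's spike train from lambda_net by per-bin Poisson counts.

    ``gamma_normalization`` selects the Boltzmann gate's normalizer:
    ``"raw"`` (default) applies e^{-beta A} unnormalized, as the Boltzmann
    factor is written; ``"cell"`` divides by the cell's rate-weighted
    average of e^{-beta A} (expected spike count beta-invariant);
    ``"session"`` divides by the session time-average (mean-one gate).
    The potential A(t) is saturated at ``+-gamma_clip_sd`` standard
    deviations (inhibition cannot grow without bound; troughs beyond the
    "very deep" class act alike), which keeps the Boltzmann weights of a
    session within a bounded dynamic range.
    ``theta_modulation=False`` disables the precession gate, which together
    with ``beta = 0`` reduces the generator to an inhomogeneous spatial
    Poisson process.  Deterministic given ``seed``.
    """
    if gamma_normalization not in ("cell", "session", "raw"):
        raise ValueError("gamma_normalization must be 'cell', 'session' or 'raw'")
    dt = _check_grids(trajectory, lfp)
    if rng is None:
        rng = np.random.default_rng(seed)

    l_t = field_traversal(cell, trajectory, cumlen=cumlen)
    mask = np.isfinite(l_t)
    if not mask.any():
        return SpikeTrain(cell.id, np.empty(0))

    cx, cy = cell.r_c
    d2 = (trajectory.x[mask] - cx) ** 2 + (trajectory.y[mask] - cy) ** 2
    lam = cell.f_c * np.exp(-d2 / (2.0 * cell.s_c**2))

    if theta_modulation:
        eps = TWO_PI * tuning_width(
            trajectory.v_mean, cell.L_c, TWO_PI * lfp.theta_hz
        )  # cycle fraction -> phase width, rad
        phi_pref = preferred_phase(l_t[mask], cell.L_c)
        gate = theta_factor(lfp.theta_phase[mask], phi_pref, eps)
        if lambda_theta_normalized:
            gate = gate / theta_gate_normalizer(eps)
        lam = lam * gate

    if beta > 0:
        A = lfp.gamma_scaled
        if gamma_clip_sd is not None:
            A = np.clip(A, -gamma_clip_sd, gamma_clip_sd)
        w_gamma = np.exp(-beta * A[mask])
        if gamma_normalization == "cell":
            w_gamma /= float(np.sum(lam * w_gamma) / np.sum(lam))
        elif gamma_normalization == "session":
            w_gamma /= float(np.mean(np.exp(-beta * A)))
        lam = lam * w_gamma

    counts = np.zeros(trajectory.n, dtype=np.int64)
    counts[mask] = rng.poisson(lam * dt)
    return SpikeTrain(cell.id, _bins_to_times(counts, trajectory.t, dt))


def _bins_to_times(counts: np.ndarray, t: np.ndarray, dt: float) -> np.ndarray:
    """Spread k spikes evenly inside each bin so times stay strictly increasing."""
    idx = np.nonzero(counts)[0]
    if idx.size == 0:
        return np.empty(0)
    k = counts[idx]
    total = int(k.sum())
    reps = np.repeat(idx, k)
    pos = np.arange(total) - np.repeat(np.cumsum(k) - k, k)
    within = (pos + 0.5) / np.repeat(k, k)
    return t[reps] + (within - 0.5) * dt * 0.99


def generate_ensemble_spikes(
    place_map: PlaceMap,
    trajectory: Trajectory,
    lfp: LFPSignal,
    beta: float,
    seed=None,
    *,
    gamma_normalization: str = "raw",
    gamma_clip_sd: float | None = 3.0,
    theta_modulation: bool = True,
    lambda_theta_normalized: bool = True,
) -> list[SpikeTrain]:
    """Spike trains for every cell of the ensemble, one child seed per cell.

    Per-cell randomness comes from ``SeedSequence(seed).spawn``, so any
    cell's train is reproducible independently of the others.
    """
    _check_grids(trajectory, lfp)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(place_map.N)
    cumlen = path_cumlen(trajectory)
    return [
        generate_spikes(
            cell,
            trajectory,
            lfp,
            beta,
            gamma_normalization=gamma_normalization,
            gamma_clip_sd=gamma_clip_sd,
            theta_modulation=theta_modulation,
            lambda_theta_normalized=lambda_theta_normalized,
            rng=np.random.default_rng(children[i]),
            cumlen=cumlen,
        )
        for i, cell in enumerate(place_map.cells)
    ]


# ------------------------------------------------------------- statistics

def spike_spread(
    trains: Sequence[SpikeTrain],
    troughs: Sequence[GammaTrough],
    theta_period: float,
    beta: float = float("nan"),
    min_depth_sd: float = DEEP_TROUGH_SD,
    quantile: float = 68.0,
) -> SpreadEstimate:
    """Temporal spread of assembly coactivity around deep gamma troughs.

    The session is tiled into theta periods; every period in which at least
    two distinct cells spiked is a coactivity episode.  All episode spikes
    are pooled by their offset from the nearest deep trough (depth >=
    ``min_depth_sd`` SD) and Delta_beta is twice the ``quantile``-th
    percentile of the absolute offsets — for the default 68 this is the
    Gaussian-equivalent 2-sigma full width, robust to the diffuse
    background of coactivity unrelated to any deep trough.
    """
    deep = deep_troughs(troughs, min_depth_sd)
    active = [tr for tr in trains if tr.n > 0]
    if len(active) < 2 or not deep:
        return SpreadEstimate(beta, float("nan"), 0)

    times = np.concatenate([tr.times for tr in active])
    cells = np.concatenate([np.full(tr.n, tr.cell_id) for tr in active])
    order = np.argsort(times)
    times, cells = times[order], cells[order]

    period_idx = np.floor(times / theta_period).astype(np.int64)
    # episodes: theta periods containing >= 2 distinct cells
    offsets = []
    n_events = 0
    trough_times = np.array([g.t_i for g in deep])
    start = 0
    while start < times.size:
        stop = start
        while stop < times.size and period_idx[stop] == period_idx[start]:
            stop += 1
        if np.unique(cells[start:stop]).size >= 2:
            n_events += 1
            ts = times[start:stop]
            j = np.clip(np.searchsorted(trough_times, ts), 1, trough_times.size - 1)
            nearest = np.where(
                np.abs(ts - trough_times[j - 1]) <= np.abs(ts - trough_times[j]),
                trough_times[j - 1],
                trough_times[j],
            )
            offsets.append(ts - nearest)
        start = stop

    if n_events == 0:
        return SpreadEstimate(beta, float("nan"), 0)
    pooled = np.abs(np.concatenate(offsets))
    return SpreadEstimate(beta, float(2.0 * np.percentile(pooled, quantile)), n_events)


def _log_bins(lo: float = 1e-3, hi: float = 2.0, n: int = 60) -> np.ndarray:
    return np.geomspace(lo, hi, n + 1)


def isi_stats(train: SpikeTrain, bins: np.ndarray | None = None):
    """Normalized inter-spike-interval histogram on a log-spaced lag axis.

    Returns ``(hist, bin_edges)``; empty histogram if fewer than 2 spikes.
    """
    if bins is None:
        bins = _log_bins()
    if train.n < 2:
        return np.zeros(bins.size - 1), bins
    isi = np.diff(train.times)
    h, _ = np.histogram(isi, bins=bins)
    total = h.sum()
    return (h / total if total else h.astype(float)), bins


def pooled_isi_hist(trains: Sequence[SpikeTrain], bins: np.ndarray | None = None):
    """ISI histogram pooled over all cells (each cell's own ISIs)."""
    if bins is None:
        bins = _log_bins()
    h = np.zeros(bins.size - 1)
    for tr in trains:
        if tr.n >= 2:
            hh, _ = np.histogram(np.diff(tr.times), bins=bins)
            h += hh
    total = h.sum()
    return (h / total if total else h), bins


def trough_interval_stats(
    troughs: Sequence[GammaTrough],
    depth_threshold: float = DEEP_TROUGH_SD,
    bins: np.ndarray | None = None,
):
    """Histogram of intervals between successive deep troughs (same axis)."""
    if bins is None:
        bins = _log_bins()
    deep = deep_troughs(troughs, depth_threshold)
    if len(deep) < 2:
        return np.zeros(bins.size - 1), bins
    iv = np.diff([g.t_i for g in deep])
    h, _ = np.histogram(iv, bins=bins)
    total = h.sum()
    return (h / total if total else h.astype(float)), bins


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two histograms on matched bins."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def gamma_phase_histogram(
    trains: Sequence[SpikeTrain], lfp: LFPSignal, n_bins: int = 36
):
    """Circular histogram of the gamma phase at spike times.

    Returns ``(hist, bin_edges, circular_variance)``.  Gamma troughs sit at
    phase +/- pi, so tighter gamma coupling concentrates mass there and the
    circular variance 1 - |mean(exp(i*phi))| decreases with beta.
    """
    phases = gamma_phase(lfp)
    all_idx = [
        np.clip(np.round(tr.times * lfp.fs).astype(np.int64), 0, lfp.n - 1)
        for tr in trains
        if tr.n
    ]
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    if not all_idx:
        return np.zeros(n_bins), edges, float("nan")
    ph = phases[np.concatenate(all_idx)]
    h, _ = np.histogram(ph, bins=edges)
    circ_var = 1.0 - float(np.abs(np.mean(np.exp(1j * ph))))
    total = h.sum()
    return (h / total if total else h.astype(float)), edges, circ_var


# ---------------------------------------------------------------- CSV I/O

def spikes_to_csv(trains: Sequence[SpikeTrain], path) -> None:
    """Write (cell_id, t_s) sorted by time."""
    cell_ids = np.concatenate([np.full(tr.n, tr.cell_id) for tr in trains]) if trains else np.empty(0, int)
    times = np.concatenate([tr.times for tr in trains]) if trains else np.empty(0)
    order = np.argsort(times, kind="stable")
    pd.DataFrame({"cell_id": cell_ids[order].astype(int), "t_s": times[order]}).to_csv(
        path, index=False
    )


def spikes_from_csv(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(int(cid), np.sort(grp["t_s"].to_numpy(float)))
        for cid, grp in df.groupby("cell_id")
    ]
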