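"""Sweeps over gamma coupling (beta) and readout window (w); result tables.

This module wires the full pipeline — synthetic LFP, exploratory
trajectory, place-cell ensemble, gamma-modulated spiking, coactivity
complex, persistent homology — into reproducible parameter sweeps:

* :func:`run_condition` runs one (beta, w, complex kind) cell and returns a
  result row with the 2-simplex count, total loop count, learning time and
  assembly spike spread;
* :func:`run_sweep` runs the full beta x w x seed grid of a
  :class:`SweepConfig`;
* :func:`run_ensemble_map` maps mean learning time over (field size, cell
  count) grids, averaging several place-field maps per point.

Seed scheme: a single master seed is expanded into named streams via
``numpy.random.SeedSequence([master, crc32(name), index])``, so every
artifact (LFP, trajectory, map, spikes) draws from an independent,
reproducible stream and tables are byte-identical across reruns.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field as _field
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import Arena, Trajectory, default_arena, simulate_trajectory
from .complexes import (
    DEFAULT_HORIZON,
    build_clique_complex,
    build_coactivity_graph,
    build_simplicial_complex,
    count_simplexes,
    detect_coactivity,
)
from .ensemble import PlaceMap, PlaceMapParams, generate_place_map
from .lfp import LFPSignal, detect_troughs, synthesize_lfp
from .spiking import SpikeTrain, generate_ensemble_spikes, spike_spread
from .topology import (
    count_loops,
    default_grid,
    betti_timeline,
    learning_time,
    persistent_homology,
)

log = logging.getLogger("placetopo")

THETA_HZ = 8.0
THETA_PERIOD = 1.0 / THETA_HZ  # 125 ms
GAMMA_PERIOD = THETA_PERIOD / 7.0  # ~17.9 ms: one theta period holds ~7 gamma cycles

#: readout windows of the headline sweep, in units of the theta period,
#: plus the gamma-period window
SWEEP_WINDOW_FACTORS = (2.0, 1.2, 0.8, 0.5, 0.3, 0.2)


def default_windows() -> list[float]:
    return [f * THETA_PERIOD for f in SWEEP_WINDOW_FACTORS] + [GAMMA_PERIOD]


def derive_seed(master_seed: int, *keys) -> np.random.SeedSequence:
    """Stable named sub-stream: strings are hashed with crc32, ints kept."""
    entropy = [int(master_seed)]
    for k in keys:
        entropy.append(zlib.crc32(k.encode()) if isinstance(k, str) else int(k))
    return np.random.SeedSequence(entropy)


def seed_int(master_seed: int, *keys) -> int:
    """A plain integer seed (< 2**31) derived from the named stream."""
    return int(derive_seed(master_seed, *keys).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepConfig:
    betas: tuple[float, ...] = tuple(np.arange(0.0, 2.01, 0.25))
    windows: tuple[float, ...] = tuple(default_windows())
    complex_kind: str = "simplicial"  # or "clique"
    map_params: PlaceMapParams = PlaceMapParams()
    duration: float = 1500.0  # 25 min session
    n_seeds: int = 5
    master_seed: int = 0
    horizon: float = DEFAULT_HORIZON
    target_betti: tuple[int, int] = (1, 1)
    grid_step: float = 15.0
    mean_speed: float = 0.20

    def __post_init__(self):
        if any(b < 0 for b in self.betas):
            raise ValueError("betas must be >= 0")
        if any(w <= 0 for w in self.windows):
            raise ValueError("windows must be positive")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.complex_kind not in ("simplicial", "clique"):
            raise ValueError("complex_kind must be 'simplicial' or 'clique'")


def session_inputs(
    master_seed: int,
    seed_index: int,
    duration: float,
    arena: Arena | None = None,
    map_params: PlaceMapParams | None = None,
    mean_speed: float = 0.20,
    fs: float = 1000.0,
):
    """Shared per-seed artifacts: (arena, lfp, trajectory, place map)."""
    arena = default_arena() if arena is None else arena
    map_params = PlaceMapParams() if map_params is None else map_params
    lfp = synthesize_lfp(duration, fs=fs, theta_freq=THETA_HZ,
                         seed=derive_seed(master_seed, "lfp", seed_index))
    traj = simulate_trajectory(arena, duration, dt=1.0 / fs, mean_speed=mean_speed,
                               seed=derive_seed(master_seed, "trajectory", seed_index))
    pmap = generate_place_map(map_params, arena,
                              seed=derive_seed(master_seed, "map", seed_index))
    return arena, lfp, traj, pmap


def build_complex(
    trains: Sequence[SpikeTrain],
    w: float,
    kind: str = "simplicial",
    t_end: float | None = None,
    horizon: float = DEFAULT_HORIZON,
):
    """Events -> coactivity complex of the requested readout kind."""
    events = detect_coactivity(trains, w, t_end=t_end)
    if kind == "simplicial":
        return build_simplicial_complex(events)
    if kind == "clique":
        graph = build_coactivity_graph(trains, w, t_end=t_end, events=events)
        return build_clique_complex(graph, horizon=horizon)
    raise ValueError(f"unknown complex kind {kind!r}")


def run_condition(
    place_map: PlaceMap,
    trajectory: Trajectory,
    lfp: LFPSignal,
    beta: float,
    w: float,
    complex_kind: str = "simplicial",
    seed=0,
    horizon: float = DEFAULT_HORIZON,
    target_betti: tuple[int, int] = (1, 1),
    grid_step: float = 15.0,
    troughs=None,
) -> dict:
    """One sweep cell: simulate spiking, build the complex, extract topology.

    Returns a row dict with keys (beta, w, seed, n_spikes, N2_end, Nl1,
    t_min, diverged, delta_spread).  Deterministic given ``seed``.
    """
    duration = trajectory.duration
    trains = generate_ensemble_spikes(place_map, trajectory, lfp, beta, seed=seed)
    n_spikes = int(sum(tr.n for tr in trains))
    fc = build_complex(trains, w, kind=complex_kind, t_end=duration, horizon=horizon)
    barcode = persistent_homology(fc)
    tl = betti_timeline(barcode, default_grid(duration, grid_step))
    lr = learning_time(tl, target_betti)
    if troughs is None:
        troughs = detect_troughs(lfp.gamma_scaled, lfp.fs)
    spread = spike_spread(trains, troughs, lfp.theta_period, beta=beta)
    row = {
        "beta": beta,
        "w": w,
        "seed": seed,
        "complex_kind": complex_kind,
        "n_spikes": n_spikes,
        "N2_end": count_simplexes(fc, 2),
        "Nl1": count_loops(barcode, 1),
        "t_min": lr.t_min if lr.t_min is not None else np.nan,
        "diverged": lr.diverged,
        "delta_spread": spread.delta,
    }
    log.info(
        "condition beta=%.2f w=%.4f kind=%s seed=%s: %d spikes, N2=%d, Nl1=%d, t_min=%s",
        beta, w, complex_kind, seed, n_spikes, row["N2_end"], row["Nl1"], row["t_min"],
    )
    return row


def run_sweep(config: SweepConfig, arena: Arena | None = None) -> pd.DataFrame:
    """Full beta x window x seed grid; one row per cell of the grid.

    Per seed index, the LFP/trajectory/map are shared across the grid and
    the spiking stream varies with (seed index, beta) so that beta
    comparisons are matched.  Returns a tidy DataFrame.
    """
    rows = []
    for k in range(config.n_seeds):
        arena_k, lfp, traj, pmap = session_inputs(
            config.master_seed, k, config.duration, arena,
            config.map_params, config.mean_speed,
        )
        troughs = detect_troughs(lfp.gamma_scaled, lfp.fs)
        for beta in config.betas:
            spike_seed = derive_seed(config.master_seed, "spikes", k, int(round(beta * 1000)))
            trains = generate_ensemble_spikes(pmap, traj, lfp, beta, seed=spike_seed)
            spread = spike_spread(trains, troughs, lfp.theta_period, beta=beta)
            for w in config.windows:
                fc = build_complex(trains, w, kind=config.complex_kind,
                                   t_end=config.duration, horizon=config.horizon)
                barcode = persistent_homology(fc)
                tl = betti_timeline(barcode, default_grid(config.duration, config.grid_step))
                lr = learning_time(tl, config.target_betti)
                rows.append({
                    "beta": beta,
                    "w": w,
                    "seed": k,
                    "complex_kind": config.complex_kind,
                    "n_spikes": int(sum(tr.n for tr in trains)),
                    "N2_end": count_simplexes(fc, 2),
                    "Nl1": count_loops(barcode, 1),
                    "t_min": lr.t_min if lr.t_min is not None else np.nan,
                    "diverged": lr.diverged,
                    "delta_spread": spread.delta,
                })
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean over seeds per (beta, w): N2, Nl1, t_min (finite runs) and the
    fraction of converged runs."""
    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "N2_end": g["N2_end"].mean(),
            "Nl1": g["Nl1"].mean(),
            "t_min": g.loc[~g["diverged"], "t_min"].mean(),
            "converged_frac": 1.0 - g["diverged"].mean(),
            "delta_spread": g["delta_spread"].mean(),
        })
    return (
        table.groupby(["beta", "w"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )


def run_ensemble_map(
    s_grid: Sequence[float],
    N_grid: Sequence[int],
    f: float = 25.0,
    beta: float = 0.0,
    w: float = 2 * THETA_PERIOD,
    n_maps: int = 10,
    duration: float = 1500.0,
    complex_kind: str = "simplicial",
    master_seed: int = 0,
    arena: Arena | None = None,
) -> pd.DataFrame:
    """Mean learning time over an (s, N) ensemble-parameter grid.

    For each grid point, ``n_maps`` independent place-field maps are run on
    the same session (LFP + trajectory); the table reports the mean T_min of
    the converged maps and the success fraction.
    """
    arena = default_arena() if arena is None else arena
    lfp = synthesize_lfp(duration, theta_freq=THETA_HZ, seed=derive_seed(master_seed, "lfp", 0))
    traj = simulate_trajectory(arena, duration, seed=derive_seed(master_seed, "trajectory", 0))
    rows = []
    for s in s_grid:
        for N in N_grid:
            t_mins = []
            for m in range(n_maps):
                params = PlaceMapParams(s=s, f=f, N=int(N))
                pmap = generate_place_map(
                    params, arena,
                    seed=derive_seed(master_seed, "map", m, int(round(s * 1e4)), int(N)),
                )
                row = run_condition(
                    pmap, traj, lfp, beta, w, complex_kind,
                    seed=derive_seed(master_seed, "spikes", m, int(round(s * 1e4)), int(N)),
                )
                t_mins.append(row["t_min"])
            t_arr = np.asarray(t_mins, dtype=float)
            finite = np.isfinite(t_arr)
            rows.append({
                "s": s,
                "N": int(N),
                "beta": beta,
                "w": w,
                "mean_t_min": float(t_arr[finite].mean()) if finite.any() else np.nan,
                "success_frac": float(finite.mean()),
                "n_maps": n_maps,
            })
    return pd.DataFrame(rows)
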