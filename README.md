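# placetopo

A topological model of hippocampal spatial learning, built to study how
**gamma synchronization** changes the time it takes a place-cell ensemble to
form a map of its environment.

Hippocampal place cells fire in localized regions (place fields) that
jointly cover the environment.  Because overlapping fields mean co-firing
cells, the *temporal* pattern of place-cell coactivity carries the *spatial*
pattern of field overlaps — and, by the nerve (Alexandrov–Čech)
construction, the topology of the environment itself.  The package
simulates this code end to end:

1. a synthetic LFP with a theta wave (8 Hz) and a broadband gamma wave
   (30–80 Hz, about seven gamma cycles per theta period, with burst
   intermittency);
2. a non-preferential exploratory trajectory in a 1 m × 1 m arena with a
   central obstacle;
3. an ensemble of N place cells with lognormal field sizes and peak rates,
   spiking with rate
   `lambda_net = lambda_c(r) · Lambda_theta(phi) · Lambda_gamma(A)`:
   a spatial Gaussian, a theta-precession gate
   (`phi_pref = 2π(1 − l/L_c)`), and a Boltzmann gamma factor
   `exp(−β·A(t))` that pulls spikes into gamma troughs, with `1/β` the
   effective temperature of the cell assemblies;
4. coactivity complexes from windowed co-firing — the simplicial complex
   of a coincidence-detector readout and the clique complex of an
   integrator readout with a 10-minute working-memory horizon;
5. persistent homology (Z2, dimensions 0–1) of the growing complex, Betti
   timelines `b0(t), b1(t)`, and the learning time `T_min`: the earliest
   moment from which the complex stably shows the environment's signature
   `(b0, b1) = (1, 1)` — one connected map with exactly one hole, the
   obstacle.

The headline result this machinery reproduces: cooling the assemblies
(raising β from 0 to 2) concentrates coactivity at the deep gamma troughs,
which increases the number of detected coincidences at short readout
windows, suppresses spurious topological loops, and accelerates — or
rescues — learning when the readout integrates over less than a theta
period.

## Worked example

Ten simulated minutes of the headline ensemble (mean field extent 24 cm,
mean peak rate 20 Hz, 450 cells), readout window of half a theta period:

```python
import placetopo as pt
from placetopo.topology import (persistent_homology, betti_timeline,
                                learning_time, default_grid, count_loops)

arena = pt.default_arena()                       # 1 m x 1 m, central 25 cm obstacle
lfp = pt.synthesize_lfp(600.0, seed=1)           # 10 min of theta + gamma surrogate
traj = pt.simulate_trajectory(arena, 600.0, seed=2)
pmap = pt.generate_place_map(pt.PlaceMapParams(), arena, seed=3)

for beta in (0.0, 2.0):
    trains = pt.generate_ensemble_spikes(pmap, traj, lfp, beta, seed=4)
    events = pt.detect_coactivity(trains, w=0.0625, t_end=600.0)   # w = 0.5 T_theta
    fc = pt.build_simplicial_complex(events)
    barcode = persistent_homology(fc)
    tl = betti_timeline(barcode, default_grid(600.0))
    lr = learning_time(tl, target=(1, 1))
    print(f"beta={beta:.0f}: N2={fc.count(2)}  loops={count_loops(barcode)}  "
          f"(b0,b1) at end=({tl.b0[-1]},{tl.b1[-1]})  T_min={lr.t_min}")
```

prints

```
beta=0: N2=157359  loops=27  (b0,b1) at end=(1,1)  T_min=105.0
beta=2: N2=193772  loops=10  (b0,b1) at end=(1,1)  T_min=30.0
```

Read: both the hot (β = 0) and cold (β = 2) ensembles eventually learn the
arena — one component, one loop (the obstacle) — but cooling yields ~23%
more 2-simplexes, fewer than half the spurious loops along the way, and a
map in 30 s instead of 105 s of exploration.  `T_min` is reported on a
15 s sampling grid.

A command-line interface mirrors the stages
(`placetopo lfp | trajectory | placemap | spikes | complex | persistence |
run | sweep | ensemble-map`), reading and writing plain CSV/text artifacts;
`placetopo --config my.yaml sweep` runs the full β × w grid and writes
tidy result tables.  See `placetopo --help`.

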