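# Methods

`placetopo` implements a topological model of hippocampal map formation and
asks how the gamma rhythm changes the speed and reliability of spatial
learning.  The pipeline has five stages — surrogate LFP, exploratory
trajectory, place-cell ensemble, modulated spiking, coactivity topology —
each exposed as a module and each reproducible from a seed.

## The model

### Spatial code and readout

Hippocampal place cells fire inside restricted regions (place fields) that
jointly cover the environment.  By the nerve construction
(Alexandrov–Čech), the pattern of field overlaps determines the topology of
the covered space, and overlaps are expressed in spike timing: cells with
overlapping fields fire together.  A downstream readout neuron integrating
inputs over a window `w` therefore detects, window by window, the sets of
coactive cells.  Two readout idealizations are implemented:

* **coincidence detector** — every coactive set of p cells contributes the
  2-skeleton of a (p−1)-simplex, born at the end of the first window where
  the full set co-fired (the simplicial coactivity complex);
* **integrator** — pairwise coactivities accumulate into a graph, and
  every 3-clique whose three edges have all been observed within one
  working-memory span (default 10 min) becomes a triangle (the clique
  coactivity complex).  Re-observations count: the integrator keeps seeing
  an edge each time the pair co-fires, which is what lets cliques complete
  late without violating the memory bound.

The complex grows with exploration.  Its persistent homology (Z2, computed
over the birth-time filtration by union-find in dimension 0 and
boundary-matrix reduction with bitmask columns in dimension 1) yields Betti
timelines b0(t), b1(t).  The *learning time* `T_min` is the earliest
sampled time from which (b0, b1) stably equals the environment's signature
— (1, 1) for a connected arena with one obstacle — through the session's
end; if that never happens the session diverged.  Intervals are half-open
(`birth <= t < death`) and zero-persistence pairs are dropped: they are
unobservable on any timeline and would make the "total loops observed"
count depend on within-window insertion order.

### Spiking model

The rate of cell c is the product
`lambda_net = lambda_c(r) * Lambda_theta(phi) * Lambda_gamma(A)` inside the
cell's field (the disc of diameter L_c = 3 s_c; zero outside — the
Gaussian tail at 1.5 s_c is still a third of the peak, and untruncated,
unmodulated rim firing would swamp the in-field theta structure):

* `lambda_c(r) = f_c exp(-|r - r_c|^2 / 2 s_c^2)` — the spatial tuning;
* `Lambda_theta` — phase precession: the preferred phase advances as
  `phi_pref = 2 pi (1 - l/L_c)` with the path length `l` traveled into the
  field, and spiking is gated by a circular Gaussian around it.  The
  tuning width is the fraction of the field crossed per theta cycle,
  `eps = v T_theta / L_c`, mapped to a phase width `2 pi eps` (~0.65 rad
  at the defaults — the scale of measured CA1 phase locking).  The gate is
  divided by its uniform-phase average, so precession redistributes spikes
  within the cycle and `f` remains the realized in-field rate scale; an
  unnormalized narrow gate would silently cut all rates ~25-fold and no
  map would ever form;
* `Lambda_gamma = exp(-beta * A(t))` — the gamma wave, scaled to unit SD,
  acts as an inhibitory potential; spikes settle into its troughs like
  particles into wells, with `1/beta` the effective temperature.  The
  factor is applied unnormalized (the default): cooling both sharpens and
  boosts firing at the troughs, which is what makes assemblies grow with
  beta while leaving large-window statistics unchanged.  Mean-preserving
  per-cell ("cell") and per-session ("session") normalizations are
  available; under them cooling cannot increase distinct coincidences (a
  cell's participation is concave in its local rate), so every
  beta-contrast reverses sign.  The potential is saturated at ±3 SD
  (`gamma_clip_sd`): inhibition is bounded, and without the cap the
  heaviest trough of a session dominates the Boltzmann weights (dynamic
  range 10^7 at beta = 2) and place fields collapse onto single bursts.

Spike counts per 1 ms bin are Poisson; several spikes in one trough model
the within-cycle burst discharge.  Near a trough, where
`A(t) ≈ a_i + A_i omega_i^2 t^2 / 2`, the placement law is Gaussian with
`Delta_i = 1/sqrt(beta_gamma A_i omega_i^2)`; requiring the physiological
spread of about a sixth of the gamma period calibrates
`beta = 1/mean(A_i)` on the unit-SD scale, which lands at ~0.85 for the
surrogate — inside the physiological range 0.5–2 that the sweeps cover.

### Surrogate LFP

The recordings behind the original analysis are not available, so the LFP
is synthesized to their stated statistics: theta is an 8 Hz sinusoid
(T_theta = 125 ms) with ±10% cycle-to-cycle amplitude/frequency jitter and
a closed-form phase; gamma is white noise band-passed to 30–80 Hz so that
one theta period contains about seven gamma cycles (troughs are counted as
local minima below the mean; the cadence lands at ~7.4 per cycle).  The
gamma amplitude is further modulated by a slow lognormal burst envelope
(stationary AR(1) log-envelope, sigma = 0.25, correlation ~0.12 s).  This
intermittency is essential, not cosmetic: real gamma arrives in bursts of
roughly a theta cycle during which *all* troughs are deep.  Burst epochs
are shared by every cell, so Boltzmann cooling concentrates the whole
local ensemble into the same epochs — dynamical assemblies — without any
cell leaving its own phase gate; a stationary-envelope surrogate has no
such shared structure and cooling then decorrelates cells instead of
synchronizing them.  sigma = 0.25 gives mild excess kurtosis and 4–5 SD
extreme troughs, consistent with treating 2 SD ("deep") and 3 SD ("very
deep") troughs as meaningful classes.

### Trajectory and ensemble

Exploration is non-preferential: a constant-speed (0.20 m/s) correlated
random walk with ~1 s heading decorrelation, specular reflection at the
walls and the obstacle, integrated at 10 ms and resampled to the 1 ms
simulation grid.  The arena is 1 m × 1 m with a centered 25 cm square
obstacle (free space has b0 = 1, b1 = 1); 10 minutes of walk visit ≥95%
of the free 10 cm cells.  The ensemble is summarized by (s, f, N): widths
s_c and peak rates f_c are lognormal, moment-matched to means (s, f) and
SDs (0.25 s, 0.25 f), centers uniform over free space.  The headline map
uses mean field extent 3 s = 24 cm, f = 20 Hz, N = 450.  Fields truncated
by walls are not renormalized.

## Measured quantities

* **Assembly spread `Delta_beta`** — the session is tiled into theta
  periods; periods with ≥2 distinct active cells are coactivity episodes.
  Episode spikes are pooled by their offset from the nearest *deep*
  (≥2 SD) trough and `Delta_beta` is twice the 68th percentile of the
  absolute offsets — the Gaussian-equivalent 2-sigma full width, robust to
  the diffuse background.  (The source figures annotate the spread without
  defining its estimator; this choice reproduces the hot-side value
  exactly and the ordering always.)
* **Coactivity detection** — sliding windows of width `w`, step `w/2`;
  a window with ≥2 active cells emits one event (consecutive identical
  active sets collapse).  Window grids tile from t = 0; the event time is
  the window end.
* **N2, loop counts, T_min** — 2-simplex counts at session end, total
  dim-1 intervals of the barcode over the whole session, and the stable
  learning time defined above (Betti grid step 15 s, which resolves
  minute-scale learning without inflating cost).

## Reproducibility and numerics

Every stochastic stage draws from a named `SeedSequence` stream
(`[master, crc32(name), index]`), so sweep tables are byte-identical across
reruns and any single cell's train can be regenerated in isolation.
Persistence is validated against an independent dense GF(2) reduction on
random small filtrations; complex builders against exhaustive window
enumeration; clique births against a brute-force completion search.
Trough frequencies are solved from the exact local-cosine identity at a
lag of about a sixth of a period (a fixed-width quadratic fit at 1 kHz has
a several-percent curvature bias); trough times/values come from 3-point
parabolic refinement.  Degenerate inputs (zero duration, constant gamma,
empty trough lists, windows without spikes) return empty objects or raise
`ValueError` as documented per function.

## Problem sizes

The acceptance script runs the headline ensemble at full size (N = 450):
25-minute sessions, five matched seeds for the beta-contrast quantities,
and a 10-minute session for the spread ladder.  The pytest acceptance
layer runs one 25-minute matched-seed session plus a 10-minute ladder
session.  Unit and property tests use 60-second sessions with 120-cell
ensembles.

## What the surrogate does and does not show

Passing results demonstrate that the model's mechanisms behave as the
theory predicts *under a Gaussian-statistics surrogate with lognormal
burst intermittency*.  Real LFP differs in ways that matter quantitatively:
its gamma amplitude distribution (and hence the depth profile of troughs)
is unknown and likely more intermittent than any stationary model, its
theta-gamma phase coupling is ignored here, and absolute learning times
additionally depend on the unreported animal speed and obstacle size.
Intermediate couplings are the most sensitive point: at beta = 1 the
surrogate concentrates coactivity around deep troughs noticeably less
than the recorded-LFP figures suggest (our Delta_1 is ~2x the annotated
value), while the hot (beta = 0) and cold (beta = 2) regimes, and all
directional beta-contrasts, are reproduced.  Only scaled, within-model
comparisons should be read quantitatively.

## Known limitations

* Trough-locking cells only; rising-phase-locked cells and mixed ensembles
  are out of scope.
* No refractory dynamics beyond the per-bin Poisson discretization; burst
  structure is a byproduct of the Boltzmann gate, not a biophysical model.
* Homology is computed over the 2-skeleton (b0, b1 only), with permanent
  simplex births (no forgetting).
* The clique complex's working-memory horizon applies to pair
  re-observations; a horizon applied to first detections only would leave
  late-discovered cliques permanently open and the integrator complex
  would not converge.
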