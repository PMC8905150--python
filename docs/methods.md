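# Methods

## The agent model

`antsync` simulates a colony of *N* mobile excitable agents in a bounded
`grid_side × grid_side` square arena (default 32 × 32 length units; one
unit is roughly one ant body length, one time step is one second). Each
agent is in one of two states with a personal clock *T* reset to zero at
every state switch.

**Active** (bout length *A*, fixed per configuration): the agent takes one
unit step per second along a heading jittered uniformly within
±`walk_jitter` degrees (default 45°; 360° yields an uncorrelated random
walk). A step that would leave the arena has a uniform integer rotation in
[0°, 180°) added, re-proposed until it stays inside (bounded at 64 tries,
then the heading is reversed — in practice one or two rotations suffice).
Agents pass freely through one another. When *T* ≥ *A* the agent becomes
inactive and draws a fresh bout pair (*R*, *S*).

**Inactive**: the agent is motionless. It re-activates spontaneously when
*T* ≥ *S*, or through stimulation: whenever an active agent is within
`stim_radius` (default 1 unit, Euclidean distance on continuous
coordinates) and *T* ≥ *R*. Contacts arriving while *T* < *R* are ignored
(and logged once per proximity episode).

Bout parameter distributions (`DistributionSpec`): *S* is exponential with
mean ⟨S⟩ (continuous draws); *R* is fixed, integer-uniform on an interval,
integer-uniform on [⟨R⟩ − Ω, ⟨R⟩ + Ω] (Ω is the refractory-noise
amplitude), or exponential. Uniform draws are integers because the noise
mechanism is specified on integer seconds; exponential draws are left
continuous.

### Update schedule

The update is synchronous with a fixed sub-step order: (1) all clocks
advance one second; (2) spontaneous activations; (3) all active agents
move; (4) stimulation is evaluated and applied simultaneously (an agent
woken in this sub-step neither moves nor stimulates until the next step);
(5) deactivations and fresh (*R*, *S*) draws. Ordering within a step is a
design choice — the state-transition rules do not force one — and is fixed
so runs are exactly reproducible.

Two stimulation-evaluation modes exist. The default, `every_step`,
re-tests *T* ≥ *R* every second a pair stays within the contact radius, so
an agent that matures while a neighbour lingers wakes immediately.
`episode_onset` tests only when a pair first comes within the radius (an
episode ends when the pair separates or either agent switches state). The
default is `every_step`: under the analysis pipeline below it reproduces
the reference collective periods of both species presets noticeably better
(means 12.0 and 8.1 min versus 10.8 and 7.3 min for episode-onset), and it
is the natural behaviour of a per-tick proximity check. Both modes are
retained and tested.

### Initial conditions

Positions and headings are uniform; `n_initial_active` agents (default
*N*/2) start active with *T* = 0, the rest start inactive with fresh
(*R*, *S*) draws. The initial transient is negligible over the default
100 001-step (27.8 h) run.

### Implementation

The production path is a numba-compiled kernel (~0.2 s per 100 001-step,
50-agent colony); a readable pure-Python per-step reference implementation
with identical semantics serves as an independent oracle in the tests
(exact agreement is asserted wherever randomness cannot influence the
activity trace, e.g. the single-agent closed form; the two paths use
different RNG streams, so each is bit-reproducible for a fixed seed but
they are not bit-identical to each other). Campaigns derive replicate
seeds as `base_seed + condition_index * n_replicates + i`.

## Species presets

Calibrated to individual-level observations of two *Leptothorax* species:

| preset | R | S | A |
|---|---|---|---|
| `spW` | Uniform(530 s, 1415 s) | Exp(3824 s) | 218 s |
| `crassipilis` | Exp(1513 s) | Exp(2385 s) | 138 s |

Both use 50 ants, a 32 × 32 arena, 100 001 steps, a 25/25 initial split
and 45° jitter.

## Time-series pipeline

All records are smoothed with a Gaussian-weighted moving average
(15 points, σ = window/5 points, truncated-kernel renormalisation at the
edges) and min-max rescaled to [0, 1]. Peaks are local maxima with
topographic prominence ≥ 0.2 (scipy's definition, plateau centres for flat
tops); CV uses the sample (n − 1) standard deviation of inter-peak
intervals and requires at least two intervals. Long non-stationary records
are detrended by least-squares polynomial subtraction (degree 4) before
Lomb–Scargle analysis.

**Morse CWT.** The generalized Morse wavelet with γ = 3 and time-bandwidth
*P*² = 60 (β = 20), L1-normalised filters, 10 voices per octave. Scale
maps to period via the wavelet peak frequency ω_p = (β/γ)^{1/γ}.
Coefficients closer to a record edge than *s*·τ_e are discarded, where τ_e
is the e-folding time of the mother wavelet's envelope, computed
numerically once. The dominant period maximises the **time-averaged**
magnitude over retained coefficients (scales with < 5 % usable
coefficients are dropped); the default period range is 2·dt to a quarter
of the record, so at least ~4 cycles of every reported period fit the
record. The CWT is computed scale-by-scale via FFT, so 10⁵-sample records
need no large coefficient matrix.

**Lomb–Scargle.** `scipy.signal.lombscargle` with variance normalisation
on a 2000-point logarithmic period grid from 2·dt to half the record.

**Analysis cadence.** The simulator records at its native 1 s resolution.
Species-preset batches are analysed at that cadence (the 15-point filter
then spans 15 s), with the CWT restricted to periods above one minute;
this is the configuration that reproduces the reference simulated
collective periods (~12 and ~8 min). The coarser empirical-style cadence
(30 s, filter = 7.5 min) attenuates the sharp recruitment fronts and reads
the same runs 30–40 % longer, because in switching colonies it biases the
magnitude toward the long mode. Parameter sweeps are analysed at 30 s
cadence with Lomb–Scargle: the long simulated series are stationary, and
in the relevant 10 min – 1 h band the two cadences give identical LS
periods at a thirtieth of the cost.

**Birhythmicity.** Two detectors, both configurable:

* `birhythmicity_index` — generic: a secondary spectral peak ≥ 1.25× away
  in period carrying ≥ 0.5 of the dominant peak's power.
* `subharmonic_birhythmic` — used for per-replicate sweep flags. The
  model's second collective cycle arises by period doubling (part of the
  colony skips every other wave), so genuine two-cycle dynamics show peak
  pairs near a 2:1 period ratio (measured 22 vs 11.5 min at R = 1100 s),
  whereas refractory noise broadens a single rhythm into spectral
  neighbours within ~1.5×. The flag therefore requires the secondary peak
  to lie at 1.6–2.5× (either direction) with ≥ 0.5 relative power.

A sweep condition is *population-bimodal* when exact 1-D 2-means on the
log replicate dominant periods yields clusters whose means differ by more
than the pooled within-cluster standard deviation **and** by at least a
1.25× period ratio, with ≥ 2 replicates per cluster. The ratio guard
exists because below the birhythmic threshold replicate periods are
quantised onto a few adjacent grid bins, and a gap-versus-variance rule
alone would flag those degenerate splits.

`aggregate_spectra` rescales each spectrum to unit maximum and sums
pointwise (interpolating in log period when grids differ), so
periodicities shared across records reinforce.

## Synthetic fixtures

`antsync.fixtures` generates signals with stored ground truth: Poisson and
gamma renewal spike trains (CV → 1 and 1/√k), sinusoid mixtures with
optional Gaussian noise and polynomial trends, square waves, and
burst-train "colony-like" traces (Gaussian burst envelopes recurring at a
known period over a drifting baseline, 30 s cadence). They emulate the
morphology and descriptive scales of real colony and singleton recordings
— burst periods of tens of minutes, 9–35 h records, CVs of ~0.7–1 — but
none of their statistics are fit to data. A green analysis test therefore
establishes estimator correctness on signals of realistic shape and noise,
not agreement with any particular empirical recording.

## Statistical calibration notes

* The sample CV of 1000 exponential intervals has sampling s.d. ≈ 0.031;
  estimator calibration is asserted on the mean over independent trains.
* "No collective rhythm without coupling" cannot be tested against a fixed
  multiple of the spectrum median: the maximum over the hundreds of
  independent band frequencies of even white noise concentrates near 8–15×
  the median. The test instead calibrates the peak-to-median ratio against
  simulated uncoupled colonies (the null model itself) and requires the
  coupled colony to be a far outlier — it is, by roughly a factor of
  seven.
* With no coupling, mean activity matches the renewal closed form
  A/(A + ⟨S⟩) within a few percent over 10⁵ steps.

## Known limitations

* Agents are homogeneous; no spatial fidelity zones, dominance
  interactions, brood or queen effects, and no collision exclusion.
* The refractory mechanism is a hard threshold on *T*; real ants show a
  graded response probability.
* Periods reported by either estimator are quantised to the analysis grid
  (~7 % steps for the CWT at 10 voices/octave).
* The wavelet pipeline performs no red-noise significance testing and no
  cross-colony coherence analysis.
* At very large refractory noise (Ω ≥ ~500 s at ⟨R⟩ = 1100 s) the lower
  tail of the refractory distribution re-enables short-cycle entrainment,
  so birhythmicity is suppressed non-monotonically in Ω: strongly at
  Ω ≈ 200–400 s, only partially at Ω = 500 s.
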