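# Methods

## Model

The package models the interaction of free intracellular calcium
`x = [Ca²⁺]`, free indicator `y = [CI]` and bound (fluorescing) indicator
`z = [CI*]` as the mass-action network `Ca²⁺ + CI ⇌ CI*` with forward rate
`k_f` and reverse rate `k_r`. Assuming the indicator does not leave the cell,
`y + z = L` is conserved and `y` is eliminated. Firing at rate `s(t)` drives
calcium influx `α·s`, and calcium is cleared passively at rate `γ`:

    dx/dt = α·s − γ·x + k_r·z − k_f·x·(L − z)
    dz/dt = k_f·x·(L − z) − k_r·z

Assumptions worth keeping in mind: a single well-mixed compartment; a 1:1
binding stoichiometry with no cooperativity (real GCaMPs bind multiple Ca²⁺
ions cooperatively — the model is an effective description); deterministic
mass-action kinetics (no chemical noise); and fluorescence equated with `z`
(no separate photophysics, bleaching or baseline model).

Units: time in seconds, rates in Hz, concentrations in the arbitrary
normalized units in which fluorescence is read out. Under constant drive the
equilibrium is `x* = α·s/γ`, `z* = L·k_f·x*/(k_r + k_f·x*)`; the Jacobian at
any such equilibrium has trace `−(γ + k_f(L−z*) + k_r + k_f x*) < 0` and
determinant `γ·(k_r + k_f x*) > 0`, so every constant-drive equilibrium is
locally asymptotically stable for all `s ≥ 0` and all positive parameters.
`stability_report` verifies this numerically rather than symbolically.

### Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `k_f` | binding rate | 1/(conc·s) | 0.0514 (GCaMP6s) |
| `k_r` | unbinding rate | 1/s | 7.6 (GCaMP6s) |
| `L` | total indicator | conc | 30 |
| `α` | calcium influx per unit firing rate | conc/spike | 50 (inference), calibrated per dataset |
| `γ` | calcium clearance | 1/s | 1 |

`k_d = k_f/k_r` summarizes affinity but, as the frequency-response tests
show, does not determine the dynamic response: indicators with equal `k_d`
and tenfold different absolute rates attenuate fast drives very differently.

## Numerical integration

Open-loop simulation uses SciPy's adaptive explicit Runge–Kutta (RK45,
rtol 1e−8) for callable drives and a fixed-step classical RK4 (10 substeps
per 10 ms sample) for zero-order-hold drives, which handles the
piecewise-constant spike-drive discontinuities exactly at sample boundaries.
The system is non-stiff in the physiological regime (slowest/fastest rates
`γ ≈ 1/s` to `k_r + k_f·x`); an independent RK4 reference at dt/100 agrees
with the production integrator to better than 1e−5 relative error. The
frequency-response sweeps use LSODA because post-transient trajectories are
slowly varying relative to the binding rates.

## The controller

At measurement step `t` the horizon problem

    min_{0 ≤ s ≤ s_max} Σ_{k=0..n−1} (z_k − m_{t+k+1})² + r(s_k − s_{k−1})² + w_T (z_{n−1} − m_{t+n})²

is transcribed by direct single shooting: the dynamics are rolled out with
RK4 inside each 10 ms interval (substeps adapt to the local relaxation rate
`γ + k_r + k_f·x` so the explicit scheme stays in its stability region, and
states are clamped to the physical set `x ≥ 0`, `0 ≤ z ≤ L`), and the
resulting n-variable bound-constrained problem is solved with L-BFGS-B
(ftol-scale 1e−10, warm-started from the previous horizon shifted one step).
If a warm-started solve fails, or the zero-input candidate undercuts it, the
solve is restarted from `s ≡ 0` and the better result kept — this also
guarantees the reported optimal cost never exceeds the zero-input cost.
Defaults: `n = 6` (60 ms look-ahead), `r = 0.01`, `s_max = 1000` Hz
(a solver-robustness bound, effectively unconstrained), `w_T = 1`.

The terminal term is implemented as an extra weight on the horizon-end
tracking error — the standard realization of a terminal penalty that
approximates the infinite-horizon value function; the weight is configurable.

State update between solves: by default the bound-indicator state is
re-anchored to the current measurement before each solve (measurement
feedback — the receding-horizon policy is recomputed from updated
measurements), while free calcium, which is not measured, is propagated by
the model. Pure open-loop propagation is available
(`reset_state_to_measurement=False`) but measurably smears inferred spikes:
with open-loop state drift the quadratic smoothness penalty spreads each
spike's inferred mass across roughly three 40 ms bins, dropping the binned
correlation on noiseless synthetic data from ≈0.83 to ≈0.7.

Initial state (`init="auto"`): `z₀` is the first measurement clipped to at
most 99% occupancy, and `x₀` is placed on the binding nullcline
`x₀ = k_r z₀ / (k_f (L − z₀))` — i.e. binding is assumed equilibrated when
the recording starts.

The receding loop emits each first control causally and never revises it;
the final `n − 1` samples reuse the last solved horizon (there are no
further measurements to shift the window into), with the horizon-end sample
holding the last reused control.

## Fluorescence preprocessing

Raw traces are normalized per neuron (z-score by default; the sigmoid's
centering at −1 presumes roughly standardized input; min-max and identity
are available) and mapped through `σ(x) = 1/(1+e^−(x+1)) − h` with
`h = 0.15`. If the simulated indicator then sits above 95% of the filter
ceiling `1 − h` for 25 consecutive samples (250 ms — long enough to exclude
single-sample transients), the trace is re-filtered once with `h = 0.25` and
inference restarted; no further escalation ever occurs. Leading/trailing NaN
padding is stripped on load; interior NaNs are linearly interpolated with a
warning.

## Calibration

Published kinetics (`k_f`, `k_r`) and the clearance `γ` transfer across
datasets; the firing gain α (expression level, optical gain) does not, so it
is calibrated per dataset on 1–3 cells with simultaneous electrophysiology.
Because the dynamics depend on α and `s` only through the product `α·s`, any
scale-invariant score — Pearson correlation included — cannot identify α:
halving α exactly doubles the inferred rate and leaves the correlation
unchanged. The default objective therefore pins the scale directly: α is
chosen so the integrated inferred rate `Σ ŝ·dt` equals the ground-truth
spike count (score `−|log(mass/count)|`, unimodal at the true gain). The
search is a 16-point log-spaced grid over the bounds (default [5, 500])
followed by golden-section refinement of the bracket; it is deterministic
given its spec. Scale-invariant objectives (`pearson_binned`, `neg_vp`)
remain selectable for scoring and for parameters that shape the trajectory.
Multiple free parameters are handled by one coordinate-wise pass of 1-D
searches. Calibration requires ground-truth spikes; unsupervised calibration
is out of scope.

## Evaluation protocol

Inferred rates and ground-truth spikes are compared after downsampling the
native 10 ms grid by a factor of 4 (40 ms bins): rates are summed as
`Σ s·dt` mass per bin, spikes counted per bin, and scored with the sample
Pearson correlation (invariant to positive affine rescaling, so rate
normalization never changes it). The Victor–Purpura distance is computed on
the native grid by the standard dynamic program with unit insert/delete cost
and shift cost `q·|Δt|`, `q` calibrated so a one-timestep (10 ms) move costs
exactly 1. `rates_to_spikes` converts a rate to events by rounding each
40 ms bin's expected count (half-to-even) and emitting spikes at bin
centers. Group summaries report mean, median and sample standard deviation
per dataset plus pooled values; singleton groups are flagged degenerate.

## Frequency response

For `s(t) = A·sin(ωt) + c` the simulation starts at the steady state of the
mean drive, discards `max(10 periods, 60 s)` of transient (extended, up to
twice, if the amplitude over the last window still differs by >2% from the
preceding window), and reports half the peak-to-peak excursion of `x`, `z`
and `x + z` over the final 3 periods, divided by `A`. Half peak-to-peak is
used instead of the FFT fundamental because the saturating response is
asymmetric. Drives with `c < A` would go negative and are clipped at zero by
default (with a warning); unclipped behavior is selectable. The default
sweep grid is 40 log-spaced ω values (natural-log axis).

The default worked-example cell uses α = 200, γ = 1 with the drive
`10·sin(ωt) + 11` (firing between 1 and 21 Hz). The gain is chosen so that
the quasi-static calcium excursion `x* = α·s/γ` (200–4200) spans and exceeds
GCaMP6s's half-occupancy point `k_r/k_f ≈ 148` — the saturating regime in
which indicator redesign is interesting. There the quasi-static `z`-ratio
has the closed form `L·K·(α/γ)/((K + x_min)(K + x_max))` with `K = k_r/k_f`,
maximized at `K = √(x_min·x_max)`; this is both the small-ω oracle for the
tests and the reason a lower-affinity candidate (`k_f = 0.01`, `k_r = 10`,
`k_d = 0.001`) out-responds GCaMP6s at low frequencies while both roll off
at high ω.

## Synthetic data generator

The generator emulates the measurement chain: an inhomogeneous Poisson train
on the 10 ms grid (constant, piecewise-constant or clipped-sinusoidal rate
profile), converted to a zero-order-hold drive `s = counts/dt` (so the
integral of `s` over any window equals the spike count and each spike
injects α units of calcium), forward-simulated from the zero-input
equilibrium, plus seeded additive iid Gaussian noise on `z`. Defaults:
`dt = 10 ms`, α = 50, γ = 1, `noise_sigma = 0.1` (about 1–2% of a typical
spike transient's peak). What it does *not* emulate: photon shot noise,
baseline drift and bleaching, motion artifacts, cooperative indicator
binding, and the nonlinear fluorescence-to-concentration mapping of real
imaging. Passing the synthetic tests therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not performance
on real recordings.

## Test problem sizes and numerical choices

The identifiability check runs a 60 s noiseless recording with
piecewise-constant drive (2 → 8 → 2 Hz, switches at 20 s and 40 s) and
requires <10% mean absolute relative error outside a 1 s settling window
after each switch — 1 s being the calcium clearance timescale `1/γ`.
Calibration recovery uses a single 15 s, 2 Hz cell at noise σ = 0.05.
The frequency-response claims use a 6-point log grid over ω ∈ [e⁻², e²].
The full-loop correlation bound (binned Pearson ≥ 0.8, noiseless, ≤2 Hz) is
asserted on a 20 s, 2 Hz recording (32 events); with only ~10 events the
binned-correlation estimator itself fluctuates by ±0.05 and a 10 s, 1 Hz
fixture scores ≈0.79, so short sparse fixtures assert mass/timing recovery
instead.

## Known limitations

- Fluorescence is equated with bound indicator; a nonlinear
  fluorescence→calcium stage (as in MLspike-style models) would improve
  robustness on real data and is deliberately out of scope.
- The quadratic smoothness penalty favors smooth rate estimates; sparse
  (l0/l1) penalties would sharpen isolated-spike recovery but change the
  optimization class.
- Calibration relies on simultaneous ground-truth spikes.
- The noise model used for testing is additive Gaussian; no particle/Kalman
  filtering of measurement noise is attempted.
- Spikefinder benchmark scores against STM/Oasis require the external
  dataset and are not reproduced here.
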