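# spikempc

Firing-rate inference from calcium imaging by model predictive control.

Two-photon calcium imaging reports neuronal activity only indirectly: a
fluorescent indicator (e.g. GCaMP6s) binds free calcium, and the slow binding,
unbinding and clearance kinetics smear the fast spiking signal that
experimenters actually care about. `spikempc` treats deconvolution as a
control problem. A mass-action model couples free calcium `x = [Ca²⁺]` and
bound indicator `z = [CI*]` (total indicator `L` conserved, free indicator
`y = L − z`):

```
dx/dt = α·s − γ·x + k_r·z − k_f·x·(L − z)
dz/dt = k_f·x·(L − z) − k_r·z
```

The unknown firing rate `s(t) ≥ 0` (Hz) is the control input. At every 10 ms
measurement step a receding-horizon controller solves

```
min_{s ≥ 0}  Σ_{k=0..n−1} (z_sim,k − z_meas,k)² + r·(s_k − s_{k−1})²  +  w_T·(terminal error)²
```

over an `n = 6` step (60 ms) horizon with smoothness weight `r = 0.01`,
applies the first control, and shifts the window. Controls are emitted
causally and never revised — the method runs with a fixed 60 ms lag and is
therefore suitable for real-time, closed-loop experiments (track a *desired*
indicator trajectory instead of a measured one and the same loop plans the
stimulation). The package is aimed at experimenters who want interpretable,
real-time-capable spike inference, and at indicator designers who want to ask
what kinetics (`k_f`, `k_r`, affinity `k_d = k_f/k_r`) an indicator needs to
follow a given band of firing-rate fluctuations.

What's inside:

- `spikempc.model` — the binding ODE: simulation (adaptive and fixed-step),
  closed-form steady states, stability analysis (the constant-drive
  equilibrium is provably stable for every `s ≥ 0`).
- `spikempc.preprocess` — shifted-sigmoid fluorescence filter
  `σ(x) = 1/(1+e^−(x+1)) − h` with `h = 0.15` and a single `h = 0.25`
  fallback pass when the simulated indicator saturates.
- `spikempc.mpc` — the receding-horizon engine (`infer_rates`,
  `track_reference`, `infer_from_raw`).
- `spikempc.calibration` — fits the firing gain α on 1–3 cells with
  ground-truth spikes; `k_f`, `k_r`, `γ` transfer across datasets.
- `spikempc.metrics` — the benchmarking protocol: 40 ms binning, Pearson
  correlation, Victor–Purpura spike distance (unit move cost per 10 ms step).
- `spikempc.freq` — frequency-response analysis of indicators under
  sinusoidal drive `s(t) = A·sin(ωt) + c`.
- `spikempc.synthetic` — seeded Poisson → ODE → noise generator producing
  drop-in replacements for real recordings.
- `spikempc.io` / CLI — spikefinder-style CSV reading/writing (columns =
  neurons, rows = 10 ms samples, NaN padding) and the `spikempc` command with
  `simulate`, `infer`, `calibrate`, `evaluate`, `freqresponse` subcommands.

## Worked example

Generate a 20 s synthetic recording (2 Hz Poisson spikes through GCaMP6s
kinetics, gain α = 50, clearance γ = 1/s, additive noise σ = 0.05), infer the
rate, and score it:

```python
import numpy as np
from spikempc import (
    GCAMP6S, CellModelParams, MPCConfig, SyntheticSpec,
    generate_spike_train, synth_recording, infer_rates,
    bin_downsample, pearson,
)

cell = CellModelParams(indicator=GCAMP6S, alpha=50.0, gamma=1.0)
spec = SyntheticSpec(duration=20.0, seed=3, mean_rate=2.0, noise_sigma=0.05)
train = generate_spike_train(spec)
clean, noisy = synth_recording(cell, train, spec)

result = infer_rates(noisy, cell, MPCConfig())  # n=6, r=0.01
mass = result.s_hat.values.sum() * 0.01
pred = bin_downsample(result.s_hat, 4)
true = bin_downsample(train, 4, native_dt=0.01, n_samples=len(noisy))
m = min(len(pred), len(true))
print(f"true spikes: {len(train)}")
print(f"inferred rate mass: {mass:.1f} expected spikes")
print(f"binned Pearson r: {pearson(pred[:m], true[:m]):.3f}")
```

prints

```
true spikes: 32
inferred rate mass: 33.4 expected spikes
binned Pearson r: 0.832
```

i.e. the integrated inferred rate recovers the number of spikes to within
~4%, and the 40 ms-binned inferred rate correlates at 0.83 with the true
spike counts. The same pipeline from the shell:

```sh
spikempc simulate --duration 20 --rate 2 --seed 3 --out sim/
spikempc infer --calcium sim/calcium.csv --params sim/params.txt --out run/
spikempc evaluate --pred run/rates.csv --truth sim/spikes.csv --out metrics.csv
```

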