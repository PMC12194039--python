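"""Ground-truth synthetic recordings for testing and calibration.

The generator emulates the measurement chain end to end: an (inhomogeneous)
Poisson spike train is drawn on the 10 ms acquisition grid, converted to a
piecewise-constant firing-rate drive, pushed through the binding model to
produce the clean bound-indicator trajectory z(t), and corrupted with
additive iid Gaussian noise to stand in for imaging noise.  Every stochastic
draw is seeded, so fixtures are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import SpikeTrain
from .model import CellModelParams, ModelState, TimeSeries, simulate

__all__ = [
    "SyntheticSpec",
    "rate_profile_fn",
    "generate_spike_train",
    "spikes_to_drive",
    "synth_recording",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of one synthetic recording.

    rate_profile: 'constant' (mean_rate Hz), 'piecewise' (levels switching
    at switch_times), or 'sinusoidal' (mean_rate + sine_amp*sin(sine_omega*t),
    clipped at 0).  noise_sigma is the additive Gaussian noise scale on z in
    indicator-concentration units.
    """

    duration: float
    seed: int
    dt: float = 0.010
    rate_profile: str = "constant"
    mean_rate: float = 1.0
    levels: tuple[float, ...] = (1.0, 5.0)
    switch_times: tuple[float, ...] = (0.5,)
    sine_amp: float = 0.5
    sine_omega: float = 1.0
    noise_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.rate_profile not in ("constant", "piecewise", "sinusoidal"):
            raise ValueError(f"unknown rate_profile {self.rate_profile!r}")
        if self.rate_profile == "piecewise" and len(self.levels) != len(self.switch_times) + 1:
            raise ValueError("piecewise profile needs len(levels) == len(switch_times)+1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.dt))


def rate_profile_fn(spec: SyntheticSpec):
    """The deterministic underlying rate lambda(t) of the spike process."""
    if spec.rate_profile == "constant":
        return lambda t: spec.mean_rate + 0.0 * np.asarray(t, dtype=float)
    if spec.rate_profile == "piecewise":
        edges = np.asarray(spec.switch_times)
        levels = np.asarray(spec.levels)

        def piecewise(t):
            return levels[np.searchsorted(edges, np.asarray(t, dtype=float), side="right")]

        return piecewise

    def sinusoid(t):
        return np.maximum(
            spec.mean_rate + spec.sine_amp * np.sin(spec.sine_omega * np.asarray(t, dtype=float)),
            0.0,
        )

    return sinusoid


def generate_spike_train(spec: SyntheticSpec) -> SpikeTrain:
    """Inhomogeneous Poisson draw on the dt grid (spikes at bin centers)."""
    rng = np.random.default_rng(spec.seed)
    t = (np.arange(spec.n_samples) + 0.5) * spec.dt
    lam = np.asarray(rate_profile_fn(spec)(t), dtype=float) * spec.dt
    counts = rng.poisson(lam)
    return SpikeTrain.from_counts(counts, spec.dt)


def spikes_to_drive(train: SpikeTrain, dt: float, n_samples: int) -> TimeSeries:
    """Per-step firing rate (count/dt, zero-order hold) from a spike train.

    The integral of s over any window equals the spike count there, so the
    drive injects alpha units of calcium per spike through the model's
    alpha*s term.
    """
    counts = train.counts(dt, n_samples)
    return TimeSeries(values=counts / dt, dt=dt)


def synth_recording(
    params: CellModelParams,
    train: SpikeTrain,
    spec: SyntheticSpec,
) -> tuple[TimeSeries, TimeSeries]:
    """(clean, noisy) bound-indicator traces for a given spike train.

    clean is the z-component of the forward simulation from the zero-input
    equilibrium (0, 0); noisy adds seeded iid Gaussian(0, noise_sigma^2).
    """
    drive = spikes_to_drive(train, spec.dt, spec.n_samples)
    traj = simulate(params, drive, ModelState(0.0, 0.0))
    clean = traj.z_series()
    if spec.noise_sigma == 0:
        noisy = TimeSeries(values=clean.values.copy(), dt=clean.dt, t0=clean.t0)
    else:
        rng = np.random.default_rng([spec.seed, 1])  # independent of the spike draw
        noisy = TimeSeries(
            values=clean.values + rng.normal(0.0, spec.noise_sigma, len(clean)),
            dt=clean.dt,
            t0=clean.t0,
        )
    return clean, noisy
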