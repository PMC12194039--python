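"""Frequency response of the binding model to sinusoidal firing-rate drive.

The model is nonlinear, so the response is probed empirically: drive the
system with s(t) = A*sin(w*t) + c, discard transients, and report the ratio
of the settled oscillation amplitude of each state variable (free calcium x,
bound indicator z, and total calcium x + z) to the drive amplitude A.
Sweeping w maps out which firing-rate frequencies an indicator can follow —
ratios fall off at high w where binding and clearance kinetics cannot keep
up — and lets candidate indicator kinetics (k_f, k_r) be compared against an
existing indicator before any protein engineering is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import (
    CellModelParams,
    IndicatorParams,
    simulate,
    steady_state,
)

__all__ = [
    "DriveSpec",
    "SettlePolicy",
    "SettleError",
    "FreqResponseResult",
    "drive_signal",
    "amplitude_ratio",
    "frequency_sweep",
    "compare_indicators",
    "quasi_static_ratio_z",
]


@dataclass(frozen=True)
class DriveSpec:
    """Sinusoidal drive s(t) = A*sin(omega*t) + c (all in Hz except omega).

    omega is an angular frequency (rad/s); the drive oscillates at
    omega/(2*pi) Hz over the range [c - A, c + A].  If c < A the drive would
    go negative; by default it is clipped at zero with a warning (rates are
    nonnegative), which makes the response mildly non-sinusoidal.
    """

    A: float
    omega: float
    c: float
    clip_negative: bool = True

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    @property
    def frequency_hz(self) -> float:
        return self.omega / (2.0 * np.pi)


def drive_signal(spec: DriveSpec, t: "float | np.ndarray") -> "float | np.ndarray":
    """Evaluate the drive at time(s) t."""
    s = spec.A * np.sin(spec.omega * np.asarray(t, dtype=float)) + spec.c
    if spec.clip_negative:
        s = np.maximum(s, 0.0)
    return float(s) if np.isscalar(t) else s


@dataclass(frozen=True)
class SettlePolicy:
    """How long to wait out transients and how long to measure.

    Transients are discarded for max(min_periods drive periods, min_time
    seconds); amplitudes are measured as half peak-to-peak over the last
    ``measure_periods`` full periods.  Settledness is declared when the
    amplitude over the measurement window agrees with the amplitude over the
    preceding window of equal length to within ``tol`` (relative); otherwise
    the simulation is extended up to ``max_extensions`` times.
    """

    min_periods: int = 10
    min_time: float = 60.0
    measure_periods: int = 3
    tol: float = 0.02
    max_extensions: int = 2


class SettleError(RuntimeError):
    """Oscillation did not settle; ``partial`` carries the last estimate."""

    def __init__(self, message: str, partial: dict):
        super().__init__(message)
        self.partial = partial


def _half_ptp(v: np.ndarray) -> float:
    return 0.5 * float(v.max() - v.min())


def amplitude_ratio(
    params: CellModelParams,
    spec: DriveSpec,
    settle: SettlePolicy | None = None,
    rtol: float = 1e-6,
    samples_per_period: int = 400,
) -> dict:
    """Settled amplitude ratios amp(state)/A for x, z and x+z at one omega.

    The simulation starts at the steady state of the mean drive c to shorten
    transients and integrates with a stiffness-switching adaptive solver.
    """
    settle = settle or SettlePolicy()
    if spec.A <= 0:
        raise ValueError("amplitude ratios need A > 0")
    if spec.clip_negative and spec.c < spec.A:
        warnings.warn("drive dips below zero and is clipped at 0")
    period = spec.period
    discard = max(settle.min_periods * period, settle.min_time)
    discard = np.ceil(discard / period) * period  # whole periods
    meas = settle.measure_periods * period
    dt = period / samples_per_period

    def fn(t: float) -> float:
        return drive_signal(spec, t)

    init = steady_state(params, max(spec.c, 0.0))
    for attempt in range(settle.max_extensions + 1):
        duration = discard + 2 * meas
        traj = simulate(
            params, fn, init, duration=duration, dt=dt, rtol=rtol,
            atol=1e-9, method="LSODA",
        )
        i_meas = traj.t >= discard + meas
        i_prev = (traj.t >= discard) & (traj.t < discard + meas)
        out = {}
        settled = True
        for name, v in (("x", traj.x), ("z", traj.z), ("total", traj.x + traj.z)):
            amp = _half_ptp(v[i_meas])
            amp_prev = _half_ptp(v[i_prev])
            ref = max(amp, amp_prev, 1e-12)
            settled &= abs(amp - amp_prev) <= settle.tol * ref
            out[f"ratio_{name}"] = amp / spec.A
        out["omega"] = spec.omega
        out["settled"] = settled
        out["discarded_s"] = float(discard + meas)
        if settled:
            return out
        discard *= 2  # transient longer than expected; wait it out
    raise SettleError(
        f"oscillation not settled at omega={spec.omega} after "
        f"{settle.max_extensions} extensions",
        partial=out,
    )


@dataclass
class FreqResponseResult:
    """Tabular amplitude-ratio sweep (one row per omega)."""

    table: pd.DataFrame
    params: CellModelParams

    @property
    def omega_grid(self) -> np.ndarray:
        return self.table["omega"].to_numpy()


def frequency_sweep(
    params: CellModelParams,
    spec_template: DriveSpec,
    omega_grid: np.ndarray,
    settle: SettlePolicy | None = None,
    rtol: float = 1e-6,
) -> FreqResponseResult:
    """Amplitude ratios across a sorted grid of drive frequencies.

    Settle failures at individual grid points are recorded (partial result,
    ``settled=False``) and the sweep continues.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid <= 0) or np.any(np.diff(omega_grid) < 0):
        raise ValueError("omega_grid must be positive and sorted")
    rows = []
    for w in omega_grid:
        spec = replace(spec_template, omega=float(w))
        try:
            rows.append(amplitude_ratio(params, spec, settle, rtol=rtol))
        except SettleError as err:
            rows.append(err.partial)
    return FreqResponseResult(table=pd.DataFrame(rows), params=params)


def quasi_static_ratio_z(params: CellModelParams, spec: DriveSpec) -> float:
    """Closed-form omega -> 0 limit of the z amplitude ratio.

    At vanishing drive frequency the state tracks the steady-state map, so
    the ratio is |z*(s_max) - z*(s_min)| / (2A) with s clipped at 0 when
    applicable.
    """
    s_lo = max(spec.c - spec.A, 0.0) if spec.clip_negative else spec.c - spec.A
    s_hi = spec.c + spec.A
    z_lo = steady_state(params, s_lo).z
    z_hi = steady_state(params, s_hi).z
    return abs(z_hi - z_lo) / (2.0 * spec.A)


def compare_indicators(
    base: IndicatorParams,
    candidate: IndicatorParams,
    alpha: float,
    gamma: float,
    spec_template: DriveSpec,
    omega_grid: np.ndarray,
    settle: SettlePolicy | None = None,
    rtol: float = 1e-6,
) -> dict:
    """Paired frequency sweeps for two indicators in the same cell model.

    Returns both sweeps, the binding affinity k_d = k_f/k_r of each, and a
    per-omega table of ratio differences (candidate - base).
    """
    sweeps = {}
    for name, ind in (("base", base), ("candidate", candidate)):
        cell = CellModelParams(indicator=ind, alpha=alpha, gamma=gamma)
        sweeps[name] = frequency_sweep(cell, spec_template, omega_grid, settle, rtol)
    diff = sweeps["candidate"].table[["omega", "ratio_x", "ratio_z", "ratio_total"]].copy()
    for col in ("ratio_x", "ratio_z", "ratio_total"):
        diff[col] = sweeps["candidate"].table[col] - sweeps["base"].table[col]
    return {
        "base": sweeps["base"],
        "candidate": sweeps["candidate"],
        "k_d_base": base.k_d,
        "k_d_candidate": candidate.k_d,
        "diff": diff,
    }
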