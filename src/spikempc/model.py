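"""Deterministic mass-action model of calcium/indicator binding.

The model couples free intracellular calcium ``x = [Ca2+]`` to a fluorescent
calcium indicator.  Calcium binds the free indicator CI at rate ``k_f`` and
unbinds from the fluorescing complex CI* at rate ``k_r``; the total indicator
concentration ``L`` is conserved, so the free-indicator concentration is
implicit (``y = L - z``).  Neuronal firing at rate ``s(t)`` (Hz) drives a
calcium influx ``alpha * s``, and calcium is cleared at rate ``gamma``:

    dx/dt = alpha*s - gamma*x + k_r*z - k_f*x*(L - z)
    dz/dt = k_f*x*(L - z) - k_r*z

Units: time in seconds, rates in Hz, concentrations in the normalized units
in which fluorescence is read out (fluorescence is equated with CI*).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "IndicatorParams",
    "CellModelParams",
    "ModelState",
    "TimeSeries",
    "Trajectory",
    "StabilityReport",
    "ModelDomainError",
    "IntegrationError",
    "GCAMP6S",
    "HYPOTHETICAL_INDICATOR",
    "derivatives",
    "steady_state",
    "jacobian",
    "stability_report",
    "simulate",
]


class ModelDomainError(ValueError):
    """An input lies outside the model's admissible domain."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; ``last_time`` holds the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class IndicatorParams:
    """Binding kinetics of one calcium indicator.

    Parameters
    ----------
    k_f : forward (binding) rate, 1/(concentration * s).
    k_r : reverse (unbinding) rate, 1/s.
    L : total indicator concentration (bound + free), conserved.
    """

    k_f: float
    k_r: float
    L: float

    def __post_init__(self) -> None:
        if not (self.k_f > 0 and self.k_r > 0 and self.L > 0):
            raise ModelDomainError(
                f"indicator parameters must be positive: k_f={self.k_f}, "
                f"k_r={self.k_r}, L={self.L}"
            )

    @property
    def k_d(self) -> float:
        """Binding affinity k_f / k_r."""
        return self.k_f / self.k_r


#: GCaMP6s kinetics used throughout the frequency-response analyses.
GCAMP6S = IndicatorParams(k_f=0.0514, k_r=7.6, L=30.0)

#: A slower, weaker-affinity design candidate (same L as GCaMP6s).
HYPOTHETICAL_INDICATOR = IndicatorParams(k_f=0.01, k_r=10.0, L=30.0)


@dataclass(frozen=True)
class CellModelParams:
    """Full parameter set: indicator kinetics plus firing gain and clearance.

    ``alpha`` converts firing rate (Hz) into calcium influx (concentration/s
    per Hz); ``gamma`` (1/s) is the passive calcium extrusion rate.
    """

    indicator: IndicatorParams
    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.gamma > 0):
            raise ModelDomainError(
                f"alpha and gamma must be positive: alpha={self.alpha}, "
                f"gamma={self.gamma}"
            )

    # convenience pass-throughs
    @property
    def k_f(self) -> float:
        return self.indicator.k_f

    @property
    def k_r(self) -> float:
        return self.indicator.k_r

    @property
    def L(self) -> float:
        return self.indicator.L

    def with_values(self, **kwargs: float) -> "CellModelParams":
        """Return a copy with any of alpha, gamma, k_f, k_r, L replaced."""
        ind_kw = {k: kwargs.pop(k) for k in ("k_f", "k_r", "L") if k in kwargs}
        out = self
        if ind_kw:
            out = replace(out, indicator=replace(out.indicator, **ind_kw))
        if kwargs:
            out = replace(out, **kwargs)
        return out


@dataclass(frozen=True)
class ModelState:
    """Free calcium ``x`` and bound indicator ``z`` (free indicator is L-z)."""

    x: float
    z: float

    def validate(self, L: float, tol: float = 0.0) -> None:
        if self.x < -tol or self.z < -tol or self.z > L + tol:
            raise ModelDomainError(
                f"state (x={self.x}, z={self.z}) outside invariant set "
                f"[0,inf) x [0, L={L}]"
            )


@dataclass
class TimeSeries:
    """Uniformly sampled real-valued signal."""

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    def value_at(self, t: float) -> float:
        """Zero-order-hold lookup (last sample held beyond the end)."""
        i = int(math.floor((t - self.t0) / self.dt + 1e-12))
        i = min(max(i, 0), len(self.values) - 1)
        return float(self.values[i])


@dataclass
class Trajectory:
    """Simulated model trajectory sampled on a uniform grid."""

    t: np.ndarray
    x: np.ndarray
    z: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def z_series(self) -> TimeSeries:
        return TimeSeries(values=self.z.copy(), dt=self.dt, t0=float(self.t[0]))

    def final_state(self) -> ModelState:
        return ModelState(x=float(self.x[-1]), z=float(self.z[-1]))


def derivatives(
    state: ModelState, s: float, params: CellModelParams
) -> tuple[float, float]:
    """Right-hand side (dx/dt, dz/dt) of the governing ODEs.

    With ``alpha*s`` and ``gamma*x`` removed this reduces to the closed
    binding system, whose flux is ``k_f*x*(L-z) - k_r*z``.
    """
    if s < 0:
        raise ModelDomainError(f"firing rate must be nonnegative, got s={s}")
    state.validate(params.L)
    bind = params.k_f * state.x * (params.L - state.z)
    unbind = params.k_r * state.z
    dx = params.alpha * s - params.gamma * state.x + unbind - bind
    dz = bind - unbind
    return dx, dz


def steady_state(params: CellModelParams, s_const: float) -> ModelState:
    """Closed-form equilibrium under constant drive.

    x* = alpha*s/gamma; z* = L*k_f*x*/(k_r + k_f*x*).  z* < L strictly for
    any finite x*, i.e. the indicator only saturates in the s -> inf limit.
    """
    if s_const < 0:
        raise ModelDomainError(f"s_const must be nonnegative, got {s_const}")
    x_star = params.alpha * s_const / params.gamma
    z_star = params.L * params.k_f * x_star / (params.k_r + params.k_f * x_star)
    return ModelState(x=x_star, z=z_star)


def jacobian(state: ModelState, params: CellModelParams) -> np.ndarray:
    """Jacobian of the vector field with respect to (x, z)."""
    kf, kr, L = params.k_f, params.k_r, params.L
    free = L - state.z
    return np.array(
        [
            [-params.gamma - kf * free, kr + kf * state.x],
            [kf * free, -kr - kf * state.x],
        ]
    )


@dataclass(frozen=True)
class StabilityReport:
    eigenvalues: tuple[complex, complex]
    stable: bool
    steady: ModelState
    s_const: float


def stability_report(params: CellModelParams, s_const: float) -> StabilityReport:
    """Eigenvalues of the Jacobian at the constant-drive equilibrium.

    For any positive parameters and s >= 0 the Jacobian has trace
    -(gamma + k_f(L-z*) + k_r + k_f x*) < 0 and determinant
    gamma*(k_r + k_f x*) > 0, so both eigenvalues have negative real part
    and every such equilibrium is locally asymptotically stable.
    """
    ss = steady_state(params, s_const)
    eig = np.linalg.eigvals(jacobian(ss, params))
    stable = bool(np.all(eig.real < 0))
    return StabilityReport(
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stable=stable,
        steady=ss,
        s_const=s_const,
    )


RateInput = Union[Callable[[float], float], TimeSeries]


def _rate_callable(rate: RateInput) -> Callable[[float], float]:
    if isinstance(rate, TimeSeries):
        return rate.value_at
    return rate


def simulate(
    params: CellModelParams,
    rate: RateInput,
    init: ModelState,
    duration: float | None = None,
    dt: float = 0.010,
    t0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    substeps: int = 10,
) -> Trajectory:
    """Integrate the model under a firing-rate input.

    Two backends, chosen by the type of ``rate``:

    * ``rate`` a :class:`TimeSeries` — interpreted as a zero-order-hold input
      on its own grid (the measurement grid); integrated with a fixed-step
      classical RK4 using ``substeps`` substeps per sample, which handles the
      piecewise-constant (discontinuous) drive exactly at sample boundaries.
      Output sample k is the state at time ``t0 + k*dt`` (before applying
      the k-th input), so the trajectory is aligned with the input grid.
    * ``rate`` a callable ``t -> s`` — integrated with an adaptive SciPy
      solver (``method``, default explicit Runge-Kutta at rtol 1e-8) and
      evaluated on the uniform grid; requires ``duration``.
    """
    init.validate(params.L, tol=1e-12)
    alpha, gamma = params.alpha, params.gamma
    kf, kr, L = params.k_f, params.k_r, params.L

    if isinstance(rate, TimeSeries):
        n = len(rate)
        dt = rate.dt
        t0 = rate.t0
        svals = rate.values
        if np.any(svals < 0):
            raise ModelDomainError("rate series must be nonnegative")
        x = np.empty(n)
        z = np.empty(n)
        xc, zc = init.x, init.z
        h = dt / substeps
        for k in range(n):
            x[k], z[k] = xc, zc
            s = svals[k]
            drive = alpha * s
            for _ in range(substeps):
                b1 = kf * xc * (L - zc) - kr * zc
                k1x = drive - gamma * xc - b1
                k1z = b1
                x2, z2 = xc + 0.5 * h * k1x, zc + 0.5 * h * k1z
                b2 = kf * x2 * (L - z2) - kr * z2
                k2x = drive - gamma * x2 - b2
                k2z = b2
                x3, z3 = xc + 0.5 * h * k2x, zc + 0.5 * h * k2z
                b3 = kf * x3 * (L - z3) - kr * z3
                k3x = drive - gamma * x3 - b3
                k3z = b3
                x4, z4 = xc + h * k3x, zc + h * k3z
                b4 = kf * x4 * (L - z4) - kr * z4
                k4x = drive - gamma * x4 - b4
                k4z = b4
                xc += h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
                zc += h / 6.0 * (k1z + 2 * k2z + 2 * k3z + k4z)
        t = t0 + dt * np.arange(n)
        return Trajectory(t=t, x=x, z=z)

    if duration is None:
        raise ValueError("duration is required for a callable rate input")
    rate_fn = _rate_callable(rate)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        s = rate_fn(t)
        b = kf * y[0] * (L - y[1]) - kr * y[1]
        return [alpha * s - gamma * y[0] - b, b]

    t_eval = t0 + dt * np.arange(int(np.floor(duration / dt + 1e-9)) + 1)
    t_eval = np.minimum(t_eval, t0 + duration)  # guard float round-up at the end
    sol = solve_ivp(
        rhs,
        (t0, t0 + duration),
        [init.x, init.z],
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        last = float(sol.t[-1]) if len(sol.t) else t0
        raise IntegrationError(f"integration failed: {sol.message}", last_time=last)
    return Trajectory(t=sol.t, x=sol.y[0], z=sol.y[1])
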