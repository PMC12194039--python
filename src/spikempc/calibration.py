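"""Auto-calibration of model parameters from paired recordings.

The binding kinetics (k_f, k_r) of a published indicator and the clearance
rate gamma transfer across datasets; what varies most is the firing gain
alpha (indicator expression level, imaging gain).  Calibration therefore
searches alpha (by default) on 1-3 cells with simultaneous fluorescence and
electrophysiological ground truth.

Because the dynamics depend on alpha and s only through the product
alpha*s, any scale-invariant score (Pearson correlation included) is blind
to alpha: halving alpha simply doubles every inferred rate and leaves the
correlation untouched.  The default objective therefore pins the scale
directly: alpha is chosen so that the total inferred rate mass
sum(s_hat * dt) matches the ground-truth spike count (score
-|log(mass / count)|, unimodal at the true gain), i.e. so the inferred rate
is calibrated in real spikes-per-second.  Scale-invariant alternatives
("pearson_binned", "neg_vp") remain selectable for scoring or for
calibrating parameters that do shape the trajectory (gamma, k_f, k_r).
The search is a coarse log-spaced grid followed by golden-section
refinement; it is deterministic given the spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    MetricConfig,
    MetricError,
    SpikeTrain,
    bin_downsample,
    pearson,
    rates_to_spikes,
    victor_purpura,
)
from .model import CellModelParams, TimeSeries
from .mpc import MPCConfig, infer_rates

__all__ = ["CalibrationSpec", "CalibrationError", "calibrate", "objective"]

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


class CalibrationError(RuntimeError):
    """Objective was non-finite on every candidate."""


@dataclass(frozen=True)
class CalibrationSpec:
    free_params: tuple[str, ...] = ("alpha",)
    search_bounds: dict = field(default_factory=lambda: {"alpha": (5.0, 500.0)})
    objective: str = "count_match"  # or "pearson_binned" | "neg_vp"
    n_grid: int = 16
    refine_tol: float = 0.02  # relative bracket width to stop refinement
    bin_factor: int = 4

    def __post_init__(self) -> None:
        if not self.free_params:
            raise ValueError("free_params must be non-empty")
        for p in self.free_params:
            if p not in ("alpha", "gamma", "k_f", "k_r", "L"):
                raise ValueError(f"unknown free parameter {p!r}")
            lo, hi = self.search_bounds[p]
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {p} must be positive and ordered")


def objective(
    recordings: "list[tuple[TimeSeries, SpikeTrain]]",
    params: CellModelParams,
    spec: CalibrationSpec,
    mpc_cfg: MPCConfig,
) -> float:
    """Mean per-cell score of the inferred rate against ground truth."""
    metric_cfg = MetricConfig(bin_factor=spec.bin_factor, native_dt=mpc_cfg.dt)
    scores = []
    for trace, truth in recordings:
        result = infer_rates(trace, params, mpc_cfg)
        if spec.objective == "count_match":
            mass = float(np.sum(result.s_hat.values) * mpc_cfg.dt)
            count = len(truth)
            if count == 0 or mass <= 0:
                scores.append(np.nan)
            else:
                scores.append(-abs(np.log(mass / count)))
            continue
        if spec.objective == "neg_vp":
            scores.append(
                -victor_purpura(rates_to_spikes(result.s_hat, metric_cfg), truth, metric_cfg)
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = bin_downsample(result.s_hat, spec.bin_factor)
            true = bin_downsample(
                truth, spec.bin_factor, native_dt=mpc_cfg.dt, n_samples=len(trace)
            )
        m = min(len(pred), len(true))
        try:
            scores.append(pearson(pred[:m], true[:m]))
        except MetricError:
            scores.append(np.nan)
    return float(np.mean(scores))


def _search_1d(score_fn, lo: float, hi: float, n_grid: int, tol: float) -> float:
    """Log-grid scan then golden-section refinement of a 1-D objective."""
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    vals = np.array([score_fn(g) for g in grid])
    if not np.any(np.isfinite(vals)):
        raise CalibrationError("objective non-finite on the whole search grid")
    best = int(np.nanargmax(vals))
    # bracket = neighbors of the grid argmax (log domain)
    a = np.log(grid[max(best - 1, 0)])
    b = np.log(grid[min(best + 1, n_grid - 1)])
    cache = {np.log(grid[best]): vals[best]}

    def f(u: float) -> float:
        if u not in cache:
            cache[u] = score_fn(np.exp(u))
        return cache[u]

    c = b - _GOLD * (b - a)
    d = a + _GOLD * (b - a)
    while (b - a) > tol:
        if (f(c) if np.isfinite(f(c)) else -np.inf) >= (
            f(d) if np.isfinite(f(d)) else -np.inf
        ):
            b, d = d, c
            c = b - _GOLD * (b - a)
        else:
            a, c = c, d
            d = a + _GOLD * (b - a)
    candidates = [u for u in cache if a - 1e-12 <= u <= b + 1e-12] or list(cache)
    u_best = max(candidates, key=lambda u: cache[u] if np.isfinite(cache[u]) else -np.inf)
    return float(np.exp(u_best))


def calibrate(
    recordings: "list[tuple[TimeSeries, SpikeTrain]]",
    base: CellModelParams,
    spec: CalibrationSpec | None = None,
    mpc_cfg: MPCConfig | None = None,
) -> CellModelParams:
    """Return ``base`` with the free parameter(s) tuned to the recordings.

    Multiple free parameters are handled by one coordinate-wise pass of 1-D
    searches in the order given (the default, and the recommended use, is
    alpha alone).
    """
    spec = spec or CalibrationSpec()
    mpc_cfg = mpc_cfg or MPCConfig()
    if not recordings:
        raise ValueError("need at least one calibration recording")
    for trace, truth in recordings:
        if len(truth) == 0:
            raise CalibrationError(
                "ground truth has no spikes; correlation objective undefined"
            )
    params = base
    for name in spec.free_params:
        lo, hi = spec.search_bounds[name]

        def score(value: float, _name: str = name) -> float:
            return objective(
                recordings, params.with_values(**{_name: value}), spec, mpc_cfg
            )

        best = _search_1d(score, lo, hi, spec.n_grid, spec.refine_tol)
        params = params.with_values(**{name: best})
    return params
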