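"""Benchmarking metrics: binning, Pearson correlation, Victor-Purpura.

The benchmarking protocol downsamples rate/spike signals from the native
10 ms acquisition grid by a factor of 4 (40 ms bins) and scores inferred
against ground-truth activity with the Pearson correlation of the binned
signals.  As a complementary event-based score, the Victor-Purpura spike
distance is computed on the native grid with unit insert/delete cost and a
shift cost calibrated so that moving a spike by one native timestep costs
exactly 1 (lower is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import TimeSeries

__all__ = [
    "SpikeTrain",
    "MetricConfig",
    "MetricError",
    "bin_downsample",
    "pearson",
    "victor_purpura",
    "rates_to_spikes",
    "summarize",
]


class MetricError(ValueError):
    """A metric is undefined for the given inputs."""


@dataclass
class SpikeTrain:
    """Ordered spike times in seconds."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be ordered")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_counts(cls, counts: np.ndarray, dt: float, t0: float = 0.0) -> "SpikeTrain":
        """Build a train from per-bin counts, placing spikes at bin centers."""
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        times = np.repeat(t0 + (np.arange(len(counts)) + 0.5) * dt, counts.astype(int))
        return cls(times=times)

    def counts(self, dt: float, n_bins: int, t0: float = 0.0) -> np.ndarray:
        """Per-bin spike counts on a uniform grid of ``n_bins`` bins."""
        idx = np.floor((self.times - t0) / dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        return np.bincount(idx, minlength=n_bins)


@dataclass(frozen=True)
class MetricConfig:
    bin_factor: int = 4
    native_dt: float = 0.010
    vp_shift_cost_per_step: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_factor < 1:
            raise ValueError(f"bin_factor must be >= 1, got {self.bin_factor}")


def bin_downsample(
    series: TimeSeries | SpikeTrain,
    factor: int,
    native_dt: float = 0.010,
    n_samples: int | None = None,
) -> np.ndarray:
    """Block-sum a signal into bins of width ``factor * native_dt``.

    For a :class:`TimeSeries` of rates the per-bin value is the rate mass
    ``sum(s * dt)`` (expected spike count); for a :class:`SpikeTrain` it is
    the spike count per bin.  A partial tail bin is dropped with a warning.
    ``n_samples`` fixes the native-grid length for a SpikeTrain (defaults to
    the bin containing the last spike).
    """
    if factor < 1:
        raise MetricError(f"factor must be >= 1, got {factor}")
    if isinstance(series, TimeSeries):
        v = np.asarray(series.values, dtype=float) * series.dt
        native_dt = series.dt
    else:
        if n_samples is None:
            last = series.times.max() if len(series) else 0.0
            n_samples = int(np.floor(last / native_dt)) + 1
        v = series.counts(native_dt, n_samples).astype(float)
    n_full = len(v) // factor
    if len(v) % factor:
        warnings.warn(
            f"length {len(v)} not divisible by {factor}; dropping partial tail bin"
        )
    v = v[: n_full * factor]
    return v.reshape(n_full, factor).sum(axis=1)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson r; invariant to positive affine rescaling of either arg."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise MetricError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise MetricError("need at least 2 samples")
    if np.std(a) == 0 or np.std(b) == 0:
        raise MetricError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def victor_purpura(
    t1: SpikeTrain, t2: SpikeTrain, cfg: MetricConfig | None = None
) -> float:
    """Victor-Purpura edit distance between two spike trains.

    Insertions and deletions cost 1; shifting a spike by dt costs q*|dt|
    with q = vp_shift_cost_per_step / native_dt, so a one-native-timestep
    move costs exactly ``vp_shift_cost_per_step``.  Computed by the standard
    O(|a|*|b|) dynamic program; symmetric, zero on identical trains, and
    bounded by |a| + |b|.
    """
    cfg = cfg or MetricConfig()
    q = cfg.vp_shift_cost_per_step / cfg.native_dt
    a, b = t1.times, t2.times
    na, nb = len(a), len(b)
    prev = np.arange(nb + 1, dtype=float)
    for i in range(1, na + 1):
        cur = np.empty(nb + 1)
        cur[0] = i
        for j in range(1, nb + 1):
            shift = prev[j - 1] + min(q * abs(a[i - 1] - b[j - 1]), 2.0)
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0, shift)
        prev = cur
    return float(prev[nb])


def rates_to_spikes(s_hat: TimeSeries, cfg: MetricConfig | None = None) -> SpikeTrain:
    """Convert an inferred rate to discrete events for event-based metrics.

    The expected count per bin (sum of s*dt over the bin, bin width
    ``bin_factor * native_dt``) is rounded (half to even) and that many
    spikes are emitted at the bin center.
    """
    cfg = cfg or MetricConfig()
    if np.any(np.asarray(s_hat.values) < 0):
        raise ValueError("rates must be nonnegative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mass = bin_downsample(s_hat, cfg.bin_factor)
    counts = np.round(mass).astype(int)
    bin_dt = cfg.bin_factor * s_hat.dt
    return SpikeTrain.from_counts(counts, bin_dt, t0=s_hat.t0)


def summarize(scores: dict[str, "list[float] | np.ndarray"]) -> pd.DataFrame:
    """Per-group mean/median/sample-std plus a pooled 'all' row.

    Groups with a single score get std 0 and a degenerate flag; empty groups
    are skipped with a warning.
    """
    rows = []
    pooled: list[float] = []
    for group, vals in scores.items():
        vals = np.asarray(list(vals), dtype=float)
        if len(vals) == 0:
            warnings.warn(f"group {group!r} is empty; skipped")
            continue
        degenerate = len(vals) < 2
        rows.append(
            {
                "group": str(group),
                "n": len(vals),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "std": 0.0 if degenerate else float(vals.std(ddof=1)),
                "degenerate": degenerate,
            }
        )
        pooled.extend(vals.tolist())
    if pooled:
        pooled_arr = np.asarray(pooled)
        rows.append(
            {
                "group": "all",
                "n": len(pooled_arr),
                "mean": float(pooled_arr.mean()),
                "median": float(np.median(pooled_arr)),
                "std": 0.0 if len(pooled_arr) < 2 else float(pooled_arr.std(ddof=1)),
                "degenerate": len(pooled_arr) < 2,
            }
        )
    return pd.DataFrame(rows)
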