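"""Reading and writing spikefinder-style CSV recordings.

Layout: one CSV per quantity, one column per neuron, one row per 10 ms
sample; columns of unequal length are NaN-padded at the tail.  An optional
unnamed first column is treated as a row index and ignored.  Spike files
hold per-bin spike counts on the same grid.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import SpikeTrain
from .model import CellModelParams, IndicatorParams, TimeSeries

__all__ = [
    "Recording",
    "FormatError",
    "read_recordings",
    "write_columns",
    "write_results",
    "read_params",
    "write_params",
    "read_config",
]

NATIVE_DT = 0.010


class FormatError(ValueError):
    """A recording file does not match the expected layout."""


@dataclass
class Recording:
    dataset_id: str
    neuron_id: str
    calcium: TimeSeries
    spikes: SpikeTrain | None = None
    spike_counts: np.ndarray | None = None


def _read_table(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"{path}: empty file")
    first = df.columns[0]
    if str(first).startswith("Unnamed"):
        df = df.drop(columns=[first])
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise FormatError(f"{path}: non-numeric cell at row {row}, column {col!r}")
    return df.astype(float)


def _strip_padding(col: np.ndarray, label: str) -> np.ndarray:
    """Drop leading/trailing NaN padding; interpolate interior NaN."""
    finite = np.flatnonzero(~np.isnan(col))
    if len(finite) == 0:
        raise FormatError(f"column {label} is all-NaN")
    v = col[finite[0] : finite[-1] + 1]
    if np.isnan(v).any():
        warnings.warn(f"column {label}: interior NaN interpolated")
        idx = np.arange(len(v))
        good = ~np.isnan(v)
        v = np.interp(idx, idx[good], v[good])
    return v


def read_recordings(
    calcium_path: "str | Path",
    spikes_path: "str | Path | None" = None,
    dataset_id: str | None = None,
    dt: float = NATIVE_DT,
) -> list[Recording]:
    """Load paired (or calcium-only) recordings, one per column."""
    cal = _read_table(calcium_path)
    spk = _read_table(spikes_path) if spikes_path is not None else None
    if spk is not None and spk.shape[1] != cal.shape[1]:
        raise FormatError(
            f"column count mismatch: {cal.shape[1]} calcium vs {spk.shape[1]} spike columns"
        )
    dataset_id = dataset_id or Path(calcium_path).stem
    out = []
    for j, col in enumerate(cal.columns):
        trace = _strip_padding(cal[col].to_numpy(), f"{col} (calcium)")
        counts = None
        train = None
        if spk is not None:
            counts = _strip_padding(spk[spk.columns[j]].to_numpy(), f"{col} (spikes)")
            if len(counts) != len(trace):
                warnings.warn(
                    f"column {col}: calcium/spike lengths differ "
                    f"({len(trace)} vs {len(counts)}); truncating to min"
                )
                n = min(len(counts), len(trace))
                counts, trace = counts[:n], trace[:n]
            counts = np.round(counts).astype(int)
            train = SpikeTrain.from_counts(counts, dt)
        out.append(
            Recording(
                dataset_id=dataset_id,
                neuron_id=str(col),
                calcium=TimeSeries(values=trace, dt=dt),
                spikes=train,
                spike_counts=counts,
            )
        )
    return out


def write_columns(columns: dict[str, np.ndarray], path: "str | Path") -> None:
    """Write column-per-neuron CSV, NaN-padding unequal lengths."""
    n = max((len(v) for v in columns.values()), default=0)
    data = {
        k: np.concatenate([np.asarray(v, dtype=float), np.full(n - len(v), np.nan)])
        for k, v in columns.items()
    }
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_results(
    results: list,
    out_dir: "str | Path",
    params: CellModelParams | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write inferred rates, simulated CI*, and a reproducibility manifest.

    ``results`` is a list of :class:`spikempc.mpc.InferenceResult`; neuron
    columns are numbered in order.  The manifest records every parameter
    needed to re-run the inference bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_columns(
        {str(i): r.s_hat.values for i, r in enumerate(results)}, out_dir / "rates.csv"
    )
    write_columns(
        {str(i): r.ci_sim.values for i, r in enumerate(results)}, out_dir / "ci_sim.csv"
    )
    config = dict(config or {})
    manifest = {
        "n_neurons": len(results),
        "h_used": [r.h_used for r in results],
        "config": config,
        "seed": seed,
        "config_hash": _config_hash(config),
    }
    if params is not None:
        manifest["params"] = {
            "k_f": params.k_f,
            "k_r": params.k_r,
            "L": params.L,
            "alpha": params.alpha,
            "gamma": params.gamma,
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out_dir


def write_params(params: CellModelParams, path: "str | Path") -> None:
    """Parameter file: key=value, one per line."""
    with open(path, "w") as fh:
        for key, val in (
            ("k_f", params.k_f),
            ("k_r", params.k_r),
            ("L", params.L),
            ("alpha", params.alpha),
            ("gamma", params.gamma),
        ):
            fh.write(f"{key}={val!r}\n")


def read_params(path: "str | Path") -> CellModelParams:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = float(val)
    try:
        return CellModelParams(
            indicator=IndicatorParams(k_f=kv["k_f"], k_r=kv["k_r"], L=kv["L"]),
            alpha=kv["alpha"],
            gamma=kv["gamma"],
        )
    except KeyError as err:
        raise FormatError(f"{path}: missing parameter {err}") from err


def read_config(path: "str | Path") -> dict[str, dict[str, str]]:
    """Flat sectioned key=value config (INI dialect); values stay strings."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    return {sec: dict(parser[sec]) for sec in parser.sections()}
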