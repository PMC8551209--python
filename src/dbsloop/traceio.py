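"""Plain-CSV serialization of simulation traces.

One row per time step; the header documents units.  Voltage columns follow
the ``<pop>_v_<i>`` convention (1-based neuron index), control columns
``u_<i>`` and the shared sensorimotor drive ``smc``.  Round-trips preserve
full double precision.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .network import SimulationTrace

__all__ = ["write_trace", "read_trace"]

_HEADER = ("# dbsloop trace: t in ms, membrane potentials in mV, "
           "currents in uA/cm^2\n")


def trace_frame(trace: SimulationTrace, batch_index: int = 0) -> pd.DataFrame:
    """Flatten one batch member of a trace into a tidy wide table."""
    cols: dict[str, np.ndarray] = {"t": trace.t}
    n_samp = trace.t.size
    for key, arr in trace.data.items():
        for j in range(arr.shape[2]):
            cols[f"{key}_{j + 1}"] = arr[batch_index, :, j]
    if trace.i_smc is not None:
        smc = trace.i_smc
        cols["smc"] = smc[batch_index] if smc.ndim == 2 else smc
    if trace.i_dbs is not None:
        u = trace.i_dbs[batch_index]
        pad = np.full((n_samp - u.shape[0], u.shape[1]), np.nan)
        u = np.concatenate([u, pad], axis=0)
        for j in range(u.shape[1]):
            cols[f"u_{j + 1}"] = u[:, j]
    for key, arr in trace.extras.items():
        cols[key] = arr[batch_index] if arr.ndim > 1 else arr
    return pd.DataFrame(cols)


def write_trace(trace: SimulationTrace, path: str | Path,
                batch_index: int = 0) -> None:
    """Write one batch member as CSV (full precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        trace_frame(trace, batch_index).to_csv(
            fh, index=False, float_format="%.17g")


def read_trace(path: str | Path) -> SimulationTrace:
    """Read a trace CSV back into a single-batch :class:`SimulationTrace`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise IOError(f"malformed trace file {path}: {exc}") from exc
    if "t" not in df.columns:
        raise IOError(f"malformed trace file {path}: no 't' column "
                      f"(line 2 expected the header row)")
    t = df["t"].to_numpy()
    dt = float(t[1] - t[0]) if t.size > 1 else 0.0
    groups: dict[str, list[str]] = {}
    for col in df.columns:
        if col in ("t", "smc") or col.startswith("u_"):
            continue
        base, _, idx = col.rpartition("_")
        if base and idx.isdigit():
            groups.setdefault(base, []).append(col)
    data = {}
    for base, cols in groups.items():
        cols = sorted(cols, key=lambda c: int(c.rpartition("_")[2]))
        data[base] = df[cols].to_numpy()[None]
    smc = df["smc"].to_numpy() if "smc" in df.columns else None
    u_cols = sorted((c for c in df.columns if c.startswith("u_")),
                    key=lambda c: int(c.rpartition("_")[2]))
    i_dbs: Optional[np.ndarray] = None
    if u_cols:
        u = df[u_cols].to_numpy()
        u = u[~np.isnan(u).any(axis=1)]
        i_dbs = u[None]
    return SimulationTrace(t=t, dt=dt, data=data, i_smc=smc, i_dbs=i_dbs)
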