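"""Tracking-accuracy and control-effort metrics."""
from __future__ import annotations

import numpy as np

__all__ = ["rmse", "energy", "convergence_time", "max_step_change"]


class MetricError(ValueError):
    pass


def rmse(v_trace: np.ndarray, v_ref_trace: np.ndarray) -> np.ndarray:
    """Root-mean-square absolute tracking error sqrt(mean |v - v_ref|^2).

    Reduces over the leading (time) axis; any trailing axes (neurons) are
    preserved, so (T, n) inputs give per-neuron RMSE.
    """
    v = np.asarray(v_trace, dtype=float)
    r = np.asarray(v_ref_trace, dtype=float)
    if v.shape != r.shape:
        raise MetricError(f"trace shapes differ: {v.shape} vs {r.shape}")
    return np.sqrt(np.mean(np.abs(v - r) ** 2, axis=0))


def energy(u_trace: np.ndarray) -> float:
    """Energy index: RMS of the control vector, sqrt((1/T) sum_t u^T u)."""
    u = np.asarray(u_trace, dtype=float)
    if u.ndim == 1:
        u = u[:, None]
    return float(np.sqrt(np.mean(np.sum(u * u, axis=-1))))


def convergence_time(e_trace: np.ndarray, dt: float, tol: float = 1.0,
                     hold_ms: float = 1.0) -> float:
    """First time (ms) at which |e| falls and stays below ``tol`` for
    ``hold_ms``; NaN if it never does.  ``e_trace`` is (T,) for one channel.
    """
    e = np.abs(np.asarray(e_trace, dtype=float))
    hold = max(int(round(hold_ms / dt)), 1)
    ok = e < tol
    if e.size < hold:
        return float("nan")
    # run-length: position i qualifies if ok[i:i+hold] all true
    csum = np.cumsum(np.concatenate([[0], ok.astype(int)]))
    runs = csum[hold:] - csum[:-hold]
    idx = np.nonzero(runs == hold)[0]
    return float(idx[0] * dt) if idx.size else float("nan")


def max_step_change(u_trace: np.ndarray) -> float:
    """Largest per-step change max_t,i |u_i(t+1) - u_i(t)| of a control
    trace."""
    u = np.asarray(u_trace, dtype=float)
    return float(np.max(np.abs(np.diff(u, axis=0)))) if u.shape[0] > 1 else 0.0


def chattering_index(u_trace: np.ndarray, dt: float,
                     skip_ms: float = 50.0) -> float:
    """Median per-step |du| after the initial transient.

    The maximum per-step change is dominated by the large, legitimate
    control swings that accompany reference action potentials (present for
    any controller); the median instead isolates persistent switching
    activity, which is the chattering signature of the discontinuous
    classical law.
    """
    u = np.asarray(u_trace, dtype=float)
    skip = min(int(round(skip_ms / dt)), max(u.shape[0] - 2, 0))
    du = np.abs(np.diff(u[skip:], axis=0))
    return float(np.median(du)) if du.size else 0.0
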