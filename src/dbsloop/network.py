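"""Conductance-based basal-ganglia--thalamic network and its time stepper.

All state arrays carry a leading batch axis so that independent trials
(different pulse trains, initial conditions, uncertainty draws) integrate
simultaneously; a single trial is simply batch size one.  The stepper is
fixed-step forward Euler at the control update period (0.01 ms by default);
classical RK4 on the same grid is available as a high-accuracy mode and is
used by test oracles.

Internally the full network state lives in one (n_vars, batch, n_neurons)
array so that a time step is a single fused array operation; the public
:data:`NetworkState` view is a dict of named (batch, n_neurons) slices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np

from .params import NetworkParams, SmcInputParams

__all__ = [
    "NetworkState", "SimulationTrace", "IntegrationError",
    "smc_pulse_train", "synaptic_current", "initial_state",
    "membrane_derivatives", "integrate", "spike_times", "relay_fidelity",
]

STATE_KEYS = (
    "th_v", "th_h", "th_r",
    "stn_v", "stn_h", "stn_n", "stn_r", "stn_ca", "stn_s",
    "gpe_v", "gpe_h", "gpe_n", "gpe_r", "gpe_ca", "gpe_s",
    "gpi_v", "gpi_h", "gpi_n", "gpi_r", "gpi_ca", "gpi_s",
)
_IDX = {k: i for i, k in enumerate(STATE_KEYS)}
_NV = len(STATE_KEYS)

NetworkState = Dict[str, np.ndarray]  # each (batch, n) float64


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# inputs

def smc_pulse_train(params: SmcInputParams, duration: float, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Sensorimotor-cortex excitatory current trace (uA/cm^2) on the step
    grid, length ``round(duration/dt) + 1``.

    Rectangular pulses of width ``duration_ms``; each inter-pulse interval is
    the reciprocal of an instantaneous rate drawn from a gamma distribution
    with the configured mean and coefficient of variation (shape = 1/CV^2,
    scale = mean * CV^2).  The same trace drives every TH neuron.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    n = int(round(duration / dt)) + 1
    trace = np.zeros(n)
    if params.amplitude == 0.0:
        return trace
    shape = 1.0 / params.cv ** 2
    scale = params.rate_hz * params.cv ** 2
    if params.duration_ms > 1000.0 / params.rate_hz:
        warnings.warn("SMC pulse width exceeds the mean inter-pulse interval; "
                      "overlapping pulses are merged", stacklevel=2)
    t = 0.0
    while t < duration:
        rate = rng.gamma(shape, scale)  # Hz
        i0 = int(round(t / dt))
        i1 = min(int(round((t + params.duration_ms) / dt)), n)
        trace[i0:i1] = params.amplitude
        t += 1000.0 / rate  # next onset, ms
    return trace


def synaptic_current(g, v_post, e_rev, gate_sum):
    """Post-synaptic current g * (v_post - E) * sum_j s_j (uA/cm^2)."""
    return g * (v_post - e_rev) * gate_sum


# ---------------------------------------------------------------------------
# state packing

def _pack(state: NetworkState) -> np.ndarray:
    batch, n = np.asarray(state["th_v"]).shape
    y = np.empty((_NV, batch, n))
    for k, i in _IDX.items():
        y[i] = state[k]
    return y


def _unpack(y: np.ndarray) -> NetworkState:
    return {k: y[i] for k, i in _IDX.items()}


def _sigmoid(v, theta, sigma):
    """1 / (1 + exp(-(v - theta)/sigma)); sigma < 0 gives a falling curve."""
    return 1.0 / (1.0 + np.exp(-(v - theta) / sigma))


def _th_rinf(v):
    return 1.0 / (1.0 + np.exp((v + 84.0) / 4.0))


def initial_state(params: NetworkParams, batch: int,
                  rng: np.random.Generator) -> NetworkState:
    """Random initial membrane potentials uniform in [-70, -60] mV, gating
    variables at their steady state for the drawn voltage, synaptic gates and
    intracellular calcium starting at zero."""
    n = params.n_per_pop
    st: NetworkState = {}
    v = {pop: rng.uniform(-70.0, -60.0, size=(batch, n))
         for pop in ("th", "stn", "gpe", "gpi")}
    st["th_v"] = v["th"]
    st["th_h"] = _sigmoid(v["th"], -41.0, -4.0)
    st["th_r"] = _th_rinf(v["th"])
    st["stn_v"] = v["stn"]
    st["stn_h"] = _sigmoid(v["stn"], -39.0, -3.1)
    st["stn_n"] = _sigmoid(v["stn"], -32.0, 8.0)
    st["stn_r"] = _sigmoid(v["stn"], -67.0, -2.0)
    st["stn_ca"] = np.zeros((batch, n))
    st["stn_s"] = np.zeros((batch, n))
    for pop in ("gpe", "gpi"):
        st[f"{pop}_v"] = v[pop]
        st[f"{pop}_h"] = _sigmoid(v[pop], -58.0, -12.0)
        st[f"{pop}_n"] = _sigmoid(v[pop], -50.0, 14.0)
        st[f"{pop}_r"] = _sigmoid(v[pop], -70.0, -2.0)
        st[f"{pop}_ca"] = np.zeros((batch, n))
        st[f"{pop}_s"] = np.zeros((batch, n))
    return st


# ---------------------------------------------------------------------------
# right-hand side

class _Mods:
    """Effective-parameter lookup: nominal value times an optional
    time-varying multiplier (batch, 1) for that symbol."""

    __slots__ = ("mult",)

    def __init__(self, mult: Optional[Dict[str, np.ndarray]] = None):
        self.mult = mult or {}

    def __call__(self, symbol: str, nominal: float):
        m = self.mult.get(symbol)
        return nominal if m is None else nominal * m


_NO_MODS = _Mods()


def _rhs(out: np.ndarray, y: np.ndarray, params: NetworkParams,
         i_smc, i_dbs, i_dist, p: _Mods) -> None:
    """Write time derivatives of the packed state into ``out`` (units /ms)."""
    ix = _IDX
    cells, syn, gates, conn = (params.cells, params.synapses,
                               params.gates, params.connectivity)
    cm = params.c_m

    def gsum(proj):
        s = y[ix[proj.split("_")[0] + "_s"]]
        idx = conn[proj]
        if idx.ndim == 1:
            return s[:, idx]
        return s[:, idx].sum(axis=2)

    def isyn(proj, v_post):
        sp = syn[proj]
        return synaptic_current(p("g_" + proj, sp.g), v_post,
                                p("e_" + proj, sp.e_rev), gsum(proj))

    # ---- TH relay cells: leak, Na, K (n = 0.75(1-h)), low-threshold Ca (T)
    c = cells["th"]
    v = y[ix["th_v"]]
    h = y[ix["th_h"]]
    r = y[ix["th_r"]]
    il = p("g_l", c.g_l) * (v - p("e_l", c.e_l))
    minf = _sigmoid(v, -37.0, 7.0)
    ina = p("g_na", c.g_na) * minf ** 3 * h * (v - p("e_na", c.e_na))
    ik = p("g_k", c.g_k) * (0.75 * (1.0 - h)) ** 4 * (v - p("e_k", c.e_k))
    pinf = _sigmoid(v, -60.0, 6.2)
    it = p("g_t", c.g_t) * pinf ** 2 * r * (v - p("e_t", c.e_t))
    out[ix["th_v"]] = (-il - ina - ik - it - isyn("gpi_th", v)
                       + i_smc + i_dbs + i_dist) / cm
    ah = 0.128 * np.exp(-(v + 46.0) / 18.0)
    bh = 4.0 * _sigmoid(v, -23.0, 5.0)
    out[ix["th_h"]] = ah * (1.0 - h) - bh * h
    taur = 0.15 * (28.0 + np.exp(-(v + 25.0) / 10.5))
    out[ix["th_r"]] = (_th_rinf(v) - r) / taur

    # ---- STN cells
    c = cells["stn"]
    v = y[ix["stn_v"]]
    h = y[ix["stn_h"]]
    nk = y[ix["stn_n"]]
    r = y[ix["stn_r"]]
    ca = y[ix["stn_ca"]]
    e_k = p("e_k", c.e_k)
    e_ca = p("e_ca", c.e_ca)
    il = p("g_l", c.g_l) * (v - p("e_l", c.e_l))
    minf = _sigmoid(v, -30.0, 15.0)
    ina = p("g_na", c.g_na) * minf ** 3 * h * (v - p("e_na", c.e_na))
    ik = p("g_k", c.g_k) * nk ** 4 * (v - e_k)
    ainf = _sigmoid(v, -63.0, 7.8)
    binf = _sigmoid(r, 0.4, -0.1) - 1.0 / (1.0 + np.exp(4.0))
    it = p("g_t", c.g_t) * ainf ** 3 * binf ** 2 * (v - e_ca)
    cinf = _sigmoid(v, -39.0, 8.0)
    ica = p("g_ca", c.g_ca) * cinf ** 2 * (v - e_ca)
    iahp = p("g_ahp", c.g_ahp) * (v - e_k) * ca / (ca + 15.0)
    out[ix["stn_v"]] = (-il - ina - ik - it - ica - iahp
                        - isyn("gpe_stn", v) + c.i_app) / cm
    out[ix["stn_h"]] = 0.75 * (_sigmoid(v, -39.0, -3.1) - h) / \
        (1.0 + 500.0 * _sigmoid(v, -57.0, -3.0))
    out[ix["stn_n"]] = 0.75 * (_sigmoid(v, -32.0, 8.0) - nk) / \
        (1.0 + 100.0 * _sigmoid(v, -80.0, -26.0))
    out[ix["stn_r"]] = 0.2 * (_sigmoid(v, -67.0, -2.0) - r) / \
        (40.0 + 17.5 * _sigmoid(v, 68.0, -2.2))
    out[ix["stn_ca"]] = 3.75e-5 * (-ica - it - 22.5 * ca)
    gp = gates["stn"]
    s = y[ix["stn_s"]]
    out[ix["stn_s"]] = gp.alpha * _sigmoid(v, gp.theta, gp.sigma) * (1.0 - s) \
        - gp.beta * s

    # ---- pallidal cells (GPe, GPi share kinetics)
    for pop, exc, inh in (("gpe", "stn_gpe", "gpe_gpe"),
                          ("gpi", "stn_gpi", "gpe_gpi")):
        c = cells[pop]
        v = y[ix[f"{pop}_v"]]
        h = y[ix[f"{pop}_h"]]
        nk = y[ix[f"{pop}_n"]]
        r = y[ix[f"{pop}_r"]]
        ca = y[ix[f"{pop}_ca"]]
        e_k = p("e_k", c.e_k)
        e_ca = p("e_ca", c.e_ca)
        il = p("g_l", c.g_l) * (v - p("e_l", c.e_l))
        minf = _sigmoid(v, -37.0, 10.0)
        ina = p("g_na", c.g_na) * minf ** 3 * h * (v - p("e_na", c.e_na))
        ik = p("g_k", c.g_k) * nk ** 4 * (v - e_k)
        ainf = _sigmoid(v, -57.0, 2.0)
        it = p("g_t", c.g_t) * ainf ** 3 * r * (v - e_ca)
        cinf = _sigmoid(v, -35.0, 2.0)
        ica = p("g_ca", c.g_ca) * cinf ** 2 * (v - e_ca)
        iahp = p("g_ahp", c.g_ahp) * (v - e_k) * ca / (ca + 10.0)
        out[ix[f"{pop}_v"]] = (-il - ina - ik - it - ica - iahp
                               - isyn(exc, v) - isyn(inh, v) + c.i_app) / cm
        tau_hn = 0.05 + 0.27 * _sigmoid(v, -40.0, -12.0)
        out[ix[f"{pop}_h"]] = 0.05 * (_sigmoid(v, -58.0, -12.0) - h) / tau_hn
        out[ix[f"{pop}_n"]] = 0.05 * (_sigmoid(v, -50.0, 14.0) - nk) / tau_hn
        out[ix[f"{pop}_r"]] = (_sigmoid(v, -70.0, -2.0) - r) / 30.0
        out[ix[f"{pop}_ca"]] = 1e-4 * (-ica - it - 15.0 * ca)
        gp = gates[pop]
        s = y[ix[f"{pop}_s"]]
        out[ix[f"{pop}_s"]] = gp.alpha * _sigmoid(v, gp.theta, gp.sigma) \
            * (1.0 - s) - gp.beta * s


def membrane_derivatives(state: NetworkState, params: NetworkParams,
                         i_smc=0.0, i_dbs=0.0, i_dist=0.0,
                         mods: Optional[Dict[str, np.ndarray]] = None,
                         ) -> NetworkState:
    """Time derivatives of all state variables (units per ms).

    ``i_smc`` is the scalar/broadcastable sensorimotor drive, ``i_dbs`` the
    per-TH-neuron stimulation current (batch, n) and ``i_dist`` an additive
    per-TH-neuron disturbance; all three enter the TH membrane equation only.
    ``mods`` optionally maps parameter symbols (``g_l`` ... ``e_gpi_th``) to
    multiplicative uncertainty factors of shape (batch, 1).
    """
    y = _pack(state)
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state passed to membrane_derivatives")
    out = np.empty_like(y)
    _rhs(out, y, params, i_smc, i_dbs, i_dist, _Mods(mods) if mods else _NO_MODS)
    return _unpack(out)


# ---------------------------------------------------------------------------
# integration

@dataclass
class SimulationTrace:
    """Time-indexed record of one (batched) simulation.

    ``data`` maps recorded state keys to arrays of shape (batch, n_samples,
    n_neurons); ``i_smc`` is the pulse train on the same grid and ``i_dbs``
    (batch, n_steps, n_neurons) the applied control when a controller ran.
    """

    t: np.ndarray
    dt: float
    data: Dict[str, np.ndarray]
    i_smc: Optional[np.ndarray] = None
    i_dbs: Optional[np.ndarray] = None
    extras: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def batch(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return self.t.size


def integrate(params: NetworkParams,
              initial: NetworkState,
              duration: float,
              dt: float,
              smc: Optional[np.ndarray] = None,
              dbs: Optional[Callable[[int, float, np.ndarray], np.ndarray]] = None,
              disturbance: Optional[Callable[[float], np.ndarray]] = None,
              mods: Optional[Callable[[int], Dict[str, np.ndarray]]] = None,
              record: Sequence[str] = ("th_v",),
              method: str = "euler",
              check_every: int = 200,
              ) -> SimulationTrace:
    """Integrate the network for ``duration`` ms at fixed step ``dt``.

    ``smc`` is a precomputed pulse-train trace on the step grid, either
    (n_steps+1,) shared by the whole batch or (batch, n_steps+1) per trial
    (always shared by the 10 TH neurons of a trial);
    ``dbs(step, t, v_th)`` returns the per-TH-neuron control
    current and is evaluated once per step (zero-order hold);
    ``disturbance(t)`` is an additive TH current; ``mods(step)`` returns the
    uncertainty multipliers for that step.  The returned trace holds
    n_steps + 1 samples (including the initial state) of every key in
    ``record``.  Deterministic given its inputs.
    """
    if dt <= 0 or duration < 0:
        raise ValueError("need dt > 0 and duration >= 0")
    n_steps = int(round(duration / dt))
    y = _pack(initial)
    batch, n = y.shape[1:]
    ix = _IDX

    out = {k: np.empty((batch, n_steps + 1, n)) for k in record}
    for k in record:
        out[k][:, 0] = y[ix[k]]
    u_log = np.zeros((batch, n_steps, n)) if dbs is not None else None

    d = np.empty_like(y)
    bufs = [np.empty_like(y) for _ in range(3)] if method == "rk4" else None
    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown method {method!r}")

    smc_2d = smc is not None and np.ndim(smc) == 2
    for k in range(n_steps):
        t = k * dt
        if smc is None:
            i_smc = 0.0
        elif smc_2d:
            i_smc = smc[:, k, None]
        else:
            i_smc = smc[k]
        i_dbs = dbs(k, t, y[ix["th_v"]]) if dbs is not None else 0.0
        if u_log is not None:
            u_log[:, k] = i_dbs
        i_dist = disturbance(t) if disturbance is not None else 0.0
        m = _Mods(mods(k)) if mods is not None else _NO_MODS
        if method == "euler":
            _rhs(d, y, params, i_smc, i_dbs, i_dist, m)
            y += dt * d
        else:
            d2, d3, d4 = bufs
            _rhs(d, y, params, i_smc, i_dbs, i_dist, m)
            _rhs(d2, y + 0.5 * dt * d, params, i_smc, i_dbs, i_dist, m)
            _rhs(d3, y + 0.5 * dt * d2, params, i_smc, i_dbs, i_dist, m)
            _rhs(d4, y + dt * d3, params, i_smc, i_dbs, i_dist, m)
            y += (dt / 6.0) * (d + 2.0 * d2 + 2.0 * d3 + d4)
        for key in record:
            out[key][:, k + 1] = y[ix[key]]
        if (k + 1) % check_every == 0 or k == n_steps - 1:
            if not np.all(np.isfinite(y)):
                bad = [key for key, i in ix.items()
                       if not np.all(np.isfinite(y[i]))]
                raise IntegrationError(
                    f"non-finite state in {bad} at step {k + 1} "
                    f"(t = {t + dt:.3f} ms)")

    t_grid = np.arange(n_steps + 1) * dt
    return SimulationTrace(
        t=t_grid, dt=dt, data=out,
        i_smc=(smc[..., :n_steps + 1].copy() if smc is not None else None),
        i_dbs=u_log)


# ---------------------------------------------------------------------------
# spike utilities

def spike_times(v: np.ndarray, dt: float, threshold: float = -20.0) -> np.ndarray:
    """Times (ms) of upward threshold crossings of a single voltage trace."""
    v = np.asarray(v)
    up = (v[:-1] < threshold) & (v[1:] >= threshold)
    return (np.nonzero(up)[0] + 1) * dt


def relay_fidelity(v_th: np.ndarray, smc: np.ndarray, dt: float,
                   window_ms: float = 10.0, threshold: float = -20.0) -> float:
    """Fraction of sensorimotor pulses answered by a TH spike within
    ``window_ms`` of pulse onset (one voltage trace, one pulse train)."""
    onsets = np.nonzero((smc[1:] > 0) & (smc[:-1] == 0))[0] + 1
    if smc[0] > 0:
        onsets = np.concatenate([[0], onsets])
    if onsets.size == 0:
        return float("nan")
    spikes = spike_times(v_th, dt, threshold)
    answered = 0
    for o in onsets * dt:
        if np.any((spikes >= o) & (spikes <= o + window_ms)):
            answered += 1
    return answered / onsets.size
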