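"""Closed-loop tracking experiments: nominal, uncertain, and disturbed.

Each trial simulates the healthy network open loop (the reference trajectory
x_d and its same-step finite-difference derivative), then the Parkinsonian
network in closed loop with the chosen controller, and scores tracking RMSE,
the control-energy index, and the transient convergence time.  Independent
trials run batched; everything is reproducible from (scenario, master seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import network as net
from .controller import ControllerConfig, SlidingModeController
from .metrics import (chattering_index, convergence_time, energy,
                      max_step_change, rmse)
from .params import NetworkParams, SmcInputParams, apply_condition
from .uncertainty import channel_disturbance, perturb_parameters

__all__ = ["Scenario", "TrialMetrics", "run_trial", "run_trials",
           "compare_controllers", "one_way_anova"]


@dataclass
class Scenario:
    """One experimental condition: reference = healthy network, plant = PD
    network under closed-loop stimulation."""

    mode: str = "aftsmc"            # controller mode
    uncertainty: float = 0.0        # maximal relative parameter deviation
    disturbance: bool = False       # sinusoidal ionic-channel disturbance
    duration: float = 1000.0        # ms
    dt: float = 0.01                # ms
    n_trials: int = 10
    controller: ControllerConfig = None
    network: NetworkParams = None
    smc: SmcInputParams = field(default_factory=SmcInputParams)

    def __post_init__(self):
        if not 0.0 <= self.uncertainty <= 0.5:
            raise ValueError("uncertainty level must be in [0, 0.5]")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.controller is None:
            self.controller = ControllerConfig(mode=self.mode)
        elif self.controller.mode != self.mode:
            self.controller = replace(self.controller, mode=self.mode)
        if self.network is None:
            self.network = NetworkParams()


@dataclass
class TrialMetrics:
    """Per-trial scores; voltages in mV, currents in uA/cm^2, times in ms."""

    rmse_per_neuron: np.ndarray
    rmse_mean: float
    energy: float
    max_u: float
    max_du: float
    chattering: float
    convergence_time_ms: float

    @property
    def rmse_neuron1(self) -> float:
        return float(self.rmse_per_neuron[0])


def _trial_rngs(master_seed: int, n_trials: int):
    """Named substreams per trial: (smc, healthy-init, pd-init, fuzzy-init,
    uncertainty)."""
    root = np.random.SeedSequence(master_seed)
    streams = []
    for child in root.spawn(n_trials):
        streams.append([np.random.default_rng(s) for s in child.spawn(5)])
    return streams


@dataclass
class ReferenceTrajectory:
    """Healthy-network reference shared by controller variants: the pulse
    trains, the reference TH voltages x_d and their same-step
    finite-difference derivative.  Tagged by (master_seed, n_trials,
    duration, dt) so it is only reused for the matching trial set."""

    smc: np.ndarray
    x_d: np.ndarray
    x_d_dot: np.ndarray
    tag: tuple


def compute_reference(scenario: Scenario, master_seed: int,
                      n_trials: Optional[int] = None) -> ReferenceTrajectory:
    """Simulate the healthy network open loop for each trial."""
    sc = scenario
    B = n_trials if n_trials is not None else sc.n_trials
    dt, dur = sc.dt, sc.duration
    rngs = _trial_rngs(master_seed, B)
    p_h = apply_condition(sc.network, "healthy")
    smc = np.stack([net.smc_pulse_train(sc.smc, dur, dt, r[0]) for r in rngs])
    init_h = _stack_states([net.initial_state(p_h, 1, r[1]) for r in rngs])
    ref = net.integrate(p_h, init_h, dur, dt, smc=smc)
    x_d = ref.data["th_v"]                                  # (B, T+1, 10)
    x_d_dot = np.diff(x_d, axis=1) / dt                     # (B, T, 10)
    return ReferenceTrajectory(smc, x_d, x_d_dot,
                               tag=(master_seed, B, dur, dt))


def run_trials(scenario: Scenario, master_seed: int,
               n_trials: Optional[int] = None, record_traces: bool = False,
               reference: Optional[ReferenceTrajectory] = None,
               ) -> Tuple[List[TrialMetrics], Optional[Dict[str, np.ndarray]]]:
    """Run ``n_trials`` independent trials of one scenario, batched.

    Returns the per-trial metrics and, if ``record_traces``, a dict with the
    full time courses (t, reference and plant TH voltages, control input,
    error) for plotting or serialization.  ``reference`` may carry the
    healthy reference precomputed by :func:`compute_reference` (it depends
    only on seed/horizon, not on the controller, so the same object serves
    both controller modes).
    """
    sc = scenario
    B = n_trials if n_trials is not None else sc.n_trials
    dt, dur = sc.dt, sc.duration
    n_steps = int(round(dur / dt))
    rngs = _trial_rngs(master_seed, B)

    p_pd = apply_condition(sc.network, "pd")

    if reference is None:
        reference = compute_reference(sc, master_seed, B)
    elif reference.tag != (master_seed, B, dur, dt):
        raise ValueError(f"reference tag {reference.tag} does not match "
                         f"{(master_seed, B, dur, dt)}")
    smc, x_d, x_d_dot = reference.smc, reference.x_d, reference.x_d_dot

    # plant: PD network, closed loop
    init_pd = _stack_states([net.initial_state(p_pd, 1, r[2]) for r in rngs])
    ctrl = SlidingModeController(sc.controller)
    ctrl.reset(B, _stacked_rng([r[3] for r in rngs]))

    mods = None
    if sc.uncertainty > 0.0:
        mod = perturb_parameters(sc.uncertainty, dur, dt,
                                 _stacked_rng([r[4] for r in rngs]), batch=B)
        mods = mod.at_step
    dist = channel_disturbance if sc.disturbance else None

    e_log = np.empty((B, n_steps, 10))
    extras = {}
    if record_traces:
        ctrl.log_internals = True
        extras["s"] = np.empty((B, n_steps, 10))
        extras["pred"] = np.empty((B, n_steps, 10))
        extras["u_eq"] = np.empty((B, n_steps, 10))

    def dbs(k, t, v_th):
        e_log[:, k] = x_d[:, k] - v_th
        u = ctrl.step(v_th, x_d[:, k], x_d_dot[:, k], dt)
        if record_traces:
            extras["s"][:, k] = ctrl.state.s
            extras["pred"][:, k] = ctrl.state.pred
            extras["u_eq"][:, k] = ctrl.state.u_eq
        return u

    trace = net.integrate(p_pd, init_pd, dur, dt, smc=smc, dbs=dbs,
                          disturbance=dist, mods=mods)
    u = trace.i_dbs                                          # (B, T, 10)

    metrics = []
    for b in range(B):
        per_neuron = rmse(trace.data["th_v"][b, 1:], x_d[b, 1:])
        metrics.append(TrialMetrics(
            rmse_per_neuron=per_neuron,
            rmse_mean=float(per_neuron.mean()),
            energy=energy(u[b]),
            max_u=float(np.max(np.abs(u[b]))),
            max_du=max_step_change(u[b]),
            chattering=chattering_index(u[b], dt),
            convergence_time_ms=convergence_time(e_log[b, :, 0], dt)))

    traces = None
    if record_traces:
        traces = {"t": trace.t, "x": trace.data["th_v"], "x_d": x_d,
                  "u": u, "e": e_log, "smc": smc, **extras}
    return metrics, traces


def run_trial(scenario: Scenario, seed: int, record_traces: bool = False):
    """One trial; returns (metrics, traces or None)."""
    m, tr = run_trials(scenario, seed, n_trials=1, record_traces=record_traces)
    return m[0], tr


def _stack_states(states: Sequence[net.NetworkState]) -> net.NetworkState:
    return {k: np.concatenate([s[k] for s in states], axis=0)
            for k in states[0]}


class _stacked_rng:
    """Per-trial generators presented as one batched generator: row b of any
    uniform draw comes from trial b's own stream, so adding trials never
    changes earlier ones."""

    def __init__(self, rngs):
        self.rngs = rngs

    def uniform(self, lo, hi, size):
        assert size[0] == len(self.rngs)
        return np.stack([r.uniform(lo, hi, size=size[1:]) for r in self.rngs])


# ---------------------------------------------------------------------------
# controller comparison and statistics

def one_way_anova(*groups) -> Tuple[float, float, bool]:
    """One-way ANOVA across groups; returns (F, p, degenerate).

    Zero within-group variance everywhere makes F undefined; such cells are
    flagged instead of tested.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        return float("nan"), float("nan"), True
    if all(np.var(a) == 0.0 for a in arrs):
        return float("nan"), float("nan"), True
    f, p = stats.f_oneway(*arrs)
    return float(f), float(p), False


def compare_controllers(levels: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
                        disturbance: bool = False, n_trials: int = 10,
                        master_seed: int = 0, duration: float = 1000.0,
                        dt: float = 0.01,
                        base_controller: Optional[ControllerConfig] = None,
                        ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sweep uncertainty levels for both controllers.

    Returns (long-format per-trial table, mean +- SD summary, per-level
    one-way ANOVA table comparing the controllers on RMSE and Energy).
    """
    if n_trials < 2:
        raise ValueError("need at least two trials per cell")
    rows = []
    reference = None
    for mode in ("aftsmc", "afsmc"):
        cc = replace(base_controller, mode=mode) if base_controller else None
        for level in levels:
            sc = Scenario(mode=mode, uncertainty=level,
                          disturbance=disturbance, duration=duration, dt=dt,
                          n_trials=n_trials, controller=cc)
            if reference is None:
                reference = compute_reference(sc, master_seed)
            metrics, _ = run_trials(sc, master_seed, reference=reference)
            for i, m in enumerate(metrics):
                rows.append(dict(controller=mode, uncertainty=level,
                                 disturbance=disturbance, trial=i,
                                 rmse=m.rmse_mean,
                                 rmse_neuron1=m.rmse_neuron1,
                                 energy=m.energy, max_u=m.max_u))
    table = pd.DataFrame(rows)
    summary = (table.groupby(["controller", "uncertainty"])[["rmse", "energy"]]
               .agg(["mean", "std"]).reset_index())
    anova_rows = []
    for level in levels:
        sub = table[table.uncertainty == level]
        for metric in ("rmse", "energy"):
            a = sub[sub.controller == "aftsmc"][metric]
            b = sub[sub.controller == "afsmc"][metric]
            f, p, degenerate = one_way_anova(a, b)
            anova_rows.append(dict(uncertainty=level, metric=metric, F=f,
                                   p=p, degenerate=degenerate))
    return table, summary, pd.DataFrame(anova_rows)
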