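"""Plant parameters for the basal-ganglia--thalamic network.

The network comprises four populations (thalamus TH, subthalamic nucleus STN,
external and internal globus pallidus GPe/GPi), ten conductance-based neurons
each, wired with sparse deterministic connectivity.  The Parkinsonian condition
is modelled purely as a reduction of the net bias currents applied to STN, GPe
and GPi, standing in for dopamine depletion.

Units follow the conventions of single-compartment membrane models throughout:
mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

import numpy as np

POPULATIONS = ("th", "stn", "gpe", "gpi")

#: projections, named presynaptic -> postsynaptic
PROJECTIONS = ("stn_gpe", "stn_gpi", "gpe_stn", "gpe_gpe", "gpe_gpi", "gpi_th")

#: net bias currents (uA/cm^2) per condition; TH receives no bias current.
CONDITION_I_APP = {
    "healthy": {"stn": 33.0, "gpe": 20.0, "gpi": 21.0},
    "pd": {"stn": 23.0, "gpe": 7.0, "gpi": 15.0},
}


class ConfigurationError(ValueError):
    """Raised for invalid model or controller configuration."""


@dataclass
class CellParams:
    """Maximal conductances (mS/cm^2), reversal potentials (mV) and bias
    current (uA/cm^2) of one cell type.  Channels a cell type lacks carry a
    zero conductance."""

    g_l: float
    e_l: float
    g_na: float
    e_na: float
    g_k: float
    e_k: float
    g_t: float
    e_t: float
    g_ca: float = 0.0
    e_ca: float = 0.0
    g_ahp: float = 0.0
    i_app: float = 0.0


@dataclass
class SynapseParams:
    """Maximal conductance and reversal potential of one projection."""

    g: float
    e_rev: float


@dataclass
class GateParams:
    """First-order synaptic-gate kinetics of one presynaptic population.

    ds/dt = alpha * Hinf(v_pre) * (1 - s) - beta * s, with Hinf a sigmoid
    opening during the presynaptic action potential.
    """

    alpha: float  # 1/ms, rise rate during the presynaptic spike
    beta: float   # 1/ms, decay rate
    theta: float = -20.0  # mV, half-activation of the spike detector
    sigma: float = 2.0    # mV, slope


def circular_connectivity(n: int = 10) -> Dict[str, np.ndarray]:
    """Deterministic sparse wiring with the in/out-degrees of the network.

    Each GPe/GPi neuron receives two STN excitatory inputs (neighbours i+-1)
    and two GPe collaterals (i+-2, never itself); each STN neuron receives two
    GPe inputs (i+-1); GPi neuron i inhibits TH neuron i (a bijection).
    """
    i = np.arange(n)
    two_near = np.stack([(i - 1) % n, (i + 1) % n], axis=1)
    two_far = np.stack([(i - 2) % n, (i + 2) % n], axis=1)
    return {
        "stn_gpe": two_near.copy(),
        "stn_gpi": two_near.copy(),
        "gpe_stn": two_near.copy(),
        "gpe_gpe": two_far.copy(),
        "gpe_gpi": two_far.copy(),
        "gpi_th": i.copy(),
    }


def _default_cells() -> Dict[str, CellParams]:
    # Thalamocortical relay cell: leak, Na, K, low-threshold Ca (T).
    th = CellParams(g_l=0.05, e_l=-70.0, g_na=3.0, e_na=50.0,
                    g_k=5.0, e_k=-75.0, g_t=5.0, e_t=0.0)
    # STN cell: adds high-threshold Ca and Ca-gated AHP currents.
    stn = CellParams(g_l=2.25, e_l=-60.0, g_na=37.5, e_na=55.0,
                     g_k=45.0, e_k=-80.0, g_t=0.5, e_t=140.0,
                     g_ca=0.5, e_ca=140.0, g_ahp=9.0, i_app=33.0)
    # Pallidal cells (GPe and GPi share kinetics; bias currents differ).
    gp = dict(g_l=0.1, e_l=-65.0, g_na=120.0, e_na=55.0,
              g_k=30.0, e_k=-80.0, g_t=0.5, e_t=120.0,
              g_ca=0.15, e_ca=120.0, g_ahp=30.0)
    gpe = CellParams(i_app=20.0, **gp)
    gpi = CellParams(i_app=21.0, **gp)
    return {"th": th, "stn": stn, "gpe": gpe, "gpi": gpi}


def _default_synapses() -> Dict[str, SynapseParams]:
    return {
        "stn_gpe": SynapseParams(g=0.15, e_rev=0.0),
        "stn_gpi": SynapseParams(g=0.15, e_rev=0.0),
        "gpe_stn": SynapseParams(g=0.5, e_rev=-85.0),
        "gpe_gpe": SynapseParams(g=0.5, e_rev=-85.0),
        "gpe_gpi": SynapseParams(g=0.5, e_rev=-85.0),
        "gpi_th": SynapseParams(g=0.112, e_rev=-85.0),
    }


def _default_gates() -> Dict[str, GateParams]:
    return {
        "stn": GateParams(alpha=5.0, beta=1.0),    # fast glutamatergic
        "gpe": GateParams(alpha=2.0, beta=0.08),   # GABAergic, ~12 ms decay
        "gpi": GateParams(alpha=2.0, beta=0.08),
    }


@dataclass
class NetworkParams:
    """All plant constants: cell parameters per population, synaptic
    conductances/reversals per projection, gate kinetics per presynaptic
    population, connectivity index maps and the condition tag."""

    c_m: float = 1.0  # uF/cm^2
    n_per_pop: int = 10
    condition: str = "healthy"
    cells: Dict[str, CellParams] = field(default_factory=_default_cells)
    synapses: Dict[str, SynapseParams] = field(default_factory=_default_synapses)
    gates: Dict[str, GateParams] = field(default_factory=_default_gates)
    connectivity: Dict[str, np.ndarray] = field(default_factory=circular_connectivity)

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_I_APP:
            raise ConfigurationError(
                f"unknown condition {self.condition!r}; expected 'healthy' or 'pd'")
        if self.n_per_pop != len(self.connectivity["gpi_th"]):
            self.connectivity = circular_connectivity(self.n_per_pop)

    @property
    def i_app(self) -> Dict[str, float]:
        return {pop: self.cells[pop].i_app for pop in ("stn", "gpe", "gpi")}


def apply_condition(params: NetworkParams, condition: str) -> NetworkParams:
    """Return a copy of *params* with the bias currents of the given
    condition; every other field is unchanged."""
    if condition not in CONDITION_I_APP:
        raise ConfigurationError(
            f"unknown condition {condition!r}; expected 'healthy' or 'pd'")
    cells = dict(params.cells)
    for pop, i_app in CONDITION_I_APP[condition].items():
        cells[pop] = replace(cells[pop], i_app=i_app)
    return replace(params, cells=cells, condition=condition)


@dataclass
class SmcInputParams:
    """Stochastic sensorimotor-cortex pulse train: rectangular pulses whose
    instantaneous rate is gamma-distributed."""

    amplitude: float = 3.5  # uA/cm^2
    duration_ms: float = 5.0  # pulse width, ms
    rate_hz: float = 14.0   # mean instantaneous rate
    cv: float = 0.2         # coefficient of variation of the rate

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigurationError("SMC amplitude must be >= 0")
        if self.duration_ms <= 0 or self.rate_hz <= 0 or self.cv <= 0:
            raise ConfigurationError("SMC duration, rate and CV must be > 0")
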