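"""Time-varying parameter uncertainty and ionic-channel disturbances.

Model uncertainty is injected as independent smooth multiplicative
trajectories m(t) on every ionic conductance, ionic reversal potential,
synaptic conductance and synaptic reversal potential: uniform white noise is
passed through a fourth-order low-pass Butterworth filter (cutoff 0.025 Hz)
and rescaled so the largest deviation from 1 equals the requested level.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.signal import butter, sosfilt

from .params import PROJECTIONS

__all__ = ["PERTURBED_SYMBOLS", "ParameterModulation", "perturb_parameters",
           "channel_disturbance"]

#: the perturbed parameter symbols: six maximal ionic conductances, five
#: ionic reversal potentials, and conductance + reversal of each projection.
PERTURBED_SYMBOLS = (
    "g_l", "g_na", "g_k", "g_t", "g_ca", "g_ahp",
    "e_l", "e_na", "e_k", "e_t", "e_ca",
    *(f"g_{p}" for p in PROJECTIONS),
    *(f"e_{p}" for p in PROJECTIONS),
)


@dataclass
class ParameterModulation:
    """Sampled multiplier trajectories, held piecewise-constant between
    coarse samples when queried on the fine integration grid."""

    multipliers: np.ndarray       # (batch, n_symbols, n_coarse)
    coarse_dt: float              # ms
    dt: float                     # integration step, ms
    symbols: tuple = PERTURBED_SYMBOLS

    def __post_init__(self):
        b, ns, nc = self.multipliers.shape
        if ns != len(self.symbols):
            raise ValueError("multiplier/symbol count mismatch")
        self._cache: Dict[int, Dict[str, np.ndarray]] = {}

    def _coarse_index(self, step: int) -> int:
        return min(int(step * self.dt / self.coarse_dt),
                   self.multipliers.shape[2] - 1)

    def at_step(self, step: int) -> Dict[str, np.ndarray]:
        """Multiplier dict {symbol: (batch, 1)} for integration step."""
        ci = self._coarse_index(step)
        hit = self._cache.get(ci)
        if hit is None:
            hit = {sym: self.multipliers[:, j, ci][:, None]
                   for j, sym in enumerate(self.symbols)}
            self._cache[ci] = hit
        return hit


def _filtered_uniform(n_out: int, fs_hz: float, cutoff_hz: float,
                      rng: np.random.Generator, shape) -> np.ndarray:
    """Low-pass-filtered uniform noise, discarding the filter warm-up."""
    warm = int(4 * fs_hz / cutoff_hz)
    raw = rng.uniform(-1.0, 1.0, size=shape + (warm + n_out,))
    sos = butter(4, cutoff_hz, fs=fs_hz, output="sos")
    return sosfilt(sos, raw, axis=-1)[..., warm:]


def perturb_parameters(level: float, duration: float, dt: float,
                       rng: np.random.Generator, batch: int = 1,
                       cutoff_hz: float = 0.025, fs_hz: float = 10.0,
                       coarse_dt: Optional[float] = None,
                       ) -> ParameterModulation:
    """Smooth multiplicative uncertainty trajectories for every perturbed
    parameter.

    ``level`` in [0, 1) is the maximal relative deviation: after rescaling,
    max_t |m(t) - 1| == level for every trajectory (exactly, by the
    rescaling contract).  Noise is generated at ``fs_hz`` (ample for the
    0.025 Hz passband), filtered with a fourth-order Butterworth low-pass in
    second-order-sections form, rescaled, then linearly interpolated onto a
    coarse grid (default 1 ms) that the integrator samples with zero-order
    hold.
    """
    if not 0.0 <= level < 1.0:
        raise ValueError("uncertainty level must be in [0, 1)")
    if coarse_dt is None:
        coarse_dt = max(dt, 1.0)
    n_sym = len(PERTURBED_SYMBOLS)
    nc = int(np.ceil(duration / coarse_dt)) + 1
    if level == 0.0:
        mult = np.ones((batch, n_sym, nc))
        return ParameterModulation(mult, coarse_dt, dt)
    # noise sampled at fs_hz over the simulated window (at least 2 samples)
    n_noise = max(int(np.ceil(duration / 1000.0 * fs_hz)) + 2, 2)
    dev = _filtered_uniform(n_noise, fs_hz, cutoff_hz, rng, (batch, n_sym))
    t_noise = np.arange(n_noise) * (1000.0 / fs_hz)  # ms
    t_coarse = np.arange(nc) * coarse_dt
    mult = np.empty((batch, n_sym, nc))
    for b in range(batch):
        for j in range(n_sym):
            mult[b, j] = np.interp(t_coarse, t_noise, dev[b, j])
    # rescale on the delivered window so max_t |m - 1| == level exactly
    peak = np.max(np.abs(mult), axis=-1, keepdims=True)
    peak[peak == 0.0] = 1.0
    mult = 1.0 + level * mult / peak
    return ParameterModulation(mult, coarse_dt, dt)


def channel_disturbance(t_ms, k=None) -> np.ndarray:
    """Sinusoidal ionic-channel disturbance i_d(t) = sin(1 + k t / 10)
    (uA/cm^2) for TH neuron k = 1..10, with t in seconds so the disturbance
    sweeps on a seconds timescale across the population.

    With ``k=None`` returns the length-10 vector for all neurons.
    """
    t_s = np.asarray(t_ms, dtype=float) / 1000.0
    if k is None:
        k = np.arange(1, 11)
    else:
        k = np.asarray(k)
        if np.any((k < 1) | (k > 10)):
            raise IndexError("neuron index k must be in 1..10")
    return np.sin(1.0 + np.multiply.outer(t_s, k) / 10.0)
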