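"""Fuzzy-logic estimator of the unknown thalamic dynamics.

A singleton-fuzzifier / product-inference / centre-average fuzzy logic system
(FLS) maps the ten TH membrane potentials to an estimate ``f1_hat`` (the drift
of the canonical first-order MIMO form, folding in the external disturbance)
and ``F2_hat`` (the input gain matrix).  Both outputs are linear in the rule
weights, which are adapted online by Lyapunov-derived gradient laws driven by
the sliding variable.

With two Gaussian membership functions on each of ten inputs the full product
rule base has 2^10 rules; the default configuration instead uses the additive
(per-dimension) rule activation with shared weights, which keeps the rule
count at 20 while remaining a linear-in-parameters universal approximator of
the same family.  The full product base is available via ``rule_base =
"product"``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import ConfigurationError

log = logging.getLogger(__name__)

__all__ = ["MembershipGrid", "FuzzyEstimator", "KnownDynamicsEstimator",
           "membership", "basis_vector", "estimate_f1", "estimate_F2",
           "update_weights"]

#: default membership-function centres (mV) and width (mV), identical for all
#: ten input dimensions; chosen to cover the operating range of TH potentials.
DEFAULT_CENTERS = (-49.59, -25.36)
DEFAULT_WIDTH = 5.0


def membership(x, center, width):
    """Gaussian membership degree exp(-((x - c)/delta)^2 / 2), in (0, 1]."""
    if np.any(np.asarray(width) <= 0):
        raise ConfigurationError("membership width must be > 0")
    z = (np.asarray(x, dtype=float) - center) / width
    return np.exp(-0.5 * z * z)


@dataclass
class MembershipGrid:
    """Gaussian membership functions per input dimension.

    ``centers`` has shape (n_mf, n_inputs) and ``widths`` broadcasts to it.
    """

    n_inputs: int = 10
    centers: np.ndarray = None
    widths: np.ndarray = None
    rule_base: str = "additive"  # or "product"

    def __post_init__(self):
        if self.centers is None:
            self.centers = np.tile(np.asarray(DEFAULT_CENTERS)[:, None],
                                   (1, self.n_inputs))
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.widths is None:
            self.widths = np.full_like(self.centers, DEFAULT_WIDTH)
        self.widths = np.broadcast_to(
            np.asarray(self.widths, dtype=float), self.centers.shape).copy()
        if self.centers.shape[1] != self.n_inputs:
            raise ConfigurationError(
                f"centers have {self.centers.shape[1]} columns for "
                f"{self.n_inputs} inputs")
        if np.any(self.widths <= 0):
            raise ConfigurationError("membership widths must be > 0")
        if self.rule_base not in ("additive", "product"):
            raise ConfigurationError(f"unknown rule base {self.rule_base!r}")

    @property
    def n_mf(self) -> int:
        return self.centers.shape[0]

    @property
    def n_rules(self) -> int:
        if self.rule_base == "additive":
            return self.n_mf * self.n_inputs
        return self.n_mf ** self.n_inputs

    def basis(self, x: np.ndarray) -> np.ndarray:
        """Normalized rule-activation vector(s); rows sum to one.

        ``x`` is (batch, n_inputs) or (n_inputs,); returns (batch, n_rules)
        or (n_rules,) accordingly.
        """
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        xb = np.atleast_2d(x)
        mu = np.exp(-0.5 * ((xb[:, None, :] - self.centers[None]) /
                            self.widths[None]) ** 2)  # (B, n_mf, n_in)
        if self.rule_base == "additive":
            # dimension-major layout: [mf1..mfK of x1, mf1..mfK of x2, ...]
            phi = mu.transpose(0, 2, 1).reshape(xb.shape[0], -1)
        else:
            phi = mu[:, :, 0]
            for j in range(1, self.n_inputs):
                phi = (phi[:, :, None] * mu[:, None, :, j]).reshape(
                    xb.shape[0], -1)
        tot = phi.sum(axis=1, keepdims=True)
        bad = (tot == 0.0) | ~np.isfinite(tot)
        if np.any(bad):
            log.warning("all rule firing strengths underflowed for %d input(s); "
                        "falling back to a uniform basis", int(bad.sum()))
            phi = np.where(bad, 1.0, phi)
            tot = phi.sum(axis=1, keepdims=True)
        phi = phi / tot
        return phi[0] if squeeze else phi


class FuzzyEstimator:
    """FLS with online weight adaptation, batched over independent trials.

    Weights: ``psi_f1`` (batch, n_rules, m) and ``psi_f2`` (batch, n_rules,
    m, m), initialized uniformly in [0, 1].  Adaptation follows the gradient
    laws d(psi_f1)[:, i] = -kappa_f1 * basis * s_i * eta*sigma*|e_i|^(eta-1)
    (and the same driven additionally by u_eq_j for psi_f2), projected onto
    the box |psi| <= psi_max so the weights stay finite.
    """

    def __init__(self, grid: Optional[MembershipGrid] = None, m: int = 10,
                 kappa_f1: float = 1.0, kappa_f2: float = 1.0,
                 psi_max: float = 1e3):
        self.grid = grid if grid is not None else MembershipGrid(n_inputs=m)
        if self.grid.n_inputs != m:
            raise ConfigurationError("grid dimension does not match m")
        if kappa_f1 < 0 or kappa_f2 < 0:
            raise ConfigurationError("adaptation gains must be >= 0")
        self.m = m
        self.kappa_f1 = kappa_f1
        self.kappa_f2 = kappa_f2
        self.psi_max = psi_max
        self.psi_f1: Optional[np.ndarray] = None
        self.psi_f2: Optional[np.ndarray] = None

    def reset(self, batch: int, rng: np.random.Generator) -> None:
        r = self.grid.n_rules
        self.psi_f1 = rng.uniform(0.0, 1.0, size=(batch, r, self.m))
        self.psi_f2 = rng.uniform(0.0, 1.0, size=(batch, r, self.m, self.m))

    def basis(self, x: np.ndarray) -> np.ndarray:
        return self.grid.basis(x)

    def estimate(self, x: np.ndarray, xi: Optional[np.ndarray] = None):
        """Return (basis, f1_hat (B, m), F2_hat (B, m, m)) at state ``x``."""
        if xi is None:
            xi = self.grid.basis(np.atleast_2d(x))
        f1 = np.einsum("br,brm->bm", xi, self.psi_f1)
        f2 = np.einsum("br,brmn->bmn", xi, self.psi_f2)
        return xi, f1, f2

    def adapt(self, xi: np.ndarray, drive: np.ndarray, u_eq: np.ndarray,
              dt: float) -> None:
        """One explicit-Euler step of the adaptation laws.

        ``drive`` is the sliding variable weighted by the surface Jacobian,
        s * eta*sigma*|e|^(eta-1), shape (B, m).
        """
        if self.kappa_f1 != 0.0:
            self.psi_f1 -= (dt * self.kappa_f1) * \
                np.einsum("br,bm->brm", xi, drive)
            np.clip(self.psi_f1, -self.psi_max, self.psi_max, out=self.psi_f1)
        if self.kappa_f2 != 0.0:
            self.psi_f2 -= (dt * self.kappa_f2) * \
                np.einsum("br,bm,bn->brmn", xi, drive, u_eq)
            np.clip(self.psi_f2, -self.psi_max, self.psi_max, out=self.psi_f2)
        if not (np.all(np.isfinite(self.psi_f1)) and
                np.all(np.isfinite(self.psi_f2))):
            raise FloatingPointError("non-finite fuzzy weights after adaptation")


class KnownDynamicsEstimator:
    """Drop-in estimator that returns known dynamics (f1, F2); used to
    exercise the controller on plants with known models (oracle mode)."""

    def __init__(self, f1_fn, f2_fn, m: int):
        self.f1_fn, self.f2_fn, self.m = f1_fn, f2_fn, m

    def reset(self, batch, rng):
        pass

    def estimate(self, x, xi=None):
        xb = np.atleast_2d(x)
        return None, np.atleast_2d(self.f1_fn(xb)), self.f2_fn(xb)

    def adapt(self, xi, drive, u_eq, dt):
        pass


# ---------------------------------------------------------------------------
# functional wrappers over single (unbatched) inputs

def basis_vector(x: np.ndarray, grid: MembershipGrid) -> np.ndarray:
    """Normalized rule activations for one input vector (sums to one)."""
    return grid.basis(np.asarray(x, dtype=float))


def estimate_f1(x, weights: np.ndarray, grid: MembershipGrid) -> np.ndarray:
    """Centre-average output: weights (n_rules, m) applied to the basis."""
    return basis_vector(x, grid) @ weights


def estimate_F2(x, weights: np.ndarray, grid: MembershipGrid) -> np.ndarray:
    """Matrix-valued output: weights (n_rules, m, m) applied to the basis."""
    return np.einsum("r,rmn->mn", basis_vector(x, grid), weights)


def update_weights(weights: np.ndarray, s: np.ndarray, jac: np.ndarray,
                   basis: np.ndarray, kappa: float, dt: float,
                   u_eq: Optional[np.ndarray] = None,
                   psi_max: float = 1e3) -> np.ndarray:
    """One adaptation step for an unbatched weight array (rules, m) or
    (rules, m, m); returns the updated copy."""
    drive = np.asarray(s) * np.asarray(jac)
    if weights.ndim == 2:
        delta = -kappa * dt * np.einsum("r,m->rm", basis, drive)
    else:
        delta = -kappa * dt * np.einsum("r,m,n->rmn", basis, drive, u_eq)
    return np.clip(weights + delta, -psi_max, psi_max)
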