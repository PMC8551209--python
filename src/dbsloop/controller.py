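"""MIMO terminal sliding-mode DBS controller.

The tracking error e = x_d - x between the healthy reference and the
Parkinsonian thalamic potentials is driven to zero in finite time through an
integral fractional-power sliding surface

    s_i = int_0^t e_i dt + sigma * sig(e_i)^eta,      1 < eta < 2,

a fast two-power reaching law ds/dt = -K1 sig(s)^rho1 - K2 sig(s)^rho2, a
regularized fuzzy equivalent control, and a corrective term with an adaptive
denominator parameter Upsilon.  Setting eta = 1, rho1 = 1 and rho2 = 0
(sig(s)^0 := sign(s)) recovers the classical adaptive fuzzy sliding-mode
baseline, whose discontinuous switching is the source of chattering.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import hyp2f1

from .fuzzy import FuzzyEstimator
from .params import ConfigurationError

__all__ = [
    "ControllerConfig", "SlidingModeController", "sig_pow", "sliding_surface",
    "reaching_rhs", "equivalent_control", "u_zero", "corrective_control",
    "upsilon_step", "sliding_settling_time", "reaching_time_bound",
]


def sig_pow(v, p):
    """Elementwise |v|^p * sign(v); continuous at 0 for p > 0, and
    sig(v)^0 = sign(v) (the classical switching limit)."""
    v = np.asarray(v, dtype=float)
    return np.abs(v) ** p * np.sign(v)


@dataclass
class ControllerConfig:
    """Gains and design parameters of the sliding-mode controller.

    The defaults are the repository's frozen tuned gain set (see the `tune`
    command for the search harness); the structural ranges of the design
    (eta, rho1, rho2 intervals, positivity) are validated at construction.
    """

    mode: str = "aftsmc"          # "aftsmc" | "afsmc"
    sigma: float = 0.1            # surface fractional-power weight
    eta: float = 1.2              # surface exponent, (1, 2)
    k1: float = 1.0               # reaching gain K1 = k1 * I
    k2: float = 1.5               # reaching gain K2 = k2 * I
    rho1: float = 1.2             # reaching exponent, (1, 3)
    rho2: float = 0.4             # reaching exponent, (0, 1)
    eps0: float = 1e-2            # inverse regularizer
    sigma0: float = 0.1           # lower bound on the input-gain matrix
    kappa0: float = 0.1           # Upsilon adaptation gain
    upsilon0: float = 1.0         # Upsilon initial value
    upsilon_min: float = 1e-6     # positivity clamp for Upsilon
    ebar_f1: float = 0.1          # approximation-error bound, f1 channel
    ebar_f2: float = 0.1          # approximation-error bound, F2 channel
    kappa_f1: float = 3.0         # fuzzy adaptation gain, f1 weights
    kappa_f2: float = 1.0         # fuzzy adaptation gain, F2 weights
    psi_max: float = 1e3          # fuzzy-weight projection box
    u_max: float = 200.0          # actuator saturation, uA/cm^2
    m: int = 10                   # number of controlled channels

    def __post_init__(self):
        if self.mode == "afsmc":
            # classical sliding-mode limit
            self.eta = 1.0
            self.rho1 = 1.0
            self.rho2 = 0.0
        elif self.mode != "aftsmc":
            raise ConfigurationError(f"unknown controller mode {self.mode!r}")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be > 0")
        if self.mode == "aftsmc" and not 1.0 < self.eta < 2.0:
            raise ConfigurationError(
                f"eta = {self.eta} outside the open interval (1, 2)")
        if self.mode == "aftsmc" and not 1.0 < self.rho1 < 3.0:
            raise ConfigurationError(
                f"rho1 = {self.rho1} outside the open interval (1, 3)")
        if self.mode == "aftsmc" and not 0.0 < self.rho2 < 1.0:
            raise ConfigurationError(
                f"rho2 = {self.rho2} outside the open interval (0, 1)")
        for name in ("k1", "k2", "eps0", "sigma0", "upsilon0"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("kappa0", "kappa_f1", "kappa_f2", "ebar_f1", "ebar_f2"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# elementary operations (batched over leading axes)

def sliding_surface(error_integral, e, sigma, eta):
    """s = int e dt + sigma * sig(e)^eta."""
    return error_integral + sigma * sig_pow(e, eta)


def reaching_rhs(s, k1, k2, rho1, rho2):
    """Fast reaching law ds/dt = -K1 sig(s)^rho1 - K2 sig(s)^rho2."""
    return -k1 * sig_pow(s, rho1) - k2 * sig_pow(s, rho2)


def _bracket(f1_hat, x_d_dot, e, s, cfg: ControllerConfig):
    """Common bracket of the equivalent control and u0."""
    return (-f1_hat + x_d_dot
            + (1.0 / (cfg.eta * cfg.sigma)) * sig_pow(e, 2.0 - cfg.eta)
            + cfg.k1 * sig_pow(s, cfg.rho1) + cfg.k2 * sig_pow(s, cfg.rho2))


def _reg_solve(F2_hat, eps0, rhs):
    """Solve (eps0 I + F2 F2^T) y = rhs for batched F2 (B, m, m)."""
    m = F2_hat.shape[-1]
    M = eps0 * np.eye(m) + F2_hat @ np.swapaxes(F2_hat, -1, -2)
    try:
        return np.linalg.solve(M, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise RuntimeError(f"regularized solve failed: {exc}") from exc


def equivalent_control(f1_hat, F2_hat, x_d_dot, e, s, cfg: ControllerConfig):
    """Regularized fuzzy equivalent control
    u_eq = F2^T (eps0 I + F2 F2^T)^-1 * bracket; always well defined."""
    f1_hat, e, s, x_d_dot = map(np.atleast_2d, (f1_hat, e, s, x_d_dot))
    F2 = np.asarray(F2_hat, dtype=float)
    if F2.ndim == 2:
        F2 = F2[None]
    y = _reg_solve(F2, cfg.eps0, _bracket(f1_hat, x_d_dot, e, s, cfg))
    return np.squeeze(np.einsum("bij,bi->bj", F2, y))


def u_zero(f1_hat, F2_hat, x_d_dot, e, s, cfg: ControllerConfig):
    """Residual term u0 = eps0 (eps0 I + F2 F2^T)^-1 * bracket."""
    f1_hat, e, s, x_d_dot = map(np.atleast_2d, (f1_hat, e, s, x_d_dot))
    F2 = np.asarray(F2_hat, dtype=float)
    if F2.ndim == 2:
        F2 = F2[None]
    y = _reg_solve(F2, cfg.eps0, _bracket(f1_hat, x_d_dot, e, s, cfg))
    return np.squeeze(cfg.eps0 * y)


def _error_bound(u_eq, u0, cfg: ControllerConfig):
    return cfg.ebar_f1 + cfg.ebar_f2 * np.abs(u_eq) + np.abs(u0)


def corrective_control(s, u_eq, u0, upsilon, cfg: ControllerConfig):
    """u_c = s |s^T| (ebar_f1 + ebar_f2 |u_eq| + |u0|) / (sigma0 ||s||^2 + Y).

    The outer product s |s^T| applied to the bound vector gives
    u_c_i = s_i * sum_j |s_j| b_j / (sigma0 ||s||^2 + Y)."""
    s, u_eq, u0 = map(np.atleast_2d, (s, u_eq, u0))
    b = _error_bound(u_eq, u0, cfg)
    den = cfg.sigma0 * np.sum(s * s, axis=-1) + upsilon
    return np.squeeze(s * (np.sum(np.abs(s) * b, axis=-1) / den)[..., None])


def upsilon_step(upsilon, s, jac, u_eq, u0, cfg: ControllerConfig, dt):
    """Explicit-Euler step of
    dY/dt = -kappa0 |s^T| diag(jac) (ebar_f1 + ebar_f2|u_eq| + |u0|) /
    (sigma0 ||s||^2 + Y), clamped to stay above upsilon_min; jac is the
    surface Jacobian factor eta*sigma*|e|^(eta-1)."""
    s, jac, u_eq, u0 = map(np.atleast_2d, (s, jac, u_eq, u0))
    b = _error_bound(u_eq, u0, cfg)
    den = cfg.sigma0 * np.sum(s * s, axis=-1) + upsilon
    dups = -cfg.kappa0 * np.sum(np.abs(s) * jac * b, axis=-1) / den
    out = np.maximum(upsilon + dt * dups, cfg.upsilon_min)
    return out.item() if out.size == 1 else out


def sliding_settling_time(sigma, eta, x_at_reach):
    """Time to slide from |x| at surface arrival to the origin:
    t = sigma / (1 - 1/eta) * |x|^(eta - 1); defined for eta > 1."""
    if eta <= 1.0:
        raise ValueError("the sliding settling time requires eta > 1")
    return sigma / (1.0 - 1.0 / eta) * np.abs(x_at_reach) ** (eta - 1.0)


def reaching_time_bound(v0, alpha1, alpha2, lam1, lam2):
    """Settling-time bound for dV/dt <= -alpha1 V^lam1 - alpha2 V^lam2,
    evaluated through Gauss's hypergeometric function.

    With k = lam1 - lam2 and a = (1 - lam2)/k,

        t_s <= V0^(1 - lam2) / (k a alpha2)
               * 2F1(1, a; a + 1; -(alpha1/alpha2) V0^k),

    which is exact for the equality case (it equals
    int_0^V0 dV / (alpha1 V^lam1 + alpha2 V^lam2)).  In the alpha1 -> 0
    limit 2F1(...; 0) = 1 and the bound reduces to the classical
    terminal-mode settling time V0^(1-lam2) / (alpha2 (1 - lam2)).
    Requires alpha1, alpha2 > 0, lam1 > 1 and 0 < lam2 < 1.
    """
    if alpha1 <= 0 or alpha2 <= 0:
        raise ValueError("alpha1 and alpha2 must be > 0")
    if lam1 <= 1.0 or not 0.0 < lam2 < 1.0:
        raise ValueError("require lam1 > 1 and 0 < lam2 < 1")
    v0 = np.asarray(v0, dtype=float)
    k = lam1 - lam2
    a = (1.0 - lam2) / k
    z = -(alpha1 / alpha2) * v0 ** k
    return v0 ** (1.0 - lam2) / (k * a * alpha2) * hyp2f1(1.0, a, a + 1.0, z)


# ---------------------------------------------------------------------------
# the closed-loop controller

@dataclass
class ControllerState:
    """Evolving controller memory for a batch of trials."""

    error_integral: np.ndarray   # (B, m), mV*ms
    upsilon: np.ndarray          # (B,), > 0
    s: np.ndarray                # (B, m), last sliding vector
    u: np.ndarray                # (B, m), last control, uA/cm^2
    pred: Optional[np.ndarray] = None   # (B, m), optional drift prediction
    u_eq: Optional[np.ndarray] = None   # (B, m), optional equivalent control


class SlidingModeController:
    """Stateful MIMO controller; one ``step`` per plant step (shared dt).

    ``estimator`` supplies (f1_hat, F2_hat); by default an online-adapted
    :class:`~dbsloop.fuzzy.FuzzyEstimator`, or any object with the same
    ``reset``/``estimate``/``adapt`` surface (e.g. known dynamics for
    oracle-mode tests).
    """

    def __init__(self, config: Optional[ControllerConfig] = None,
                 estimator=None):
        self.cfg = config if config is not None else ControllerConfig()
        if estimator is None:
            estimator = FuzzyEstimator(
                m=self.cfg.m, kappa_f1=self.cfg.kappa_f1,
                kappa_f2=self.cfg.kappa_f2, psi_max=self.cfg.psi_max)
        self.estimator = estimator
        self.state: Optional[ControllerState] = None
        #: when set, ``state.pred`` holds the model prediction
        #: f1_hat + F2_hat u of the plant drift after every step
        self.log_internals = False

    def reset(self, batch: int, rng: np.random.Generator) -> None:
        m = self.cfg.m
        self.estimator.reset(batch, rng)
        self.state = ControllerState(
            error_integral=np.zeros((batch, m)),
            upsilon=np.full(batch, self.cfg.upsilon0),
            s=np.zeros((batch, m)),
            u=np.zeros((batch, m)))

    def step(self, x: np.ndarray, x_d: np.ndarray, x_d_dot: np.ndarray,
             dt: float) -> np.ndarray:
        """Advance the controller one step and return u (B, m), uA/cm^2."""
        cfg, st = self.cfg, self.state
        e = x_d - x
        st.error_integral += e * dt
        if cfg.eta == 1.0:
            s = st.error_integral + cfg.sigma * e
            jac = np.full_like(e, cfg.sigma)
        else:
            s = st.error_integral + cfg.sigma * sig_pow(e, cfg.eta)
            jac = cfg.eta * cfg.sigma * np.abs(e) ** (cfg.eta - 1.0)
        xi, f1_hat, F2_hat = self.estimator.estimate(x)
        bracket = _bracket(f1_hat, x_d_dot, e, s, cfg)
        y = _reg_solve(F2_hat, cfg.eps0, bracket)
        u_eq = np.einsum("bij,bi->bj", F2_hat, y)
        u0 = cfg.eps0 * y
        b = _error_bound(u_eq, u0, cfg)
        den = cfg.sigma0 * np.sum(s * s, axis=-1) + st.upsilon
        u_c = s * (np.sum(np.abs(s) * b, axis=-1) / den)[:, None]
        dups = -cfg.kappa0 * np.sum(np.abs(s) * jac * b, axis=-1) / den
        st.upsilon = np.maximum(st.upsilon + dt * dups, cfg.upsilon_min)
        self.estimator.adapt(xi, s * jac, u_eq, dt)
        st.s = s
        st.u = np.clip(u_eq + u_c, -cfg.u_max, cfg.u_max)
        if self.log_internals:
            st.pred = f1_hat + np.einsum("bij,bj->bi", F2_hat, st.u)
            st.u_eq = u_eq
        return st.u
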