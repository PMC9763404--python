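"""Parameters, activation function, mean-field fixed point and critical condition.

The model describes ``n_E`` excitatory and ``n_I`` inhibitory two-state
(quiescent/active) neurons on each site of a periodic L x L lattice.  Active
neurons deactivate at rate ``alpha_rate``; quiescent neurons activate at a
rate ``f(s)`` set by their synaptic input ``s``.  The summed incoming
coupling per neuron is ``w00`` (excitation minus inhibition) and ``ws0``
(excitation plus inhibition), identical for every neuron, which makes the
system translationally invariant: the homogeneous stationary active fraction
``Sigma0`` obeys

    alpha * Sigma0 = (1 - Sigma0) * f(w00 * Sigma0 + h)

and the transcritical critical point sits at ``h = 0``,
``w00 = alpha_rate / beta_gain``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "FixedPoint",
    "activation",
    "activation_deriv",
    "solve_fixed_point",
    "critical_coupling",
]


@dataclass
class ModelParams:
    """All scalar parameters of the model and of the simulation protocol.

    Rates are in ms^-1, times in ms, distances in lattice spacings.  Exactly
    one of ``lam`` (exponential connection range) and ``omega`` (power-law
    kernel exponent) must be set; ``lam = inf`` (or ``L = 1``) selects the
    fully-connected topology.
    """

    alpha_rate: float = 0.1   # deactivation rate (ms^-1)
    beta_gain: float = 1.0    # activation gain (ms^-1); not the PSD exponent
    h: float = 1e-8           # external input (dimensionless, >= 0)
    w00: float = 0.1          # summed signed incoming coupling
    ws0: float = 13.8         # summed absolute incoming coupling
    nE: float = 1e8           # excitatory neurons per site
    nI: float = 1e8           # inhibitory neurons per site
    L: int = 1                # lattice side; L=1 is the fully-connected model
    lam: float | None = math.inf   # connection range lambda (spacings)
    omega: float | None = None     # power-law kernel exponent (exclusive with lam)
    cutoff_factor: float = 3.0     # kernel truncation radius in units of lam
    dt: float = 0.01          # integration step (ms)
    delta_bin: float = 1.0    # spike/avalanche bin width delta (ms)
    t_total: float = 1e6      # run length (ms)
    t_discard: float = 1e5    # transient discarded at the start (ms)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha_rate > 0 and self.beta_gain > 0):
            raise ValueError("alpha_rate and beta_gain must be positive")
        if self.h < 0:
            raise ValueError("external input h must be >= 0")
        if self.ws0 < abs(self.w00):
            raise ValueError("ws0 must be >= |w00|")
        if self.nE < 1 or self.nI < 1:
            raise ValueError("nE and nI must be >= 1")
        if self.L < 1:
            raise ValueError("L must be a positive integer")
        if self.dt <= 0 or self.delta_bin <= 0:
            raise ValueError("dt and delta_bin must be positive")
        if not (0 <= self.t_discard < self.t_total):
            raise ValueError("need 0 <= t_discard < t_total")
        if (self.lam is None) == (self.omega is None):
            raise ValueError("exactly one of lam / omega must be set")
        if self.lam is not None and self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.omega is not None and self.omega < 0:
            raise ValueError("omega must be >= 0")

    # -- flat key=value config round-trip ---------------------------------
    def to_config(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            lines.append(f.name + "=" + ("" if v is None else repr(v)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "ModelParams":
        kwargs = {}
        casts = {f.name: f for f in fields(cls)}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in casts:
                raise KeyError(f"unknown parameter {key!r}")
            if val in ("", "None"):
                kwargs[key] = None
            elif key in ("L", "seed"):
                kwargs[key] = int(float(val))
            else:
                kwargs[key] = float(val)
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "ModelParams":
        if ("lam" in kwargs) != ("omega" in kwargs):
            # switching kernel form: clear the other field
            if "lam" in kwargs and kwargs["lam"] is not None:
                kwargs.setdefault("omega", None)
            if "omega" in kwargs and kwargs["omega"] is not None:
                kwargs.setdefault("lam", None)
        return replace(self, **kwargs)

    @property
    def fully_connected(self) -> bool:
        return self.L == 1 or (self.lam is not None and math.isinf(self.lam))


@dataclass(frozen=True)
class FixedPoint:
    """Homogeneous stationary state of the mean-field dynamics."""

    sigma0: float          # stationary active fraction Sigma0 in [0, 1)
    s0: float              # stationary input w00*Sigma0 + h
    tau2_inv: float        # fast relaxation rate alpha + f(s0) (ms^-1)


def activation(s, beta_gain: float = 1.0):
    """Input-dependent activation rate f(s) = beta_gain*tanh(s) for s>0, else 0.

    Bounded in [0, beta_gain), continuous at 0 and monotone nondecreasing.
    Accepts scalars or arrays.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("activation input must be finite")
    out = np.where(s > 0, beta_gain * np.tanh(np.clip(s, 0.0, None)), 0.0)
    return out if out.ndim else float(out)


def activation_deriv(s, beta_gain: float = 1.0):
    """Analytic derivative f'(s) = beta_gain*(1 - tanh^2 s) for s>0.

    At s = 0 the right derivative beta_gain is returned, which is the branch
    entering the criticality condition alpha = beta_gain * w00.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("activation input must be finite")
    out = np.where(s >= 0, beta_gain * (1.0 - np.tanh(np.clip(s, 0.0, None)) ** 2), 0.0)
    return out if out.ndim else float(out)


def critical_coupling(params: ModelParams) -> float:
    """Coupling w00 at which the k=0 relaxation rate vanishes as h -> 0."""
    return params.alpha_rate / params.beta_gain


def _residual(sigma: float, params: ModelParams) -> float:
    s = params.w00 * sigma + params.h
    return params.alpha_rate * sigma - (1.0 - sigma) * activation(s, params.beta_gain)


def solve_fixed_point(params: ModelParams, tol: float = 1e-14,
                      max_iter: int = 200) -> FixedPoint:
    """Attractive fixed point of alpha*Sigma = (1-Sigma)*f(w00*Sigma + h).

    Returns the largest root in [0, 1).  For h = 0 the quiescent state
    Sigma0 = 0 is returned below the critical coupling; above it, the unique
    positive root is bracketed on a geometric grid and refined by Brent's
    method (bracketed bisection/inverse-quadratic steps).
    """
    a, b, w0, h = params.alpha_rate, params.beta_gain, params.w00, params.h
    sigma = None
    if h == 0.0 and w0 * b <= a:
        sigma = 0.0
    elif h == 0.0:
        # supercritical: residual < 0 just above 0, > 0 at 1
        lo = None
        for x in np.geomspace(1e-16, 0.5, 60):
            if _residual(x, params) < 0:
                lo = x
                break
        if lo is None:
            sigma = 0.0
        else:
            sigma = brentq(_residual, lo, 1.0, args=(params,), xtol=tol,
                           rtol=8.9e-16, maxiter=max_iter)
    else:
        # h > 0: residual(0) = -f(h) < 0 (or 0), residual(1) = alpha > 0
        if _residual(0.0, params) >= 0.0:
            sigma = 0.0
        else:
            sigma = brentq(_residual, 0.0, 1.0, args=(params,), xtol=tol,
                           rtol=8.9e-16, maxiter=max_iter)
    res = _residual(sigma, params)
    if abs(res) > 1e-12:
        raise RuntimeError(
            f"fixed-point solver residual {res:.3e} at Sigma0={sigma:.6e}")
    s0 = w0 * sigma + h
    return FixedPoint(sigma0=float(sigma), s0=float(s0),
                      tau2_inv=a + activation(s0, b))
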