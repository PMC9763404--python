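"""Translation-invariant synaptic kernel on the periodic lattice.

Per-neuron weights of the model aggregate, site by site, into a per-site
kernel acting on the active fractions: every site receives from displacement
``Delta`` an excitatory weight ``(w00+ws0)/2 * g(r)/K`` and an inhibitory
(negative) weight ``(w00-ws0)/2 * g(r)/K``, where ``g`` is the radial factor
(``exp(-r/lambda)``, ``min(1, r^-omega)`` or 1) and ``K = sum_Delta g`` the
normalization; distances are minimum-image Euclidean on the L x L torus.
By construction the signed weights sum to ``w00`` and the absolute ones to
``ws0``, the two anchors that fix the sign convention everywhere else.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from .model_core import FixedPoint, ModelParams, activation_deriv

__all__ = [
    "ConnectivityKernel",
    "KernelFourier",
    "DiffusionConstant",
    "build_kernel",
    "kernel_fourier",
    "continuum_D0",
    "min_image_distances",
    "kernel_to_csv",
]


@dataclass(frozen=True)
class ConnectivityKernel:
    """Per-displacement site-aggregated weights and their normalizations."""

    L: int
    g: np.ndarray          # (L, L) radial factor per displacement, truncated
    wE: np.ndarray         # (L, L) excitatory weight per displacement (>= 0)
    wI: np.ndarray         # (L, L) inhibitory weight per displacement (<= 0)
    normE: float           # N_E = nE * sum(g)
    normI: float           # N_I = nI * sum(g)
    kernel_form: str       # 'exponential' | 'powerlaw' | 'fully_connected'

    @property
    def signed(self) -> np.ndarray:
        return self.wE + self.wI

    @property
    def absolute(self) -> np.ndarray:
        return self.wE - self.wI


@dataclass(frozen=True)
class KernelFourier:
    """Real cosine transforms of the kernel on the L^2 wave-vector grid."""

    L: int
    k_sq: np.ndarray       # (L, L) |k|^2 with minimum-image components
    w0_k: np.ndarray       # (L, L) transform of the signed kernel
    ws_k: np.ndarray       # (L, L) transform of the absolute kernel


@dataclass(frozen=True)
class DiffusionConstant:
    """Continuum small-k diffusion constant and the 1/f frequency band."""

    D0: float              # ms^-1 * spacing^2
    f_min: float           # L^-2 D0 (ms^-1)
    f_max: float           # lambda^-2 D0 (ms^-1)


def min_image_distances(L: int) -> np.ndarray:
    """Euclidean minimum-image distance of every displacement on the torus."""
    d = np.arange(L)
    d = np.minimum(d, L - d)
    return np.hypot(d[:, None], d[None, :])


def build_kernel(params: ModelParams) -> ConnectivityKernel:
    """Build the per-site aggregated kernel for the configured topology."""
    L = params.L
    r = min_image_distances(L)
    if params.omega is not None:
        if L == 1:
            raise ValueError("power-law kernel requires a lattice (L > 1)")
        form = "powerlaw"
        with np.errstate(divide="ignore"):
            g = np.where(r > 0, np.minimum(1.0, r ** -params.omega), 1.0)
    elif math.isinf(params.lam) or L == 1:
        form = "fully_connected"
        g = np.ones((L, L))
    else:
        form = "exponential"
        cutoff = params.cutoff_factor * params.lam
        if cutoff >= L / 2:
            warnings.warn(
                f"cutoff radius {cutoff:g} >= L/2={L / 2:g}: truncation "
                "interacts with periodic images", stacklevel=2)
        g = np.exp(-r / params.lam)
        g[r > cutoff] = 0.0
    K = g.sum()
    wE = 0.5 * (params.w00 + params.ws0) * g / K
    wI = 0.5 * (params.w00 - params.ws0) * g / K
    return ConnectivityKernel(L=L, g=g, wE=wE, wI=wI,
                              normE=params.nE * K, normI=params.nI * K,
                              kernel_form=form)


def kernel_fourier(kernel: ConnectivityKernel) -> KernelFourier:
    """Cosine transforms w0_k, ws_k of the signed/absolute kernel.

    The kernel is symmetric under displacement negation, so the DFT is real;
    the k=0 entries reproduce w00 and ws0 exactly.
    """
    L = kernel.L
    w0 = np.fft.fft2(kernel.signed)
    ws = np.fft.fft2(kernel.absolute)
    if max(np.abs(w0.imag).max(), np.abs(ws.imag).max()) > 1e-10:
        raise AssertionError("kernel transform is not real: asymmetric kernel")
    idx = np.arange(L)
    k1 = (2.0 * np.pi / L) * np.minimum(idx, L - idx)
    k_sq = k1[:, None] ** 2 + k1[None, :] ** 2
    return KernelFourier(L=L, k_sq=k_sq, w0_k=w0.real.copy(), ws_k=ws.real.copy())


def _radial_moments(params: ModelParams, d: int) -> tuple[float, float]:
    """(integral r^{d+1} g dr, integral r^{d-1} g dr) for the untruncated kernel."""
    if params.omega is not None:
        om = params.omega
        if om <= d + 2:
            raise ValueError(
                f"power-law kernel with omega={om:g} <= d+2={d + 2}: second "
                "moment diverges")
        m2 = 1.0 / (d + 2) + 1.0 / (om - d - 2)
        m0 = 1.0 / d + 1.0 / (om - d)
        return m2, m0
    lam = params.lam
    if math.isinf(lam):
        raise ValueError("continuum D0 undefined for the fully-connected kernel")
    # exponential kernel: closed forms Gamma(d+2) lam^{d+2}, Gamma(d) lam^d,
    # evaluated by adaptive quadrature and checked against the closed form
    m2, err2 = quad(lambda x: x ** (d + 1) * math.exp(-x / lam), 0, np.inf)
    m0, err0 = quad(lambda x: x ** (d - 1) * math.exp(-x / lam), 0, np.inf)
    if err2 > 1e-8 * abs(m2) or err0 > 1e-8 * abs(m0):
        raise RuntimeError("quadrature for D0 did not reach 1e-8 relative")
    return m2, m0


def continuum_D0(params: ModelParams, fp: FixedPoint, d: int = 2) -> DiffusionConstant:
    """Small-k diffusion constant D0 with tau1_k^-1 ~ D0 |k|^2 at criticality.

    Uses the untruncated continuum kernel: the signed per-unit-volume weight
    density is w00 * g(r) / integral(g d^d r), and

        D0 = pi^{d/2} (1-Sigma0) f'(s0) / (2 Gamma(1+d/2))
             * integral_0^inf r^{d+1} w(r) dr .

    Also exposes the 1/f band edges f_min = L^-2 D0 and f_max = lambda^-2 D0.
    """
    if d < 1:
        raise ValueError("dimension d must be >= 1")
    m2, m0 = _radial_moments(params, d)
    # N_cont = S_d * m0 with S_d = 2 pi^{d/2} / Gamma(d/2)
    n_cont = 2.0 * math.pi ** (d / 2) / gamma_fn(d / 2) * m0
    w_density_moment = params.w00 * m2 / n_cont
    pref = math.pi ** (d / 2) / (2.0 * gamma_fn(1 + d / 2))
    slope = activation_deriv(fp.s0, params.beta_gain)
    D0 = pref * (1.0 - fp.sigma0) * slope * w_density_moment
    scale = params.lam if params.lam is not None else 1.0
    return DiffusionConstant(D0=D0, f_min=D0 / params.L ** 2,
                             f_max=D0 / scale ** 2)


def kernel_to_csv(kernel: ConnectivityKernel, path) -> None:
    """Write (offset_x, offset_y, wE, wI) rows in lexicographic offset order."""
    L = kernel.L
    with open(path, "w") as fh:
        fh.write("offset_x,offset_y,wE,wI\n")
        for ix in range(L):
            for iy in range(L):
                fh.write(f"{ix},{iy},{kernel.wE[ix, iy]!r},{kernel.wI[ix, iy]!r}\n")
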