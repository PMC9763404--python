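"""Large-N linear theory: per-mode relaxation times, autocorrelation, spectra.

After a system-size expansion about the homogeneous fixed point, the
fluctuation fields decouple in Fourier space: each wave vector k carries an
independent two-variable Ornstein-Uhlenbeck process with a slow time
``tau1_k`` (diverging at criticality as ``tau1_k^-1 ~ D0 |k|^2``), a fast
k-independent time ``tau2``, a feed-forward coupling ``wff_k`` and noise
intensity ``alpha * Sigma0``.  The single-site autocorrelation is the L^-2
mode sum of ``A1_k exp(-t/tau1_k) + A2_k exp(-t/tau2)`` and the power
spectrum its cosine transform, a sum of Lorentzian pairs.  In d dimensions
the mode density turns the pair sum into ``P(f) ~ f^{(d-4)/2}`` between
``f_min = L^-2 D0`` and ``f_max = lambda^-2 D0`` -- pink noise in d = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .connectivity import KernelFourier
from .model_core import FixedPoint, ModelParams, activation, activation_deriv

__all__ = [
    "ModeSpectrum",
    "SpectrumCurve",
    "AsymptoticExponent",
    "mode_spectrum",
    "analytic_autocorrelation",
    "analytic_power_spectrum",
    "lorentzian_pair_spectrum",
    "asymptotic_exponent",
    "band_integral_spectrum",
]

# relative tau1/tau2 separation below which amplitudes are evaluated at a
# nudged tau1 (the A1/A2 split is singular at tau1=tau2; their sum is not)
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class ModeSpectrum:
    """Per-wave-vector linear-theory quantities (arrays of length L^2)."""

    L: int
    k_sq: np.ndarray
    tau1_k: np.ndarray     # slow relaxation time (ms)
    tau2: float            # fast relaxation time 1/(alpha + f(s0)) (ms)
    wff_k: np.ndarray      # feed-forward coupling (ms^-1)
    A1_k: np.ndarray
    A2_k: np.ndarray
    noise: float           # noise intensity alpha * Sigma0 (ms^-1)


@dataclass(frozen=True)
class SpectrumCurve:
    """P(f) on a frequency grid; ``unit`` records the frequency convention."""

    frequencies: np.ndarray
    values: np.ndarray
    f_min: float | None = None
    f_max: float | None = None
    unit: str = "ms^-1"


@dataclass(frozen=True)
class AsymptoticExponent:
    """Spectral exponent beta_psd with a flag for the logarithmic d=4 case."""

    beta: float
    log_decay: bool = False


def _amplitudes(noise, tau1, tau2, wff):
    t1 = np.where(np.abs(tau1 - tau2) < _DEGENERATE_RTOL * tau2,
                  tau2 * (1.0 + 1e-6), tau1)
    denom = 2.0 * (t1 ** 2 - tau2 ** 2)
    A1 = noise * t1 ** 2 * tau2 ** 2 / denom * (t1 / tau2 ** 2 + t1 * wff ** 2 - 1.0 / t1)
    A2 = -noise * t1 ** 2 * tau2 ** 3 * wff ** 2 / denom
    return A1, A2


def mode_spectrum(params: ModelParams, fp: FixedPoint,
                  kf: KernelFourier) -> ModeSpectrum:
    """Relaxation times and autocorrelation amplitudes for every mode.

    tau1_k^-1 = alpha + f(s0) - (1-Sigma0) f'(s0) w0_k,
    tau2^-1   = alpha + f(s0),
    wff_k     = (1-Sigma0) f'(s0) ws_k,
    with noise intensity alpha*Sigma0 common to all modes.
    """
    a, bg = params.alpha_rate, params.beta_gain
    f0 = activation(fp.s0, bg)
    fp0 = activation_deriv(fp.s0, bg)
    gain = (1.0 - fp.sigma0) * fp0
    w0 = kf.w0_k.ravel()
    ws = kf.ws_k.ravel()
    tau1_inv = a + f0 - gain * w0
    if np.any(tau1_inv <= 0):
        bad = int(np.argmin(tau1_inv))
        raise ArithmeticError(
            f"fixed point linearly unstable at mode {bad}: "
            f"tau1_k^-1 = {tau1_inv[bad]:.3e} <= 0 (supercritical parameters)")
    tau2 = 1.0 / (a + f0)
    tau1 = 1.0 / tau1_inv
    wff = gain * ws
    noise = a * fp.sigma0
    A1, A2 = _amplitudes(noise, tau1, tau2, wff)
    return ModeSpectrum(L=kf.L, k_sq=kf.k_sq.ravel(), tau1_k=tau1, tau2=tau2,
                        wff_k=wff, A1_k=A1, A2_k=A2, noise=noise)


def analytic_autocorrelation(ms: ModeSpectrum, times,
                             normalize: bool = False) -> np.ndarray:
    """C(t) = L^-2 sum_k [A1_k e^{-t/tau1_k} + A2_k e^{-t/tau2}]."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be nonnegative")
    c = (np.exp(-t[:, None] / ms.tau1_k[None, :]) * ms.A1_k[None, :]).sum(axis=1)
    c += ms.A2_k.sum() * np.exp(-t / ms.tau2)
    c /= ms.L ** 2
    if normalize:
        c0 = (ms.A1_k.sum() + ms.A2_k.sum()) / ms.L ** 2
        c = c / c0
    return c


def analytic_power_spectrum(ms: ModeSpectrum, freqs) -> SpectrumCurve:
    """One-sided cosine-transform spectrum P(f), f in ms^-1.

    Evaluated through the per-mode Ornstein-Uhlenbeck transfer function

        P_k(f) = noise/2 * (1 + wff_k^2/(w^2 + tau2^-2)) / (w^2 + tau1_k^-2)

    with w = 2 pi f, which is algebraically identical to the Lorentzian pair
    ``A1 tau1/(1+4 pi^2 tau1^2 f^2) + A2 tau2/(1+4 pi^2 tau2^2 f^2)`` but
    stays finite where tau1_k crosses tau2.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency grid must be positive")
    w2 = (2.0 * math.pi * f) ** 2
    num = 1.0 + ms.wff_k[None, :] ** 2 / (w2[:, None] + 1.0 / ms.tau2 ** 2)
    den = w2[:, None] + 1.0 / ms.tau1_k[None, :] ** 2
    p = 0.5 * ms.noise * (num / den).sum(axis=1) / ms.L ** 2
    return SpectrumCurve(frequencies=f, values=p)


def analytic_rate_power_spectrum(params: ModelParams, ms: ModeSpectrum,
                                 freqs) -> SpectrumCurve:
    """Linear-theory spectrum of the single-site firing rate.

    The rate R = (1 - Sigma) f(s) mixes both fluctuation fields: to linear
    order delta R_k = u_k xi_Sigma_k + wff_k xi_Delta_k with
    u_k = alpha - tau1_k^-1 (the Sigma weight collapses to this because
    (1-Sigma0) f'(s0) w0_k = alpha + f(s0) - tau1_k^-1).  The spectrum is
    assembled from the exact per-mode transfer functions, including the
    Sigma-Delta cross term.  This is the observable plotted against the
    Welch estimate of simulated rate traces; its 1/f band matches the
    active-fraction spectrum, with cleaner knees at high frequency.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency grid must be positive")
    u = params.alpha_rate - 1.0 / ms.tau1_k
    p = np.empty_like(f)
    for i, wi in enumerate(2.0 * math.pi * f):
        hs = 1.0 / (1j * wi + 1.0 / ms.tau1_k)
        hd = 1.0 / (1j * wi + 1.0 / ms.tau2)
        p[i] = 0.5 * ms.noise * np.sum(
            np.abs(u * hs) ** 2
            + np.abs((u * ms.wff_k * hs + ms.wff_k) * hd) ** 2) / ms.L ** 2
    return SpectrumCurve(frequencies=f, values=p)


def lorentzian_pair_spectrum(ms: ModeSpectrum, freqs) -> np.ndarray:
    """Mode sum of Lorentzian pairs from the A1/A2 amplitudes (cross-check)."""
    f = np.asarray(freqs, dtype=float)
    p = (ms.A1_k[None, :] * ms.tau1_k[None, :]
         / (1.0 + 4.0 * math.pi ** 2 * ms.tau1_k[None, :] ** 2 * f[:, None] ** 2)
         ).sum(axis=1)
    p += (ms.A2_k.sum() * ms.tau2
          / (1.0 + 4.0 * math.pi ** 2 * ms.tau2 ** 2 * f ** 2))
    return p / ms.L ** 2


def asymptotic_exponent(d: int) -> AsymptoticExponent:
    """Critical spectral exponent: P(f) ~ f^-beta with beta = (4-d)/2 for d<4.

    In d = 4 the band integral develops a logarithmic divergence,
    P(f) ~ -log f; for d > 4 it cancels the prefactor and the spectrum is
    white (beta = 0).
    """
    if d < 1 or int(d) != d:
        raise ValueError("dimension must be a positive integer")
    if d < 4:
        return AsymptoticExponent(beta=(4 - d) / 2.0)
    if d == 4:
        return AsymptoticExponent(beta=0.0, log_decay=True)
    return AsymptoticExponent(beta=0.0)


def band_integral_spectrum(d: int, freqs, f_min: float,
                           f_max: float) -> SpectrumCurve:
    """Critical-band spectrum P(f) ∝ f^{(d-4)/2} * I(f) (up to a constant).

    I(f) is the band integral of x^{(2-d)/2}/(1+x^2) between f/f_max and
    f/f_min; for f_min << f << f_max and d < 4 it is flat in f, so the
    spectrum decays with the asymptotic exponent (4-d)/2.
    """
    f = np.asarray(freqs, dtype=float)
    vals = np.empty_like(f)
    expo = (4 - d) / 2.0
    for i, fi in enumerate(f):
        # substitute x = e^y: the integrand x^{(2-d)/2}/(1+x^2) dx becomes
        # x^{(4-d)/2}/(1+x^2) dy, smooth on the whole band
        integral, _ = quad(
            lambda y: math.exp(expo * y) / (1.0 + math.exp(2.0 * y)),
            math.log(fi / f_max), math.log(fi / f_min), limit=200)
        vals[i] = fi ** ((d - 4) / 2.0) * integral
    return SpectrumCurve(frequencies=f, values=vals, f_min=f_min, f_max=f_max)
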