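"""Langevin integration of the lattice dynamics with Poisson spike emission.

The per-site active fractions (x, y) of the excitatory and inhibitory
populations follow coupled Euler-Maruyama updates of

    dx/dt = -alpha x + (1-x) f(s) + nE^{-1/2} sqrt(alpha x + (1-x) f(s)) eta(t)

(and likewise for y), where the input s is the circular convolution of the
per-site kernel with the activity fields plus the external drive h.  Spikes
are a post-processing observable: per bin of width delta, the count is drawn
from a Poisson law whose mean is the temporal integral of the firing rate
R = (1 - (x+y)/2) f(s) times the number of neurons on the site.  The spike
draw never feeds back into the state.

The production path (:func:`run`) is compiled with numba; :func:`step` and
:func:`local_inputs` expose single-step numpy versions of the same update
for testing and small experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectivity import ConnectivityKernel, build_kernel
from .model_core import FixedPoint, ModelParams, activation, solve_fixed_point

__all__ = ["LatticeState", "SpikeTrace", "local_inputs", "step",
           "firing_rate", "run"]


@dataclass
class LatticeState:
    """Per-site active fractions of the two populations at time ``t``."""

    x: np.ndarray   # (L, L) excitatory active fraction
    y: np.ndarray   # (L, L) inhibitory active fraction
    t: float = 0.0


@dataclass
class SpikeTrace:
    """Binned spike counts and mean firing-rate traces of one run.

    ``counts[i, b]`` is the Poisson spike count of site ``i`` in bin ``b``;
    ``rates[i, b]`` the bin-averaged per-neuron firing rate (ms^-1).
    """

    counts: np.ndarray      # (n_sites, n_bins) integer
    rates: np.ndarray       # (n_sites, n_bins) float
    delta: float            # bin width (ms)
    params: ModelParams
    seed: int

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


def _max_dt(params: ModelParams) -> float:
    return 0.1 / (params.alpha_rate + params.beta_gain)


def local_inputs(state: LatticeState, kernel: ConnectivityKernel,
                 params: ModelParams, method: str = "fft") -> np.ndarray:
    """Per-site synaptic input s (identical for both populations).

    With presynaptic-only weights the excitatory and inhibitory inputs
    coincide: s_r = sum_Delta [wE(Delta) x_{r+Delta} + wI(Delta) y_{r+Delta}] + h,
    a circular convolution computed either spectrally (``fft``) or by a
    direct sum over the stored offsets (``direct``).
    """
    if state.x.shape != (kernel.L, kernel.L):
        raise ValueError("state and kernel lattice sizes differ")
    field = np.zeros_like(state.x)
    # summed per-displacement drive; kernel symmetric so conv == correlation
    contrib_x = kernel.wE
    contrib_y = kernel.wI
    if method == "fft":
        field = np.fft.ifft2(np.fft.fft2(state.x) * np.fft.fft2(contrib_x)
                             + np.fft.fft2(state.y) * np.fft.fft2(contrib_y)).real
    elif method == "direct":
        L = kernel.L
        for ix in range(L):
            for iy in range(L):
                wx, wy = contrib_x[ix, iy], contrib_y[ix, iy]
                if wx == 0.0 and wy == 0.0:
                    continue
                field += wx * np.roll(state.x, (-ix, -iy), axis=(0, 1))
                field += wy * np.roll(state.y, (-ix, -iy), axis=(0, 1))
    else:
        raise ValueError(f"unknown convolution method {method!r}")
    return field + params.h


def firing_rate(state: LatticeState, inputs: np.ndarray,
                params: ModelParams) -> np.ndarray:
    """Per-site firing rate R = (1 - (x+y)/2) f(s), in ms^-1 per neuron."""
    sigma = 0.5 * (state.x + state.y)
    return (1.0 - sigma) * activation(inputs, params.beta_gain)


def step(state: LatticeState, kernel: ConnectivityKernel, params: ModelParams,
         rng: np.random.Generator, method: str = "fft") -> LatticeState:
    """One Euler-Maruyama update (drift and diffusion at the pre-step state).

    The square-root argument is clamped at zero and the updated fractions
    clipped to [0, 1]; both regularizations vanish as nE, nI -> infinity.
    """
    if params.dt > _max_dt(params):
        raise ValueError(
            f"dt={params.dt:g} exceeds stability bound {_max_dt(params):g}")
    s = local_inputs(state, kernel, params, method=method)
    f = activation(s, params.beta_gain)
    a, dt = params.alpha_rate, params.dt
    gx = a * state.x + (1.0 - state.x) * f
    gy = a * state.y + (1.0 - state.y) * f
    dx = (-a * state.x + (1.0 - state.x) * f) * dt
    dy = (-a * state.y + (1.0 - state.y) * f) * dt
    dx += np.sqrt(np.clip(gx, 0.0, None) / params.nE * dt) * rng.standard_normal(state.x.shape)
    dy += np.sqrt(np.clip(gy, 0.0, None) / params.nI * dt) * rng.standard_normal(state.y.shape)
    x = np.clip(state.x + dx, 0.0, 1.0)
    y = np.clip(state.y + dy, 0.0, 1.0)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FloatingPointError(
            f"non-finite state at t={state.t:g} ms (dt={dt:g})")
    return LatticeState(x=x, y=y, t=state.t + dt)


@njit(cache=True)
def _run_fc(x0, aE, aI, h, alpha, bg, nE, nI, dt, discard_steps, n_bins,
            steps_per_bin, n_neurons, seed):
    """Scalar fully-connected run; returns (counts, rates) for the one site."""
    np.random.seed(seed)
    x = x0
    y = x0
    counts = np.zeros(n_bins, np.int64)
    rates = np.zeros(n_bins, np.float64)
    inv_sqrt_nE = 1.0 / math.sqrt(nE)
    inv_sqrt_nI = 1.0 / math.sqrt(nI)
    sqdt = math.sqrt(dt)
    for _ in range(discard_steps):
        s = aE * x + aI * y + h
        f = bg * math.tanh(s) if s > 0.0 else 0.0
        gx = alpha * x + (1.0 - x) * f
        gy = alpha * y + (1.0 - y) * f
        x += ((1.0 - x) * f - alpha * x) * dt + inv_sqrt_nE * math.sqrt(max(gx, 0.0)) * sqdt * np.random.normal()
        y += ((1.0 - y) * f - alpha * y) * dt + inv_sqrt_nI * math.sqrt(max(gy, 0.0)) * sqdt * np.random.normal()
        x = min(max(x, 0.0), 1.0)
        y = min(max(y, 0.0), 1.0)
    for b in range(n_bins):
        acc = 0.0
        for _ in range(steps_per_bin):
            s = aE * x + aI * y + h
            f = bg * math.tanh(s) if s > 0.0 else 0.0
            acc += (1.0 - 0.5 * (x + y)) * f * dt
            gx = alpha * x + (1.0 - x) * f
            gy = alpha * y + (1.0 - y) * f
            x += ((1.0 - x) * f - alpha * x) * dt + inv_sqrt_nE * math.sqrt(max(gx, 0.0)) * sqdt * np.random.normal()
            y += ((1.0 - y) * f - alpha * y) * dt + inv_sqrt_nI * math.sqrt(max(gy, 0.0)) * sqdt * np.random.normal()
            x = min(max(x, 0.0), 1.0)
            y = min(max(y, 0.0), 1.0)
        counts[b] = np.random.poisson(acc * n_neurons)
        rates[b] = acc / (steps_per_bin * dt)
    return counts, rates


@njit(cache=True)
def _run_lattice(L, x0, odx, ody, ow, aE, aI, h, alpha, bg, nE, nI, dt,
                 discard_steps, n_bins, steps_per_bin, n_neurons, seed):
    """Lattice run with direct truncated-kernel convolution.

    ``odx, ody, ow`` list the nonzero kernel offsets and their normalized
    radial weights; the convolved field is aE*x + aI*y so a single pass
    serves both populations.
    """
    np.random.seed(seed)
    n_sites = L * L
    n_off = odx.shape[0]
    x = np.full((L, L), x0)
    y = np.full((L, L), x0)
    c = np.empty((L, L))
    s = np.empty((L, L))
    acc = np.zeros((L, L))
    counts = np.zeros((n_sites, n_bins), np.int32)
    rates = np.zeros((n_sites, n_bins), np.float32)
    inv_sqrt_nE = 1.0 / math.sqrt(nE)
    inv_sqrt_nI = 1.0 / math.sqrt(nI)
    sqdt = math.sqrt(dt)
    total_steps = discard_steps + n_bins * steps_per_bin
    b = 0
    in_bin = 0
    for it in range(total_steps):
        recording = it >= discard_steps
        for i in range(L):
            for j in range(L):
                c[i, j] = aE * x[i, j] + aI * y[i, j]
        for i in range(L):
            for j in range(L):
                acc_s = h
                for o in range(n_off):
                    ii = i + odx[o]
                    if ii >= L:
                        ii -= L
                    jj = j + ody[o]
                    if jj >= L:
                        jj -= L
                    acc_s += ow[o] * c[ii, jj]
                s[i, j] = acc_s
        for i in range(L):
            for j in range(L):
                si = s[i, j]
                f = bg * math.tanh(si) if si > 0.0 else 0.0
                xi = x[i, j]
                yi = y[i, j]
                if recording:
                    acc[i, j] += (1.0 - 0.5 * (xi + yi)) * f * dt
                gx = alpha * xi + (1.0 - xi) * f
                gy = alpha * yi + (1.0 - yi) * f
                xi += ((1.0 - xi) * f - alpha * xi) * dt + inv_sqrt_nE * math.sqrt(max(gx, 0.0)) * sqdt * np.random.normal()
                yi += ((1.0 - yi) * f - alpha * yi) * dt + inv_sqrt_nI * math.sqrt(max(gy, 0.0)) * sqdt * np.random.normal()
                x[i, j] = min(max(xi, 0.0), 1.0)
                y[i, j] = min(max(yi, 0.0), 1.0)
        if recording:
            in_bin += 1
            if in_bin == steps_per_bin:
                site = 0
                inv = 1.0 / (steps_per_bin * dt)
                for i in range(L):
                    for j in range(L):
                        counts[site, b] = np.random.poisson(acc[i, j] * n_neurons)
                        rates[site, b] = acc[i, j] * inv
                        acc[i, j] = 0.0
                        site += 1
                in_bin = 0
                b += 1
    return counts, rates


def run(params: ModelParams, kernel: ConnectivityKernel | None = None,
        fp: FixedPoint | None = None, seed: int | None = None) -> SpikeTrace:
    """Integrate one run from the fixed point and return its spike trace.

    Discards ``t_discard`` ms of transient, then emits
    ``floor((t_total - t_discard)/delta_bin)`` bins of per-site Poisson
    spike counts and bin-averaged firing rates.
    """
    if params.dt > _max_dt(params):
        raise ValueError(
            f"dt={params.dt:g} exceeds stability bound {_max_dt(params):g}")
    if kernel is None:
        kernel = build_kernel(params)
    if fp is None:
        fp = solve_fixed_point(params)
    if seed is None:
        seed = params.seed
    seed = int(seed) & 0x7FFFFFFF
    steps_per_bin = int(round(params.delta_bin / params.dt))
    if abs(steps_per_bin * params.dt - params.delta_bin) > 1e-9 * params.delta_bin:
        raise ValueError("delta_bin must be an integer multiple of dt")
    n_bins = int(math.floor((params.t_total - params.t_discard) / params.delta_bin))
    if n_bins < 1:
        raise ValueError("run too short: no complete bins after the transient")
    discard_steps = int(round(params.t_discard / params.dt))
    n_neurons = params.nE + params.nI
    aE = 0.5 * (params.w00 + params.ws0)
    aI = 0.5 * (params.w00 - params.ws0)
    if params.L == 1:
        counts, rates = _run_fc(
            fp.sigma0, aE, aI, params.h, params.alpha_rate, params.beta_gain,
            params.nE, params.nI, params.dt, discard_steps, n_bins,
            steps_per_bin, n_neurons, seed)
        counts = counts[None, :]
        rates = rates[None, :]
    else:
        gn = kernel.g / kernel.g.sum()
        idx = np.argwhere(gn != 0.0)
        ow = gn[idx[:, 0], idx[:, 1]]
        counts, rates = _run_lattice(
            params.L, fp.sigma0, idx[:, 0].astype(np.int64),
            idx[:, 1].astype(np.int64), ow, aE, aI, params.h,
            params.alpha_rate, params.beta_gain, params.nE, params.nI,
            params.dt, discard_steps, n_bins, steps_per_bin, n_neurons, seed)
    return SpikeTrace(counts=counts, rates=rates, delta=params.delta_bin,
                      params=params, seed=seed)
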