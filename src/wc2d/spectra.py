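"""Welch power spectra of simulated single-site firing-rate traces.

The estimator works on the binned per-site mean firing rate (the same
observable whose linear-theory spectrum shows the 1/f band), averages
periodograms over segments and over sites, and reports frequencies in Hz
(the trace is sampled every ``delta`` ms, so Nyquist is ``500/delta`` Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .util import sliding_window_slope

__all__ = ["PsdEstimate", "estimate_psd", "sliding_window_beta", "average_psds"]


@dataclass
class PsdEstimate:
    """Averaged-periodogram spectral density of a set of site traces."""

    frequencies: np.ndarray    # Hz, strictly increasing
    density: np.ndarray        # power per Hz, >= 0
    segment_length: int        # samples per segment
    n_segments: int            # total averaged segments (all sites)
    window: str = "hann"


def estimate_psd(rate_trace: np.ndarray, delta: float = 1.0,
                 segment_length: int = 4096, overlap: float = 0.5,
                 window: str = "hann") -> PsdEstimate:
    """Welch estimate of the one-sided PSD, averaged over sites.

    ``rate_trace`` is (n_sites, n_bins) (a 1-D trace is promoted); the mean
    is removed per segment and the density normalized so its integral over
    frequency equals the trace variance (Parseval).  The zero-frequency
    bin is dropped.
    """
    x = np.atleast_2d(np.asarray(rate_trace, dtype=float))
    n_bins = x.shape[1]
    if n_bins < 2 * segment_length:
        raise ValueError(
            f"trace length {n_bins} < 2 x segment length {segment_length}")
    fs = 1000.0 / delta   # Hz
    noverlap = int(segment_length * overlap)
    f, p = signal.welch(x, fs=fs, window=window, nperseg=segment_length,
                        noverlap=noverlap, detrend="constant", axis=-1,
                        scaling="density")
    density = p.mean(axis=0)
    n_seg_per_site = 1 + (n_bins - segment_length) // (segment_length - noverlap)
    return PsdEstimate(frequencies=f[1:], density=density[1:],
                       segment_length=segment_length,
                       n_segments=n_seg_per_site * x.shape[0], window=window)


def average_psds(psds: list[PsdEstimate]) -> PsdEstimate:
    """Combine same-grid estimates from independent runs (weighted by segments)."""
    if not psds:
        raise ValueError("nothing to average")
    f0 = psds[0].frequencies
    for p in psds[1:]:
        if p.frequencies.shape != f0.shape or not np.allclose(p.frequencies, f0):
            raise ValueError("PSD frequency grids differ")
    w = np.array([p.n_segments for p in psds], dtype=float)
    dens = np.sum([p.density * wi for p, wi in zip(psds, w)], axis=0) / w.sum()
    return PsdEstimate(frequencies=f0, density=dens,
                       segment_length=psds[0].segment_length,
                       n_segments=int(w.sum()), window=psds[0].window)


def sliding_window_beta(psd: PsdEstimate, window_factor: float = 10.0):
    """Spectral exponent beta of P(f) ~ f^-beta in windows [f/window_factor, f].

    Returns (anchor frequencies, beta values), beta sign-flipped so decaying
    spectra give positive values; anchors are the upper window edges.
    """
    anchors, slopes = sliding_window_slope(
        psd.frequencies, psd.density, window_factor=window_factor)
    # windows [0.1 f, f]: re-anchor at the upper edge
    return anchors * window_factor, -slopes
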