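"""Single-site avalanche statistics from binned spike counts.

An avalanche is a maximal run of consecutive time bins, each holding at
least one spike, in the activity of one lattice site: its size S is the
total spike count of the run, its duration T the number of bins times the
bin width delta.  Runs touching the trace boundary are censored and
discarded.  All sites are statistically equivalent (translation invariance,
periodic boundaries), so avalanches are pooled across sites and runs.

At criticality P(S) ~ S^-alpha, P(T) ~ T^-tau and <S>(T) ~ T^gamma with the
crackling-noise relation gamma = (tau-1)/(alpha-1); the temporal profiles
of avalanches of duration T collapse as V(t) T^{1-gamma} vs t/T.  Exponents
are estimated by truncated maximum likelihood (distributions) and by
log-log least squares (<S>(T)), over explicitly passed ranges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

from .langevin import SpikeTrace
from .util import sliding_window_slope

__all__ = [
    "AvalancheSet",
    "ExponentFit",
    "ScalingRelationReport",
    "extract_avalanches",
    "pool",
    "size_duration_distributions",
    "fit_powerlaw_tail",
    "mean_size_vs_duration",
    "sliding_window_gamma",
    "scaling_relation_check",
    "shape_collapse",
    "sample_truncated_powerlaw",
    "synthetic_crackling",
]

log = logging.getLogger(__name__)


@dataclass
class AvalancheSet:
    """Pooled avalanches: sizes (spikes), durations (bins) and profiles.

    Profiles are stored in compressed ragged form: ``profile_values`` holds
    the concatenated per-bin counts and ``profile_offsets`` the start index
    of each avalanche (length n+1); ``profile_offsets is None`` when
    profiles were not retained.
    """

    sizes: np.ndarray            # (n,) total spikes, >= 1
    durations: np.ndarray        # (n,) bins, >= 1
    delta: float                 # bin width (ms)
    n_sites: int = 1
    profile_values: np.ndarray | None = None
    profile_offsets: np.ndarray | None = None

    def __len__(self) -> int:
        return self.sizes.size

    @property
    def durations_ms(self) -> np.ndarray:
        return self.durations * self.delta

    def profile(self, i: int) -> np.ndarray:
        if self.profile_offsets is None:
            raise ValueError("profiles were not stored for this set")
        return self.profile_values[self.profile_offsets[i]:self.profile_offsets[i + 1]]


@dataclass(frozen=True)
class ExponentFit:
    """A fitted power-law exponent with its provenance."""

    exponent: float
    stderr: float
    lo: float
    hi: float
    method: str                  # 'MLE' | 'loglog-LS'
    n_points: int


@dataclass(frozen=True)
class ScalingRelationReport:
    """gamma predicted by (tau-1)/(alpha-1) against the fitted gamma."""

    gamma_predicted: float
    gamma_predicted_se: float
    gamma_fitted: float
    gamma_fitted_se: float
    deviation_se_units: float


def _runs_of_row(row: np.ndarray):
    """(starts, ends) of maximal runs of positive entries; ends exclusive."""
    active = np.concatenate(([0], (row > 0).view(np.int8), [0]))
    d = np.diff(active)
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def extract_avalanches(trace: SpikeTrace | np.ndarray, delta: float = 1.0,
                       store_profiles: bool = True) -> AvalancheSet:
    """Extract per-site avalanches from binned counts and pool them.

    Accepts a :class:`SpikeTrace` or a raw (n_sites, n_bins) count array.
    Runs that touch the first or last bin are discarded as censored.
    """
    if isinstance(trace, SpikeTrace):
        counts = trace.counts
        delta = trace.delta
    else:
        counts = np.atleast_2d(np.asarray(trace))
    if counts.shape[1] < 1:
        raise ValueError("trace must have at least one bin")
    n_bins = counts.shape[1]
    sizes, durs, profs = [], [], []
    for row in counts:
        starts, ends = _runs_of_row(row)
        keep = np.ones(starts.size, dtype=bool)
        if starts.size:
            keep &= starts > 0
            keep &= ends < n_bins
        starts, ends = starts[keep], ends[keep]
        if starts.size == 0:
            continue
        cs = np.concatenate(([0], np.cumsum(row, dtype=np.int64)))
        sizes.append(cs[ends] - cs[starts])
        durs.append(ends - starts)
        if store_profiles:
            profs.extend(row[s:e] for s, e in zip(starts, ends))
    if sizes:
        sizes = np.concatenate(sizes)
        durs = np.concatenate(durs)
    else:
        sizes = np.zeros(0, dtype=np.int64)
        durs = np.zeros(0, dtype=np.int64)
    pv = po = None
    if store_profiles:
        if profs:
            pv = np.concatenate([np.asarray(p, dtype=np.int64) for p in profs])
        else:
            pv = np.zeros(0, dtype=np.int64)
        po = np.concatenate(([0], np.cumsum(durs)))
    return AvalancheSet(sizes=sizes, durations=durs, delta=delta,
                        n_sites=counts.shape[0], profile_values=pv,
                        profile_offsets=po)


def pool(sets: list[AvalancheSet]) -> AvalancheSet:
    """Order-independent pooling of avalanche sets with equal bin width."""
    if not sets:
        raise ValueError("nothing to pool")
    delta = sets[0].delta
    if any(s.delta != delta for s in sets):
        raise ValueError("bin widths differ between pooled sets")
    sizes = np.concatenate([s.sizes for s in sets])
    durs = np.concatenate([s.durations for s in sets])
    have_prof = all(s.profile_offsets is not None for s in sets)
    pv = po = None
    if have_prof:
        pv = np.concatenate([s.profile_values for s in sets])
        po = np.concatenate(([0], np.cumsum(durs)))
    return AvalancheSet(sizes=sizes, durations=durs, delta=delta,
                        n_sites=sum(s.n_sites for s in sets),
                        profile_values=pv, profile_offsets=po)


class Distribution(NamedTuple):
    """Log-binned empirical density; sum(density * widths) == 1."""

    centers: np.ndarray
    density: np.ndarray
    widths: np.ndarray


def _log_binned_density(samples: np.ndarray, bins_per_decade: int) -> Distribution:
    lo, hi = samples.min(), samples.max()
    if lo == hi:
        return Distribution(np.array([float(lo)]),
                            np.array([1.0 / max(lo, 1e-300)]),
                            np.array([max(lo, 1e-300)]))
    n_bins = max(1, int(math.ceil(math.log10(hi / lo) * bins_per_decade)))
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    hist, edges = np.histogram(samples, bins=edges)
    widths = np.diff(edges)
    density = hist / (samples.size * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = hist > 0
    return Distribution(centers[keep], density[keep], widths[keep])


def size_duration_distributions(av: AvalancheSet, bins_per_decade: int = 10):
    """Normalized log-binned densities P(S) and P(T) (T in ms).

    Returns (Distribution(S), Distribution(T)); each density integrates to
    one over the sampled range (sum of density x bin width).
    """
    if len(av) == 0:
        raise ValueError("empty avalanche set")
    ps = _log_binned_density(av.sizes.astype(float), bins_per_decade)
    pt = _log_binned_density(av.durations_ms.astype(float), bins_per_decade)
    return ps, pt


def _log_norm(a: float, llo: float, lhi: float) -> float:
    """log of Z(a) = integral of x^-a over [lo, hi], stable through a = 1."""
    u = 1.0 - a
    span = lhi - llo
    if abs(u) * span < 1e-10:
        return math.log(span) + u * llo + math.log1p(u * span / 2.0)
    if u > 0:
        return u * lhi + math.log1p(-math.exp(-u * span)) - math.log(u)
    return u * llo + math.log1p(-math.exp(u * span)) - math.log(-u)


def fit_powerlaw_tail(samples, fit_range, min_samples: int = 100) -> ExponentFit:
    """Truncated-power-law MLE for P(x) ~ x^-a on an explicit range [lo, hi].

    Continuous maximum likelihood with both bounds (a Hill-type estimator
    with an upper truncation); the standard error comes from the observed
    Fisher information.  The range is an input, never auto-selected.
    """
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if not lo < hi:
        raise ValueError("fit range must satisfy lo < hi")
    x = np.asarray(samples, dtype=float)
    x = x[(x >= lo) & (x <= hi)]
    n = x.size
    if n < min_samples:
        raise ValueError(
            f"only {n} samples inside [{lo:g}, {hi:g}] "
            f"(need >= {min_samples})")
    llo, lhi = math.log(lo), math.log(hi)
    mean_lx = float(np.mean(np.log(x)))

    def nll(a):
        return a * mean_lx + _log_norm(a, llo, lhi)

    res = minimize_scalar(nll, bounds=(1e-3, 15.0), method="bounded",
                          options={"xatol": 1e-10})
    a_hat = float(res.x)
    # observed Fisher information per sample = d^2 logZ / da^2
    eps = 1e-4
    d2 = (_log_norm(a_hat + eps, llo, lhi) - 2.0 * _log_norm(a_hat, llo, lhi)
          + _log_norm(a_hat - eps, llo, lhi)) / eps ** 2
    se = 1.0 / math.sqrt(n * d2) if d2 > 0 else math.inf
    return ExponentFit(exponent=a_hat, stderr=se, lo=lo, hi=hi,
                       method="MLE", n_points=n)


def mean_size_vs_duration(av: AvalancheSet, exact_max_bins: int = 100,
                          bins_per_decade: int = 10):
    """<S>(T): mean avalanche size per duration, T in ms.

    Durations up to ``exact_max_bins`` bins are kept exact (they are sparse
    integer multiples of delta); longer ones are pooled in logarithmic
    duration bins.  Returns (T_ms, mean_S, counts).
    """
    if len(av) == 0:
        raise ValueError("empty avalanche set")
    d = av.durations
    s = av.sizes.astype(float)
    T_out, S_out, N_out = [], [], []
    small = d <= exact_max_bins
    if np.any(small):
        uniq, inv = np.unique(d[small], return_inverse=True)
        sums = np.bincount(inv, weights=s[small])
        cnts = np.bincount(inv)
        T_out.extend(uniq * av.delta)
        S_out.extend(sums / cnts)
        N_out.extend(cnts)
    big = ~small
    if np.any(big):
        db = d[big].astype(float)
        lo, hi = db.min(), db.max()
        n_bins = max(1, int(math.ceil(math.log10(hi / lo) * bins_per_decade)))
        edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
        idx = np.clip(np.searchsorted(edges, db, side="right") - 1, 0, n_bins - 1)
        sums = np.bincount(idx, weights=s[big], minlength=n_bins)
        cnts = np.bincount(idx, minlength=n_bins)
        dsum = np.bincount(idx, weights=db, minlength=n_bins)
        keep = cnts > 0
        T_out.extend(dsum[keep] / cnts[keep] * av.delta)
        S_out.extend(sums[keep] / cnts[keep])
        N_out.extend(cnts[keep])
    order = np.argsort(T_out)
    return (np.asarray(T_out)[order], np.asarray(S_out)[order],
            np.asarray(N_out)[order])


def fit_gamma(curve, fit_range) -> ExponentFit:
    """Least-squares log-log fit of <S>(T) ~ T^gamma over [lo, hi] ms."""
    from .util import loglog_slope
    T, S = curve[0], curve[1]
    slope, se, n = loglog_slope(T, S, fit_range[0], fit_range[1])
    return ExponentFit(exponent=slope, stderr=se, lo=fit_range[0],
                       hi=fit_range[1], method="loglog-LS", n_points=n)


def sliding_window_gamma(curve, window_factor: float = 10.0):
    """Exponent of <S>(T) ~ T^gamma in sliding windows [T, window_factor*T].

    Plateaus of the returned curve identify genuine scaling ranges.
    """
    T, S = curve[0], curve[1]
    return sliding_window_slope(T, S, window_factor=window_factor)


def scaling_relation_check(alpha_fit: ExponentFit, tau_fit: ExponentFit,
                           gamma_fit: ExponentFit) -> ScalingRelationReport:
    """Test gamma = (tau-1)/(alpha-1) with first-order error propagation."""
    a, t = alpha_fit.exponent, tau_fit.exponent
    if a <= 1.0:
        raise ArithmeticError(
            f"size exponent alpha={a:g} <= 1: predicted gamma undefined")
    pred = (t - 1.0) / (a - 1.0)
    var = (tau_fit.stderr / (a - 1.0)) ** 2 \
        + ((t - 1.0) * alpha_fit.stderr / (a - 1.0) ** 2) ** 2
    pred_se = math.sqrt(var)
    comb = math.sqrt(var + gamma_fit.stderr ** 2)
    dev = abs(gamma_fit.exponent - pred) / comb if comb > 0 else math.inf
    return ScalingRelationReport(gamma_predicted=pred, gamma_predicted_se=pred_se,
                                 gamma_fitted=gamma_fit.exponent,
                                 gamma_fitted_se=gamma_fit.stderr,
                                 deviation_se_units=dev)


def shape_collapse(av: AvalancheSet, gamma: float, duration_bands,
                   band_factor: float = 1.09, min_count: int = 20,
                   n_grid: int = 50):
    """Collapse mean temporal profiles: V(t) T^{1-gamma} against t/T.

    For each band center T the profiles of avalanches with duration in
    [T/band_factor, T*band_factor] are averaged, interpolated on a common
    t/T grid and rescaled by T^{1-gamma}.  Returns (grid, curves, error)
    where the collapse error is the grid-mean between-band variance divided
    by the variance of the pooled mean curve; empty or undersampled bands
    are skipped with a log notice.
    """
    if av.profile_offsets is None:
        raise ValueError("profiles required for shape collapse")
    grid = (np.arange(n_grid) + 0.5) / n_grid
    curves, kept_bands = [], []
    d_ms = av.durations_ms
    for Tc in duration_bands:
        m = (d_ms >= Tc / band_factor) & (d_ms <= Tc * band_factor)
        idx = np.flatnonzero(m)
        if idx.size < min_count:
            log.info("shape_collapse: band T=%g has %d avalanches (<%d), skipped",
                     Tc, idx.size, min_count)
            continue
        acc = np.zeros(n_grid)
        for i in idx:
            prof = av.profile(i).astype(float) / av.delta    # spikes per ms
            nb = prof.size
            u = (np.arange(nb) + 0.5) / nb
            T_i = nb * av.delta
            acc += np.interp(grid, u, prof) * T_i ** (1.0 - gamma)
        curves.append(acc / idx.size)
        kept_bands.append(Tc)
    if not curves:
        raise ValueError("no duration band had enough avalanches")
    curves = np.vstack(curves)
    if curves.shape[0] == 1:
        return grid, curves, 0.0, kept_bands
    mean_curve = curves.mean(axis=0)
    err = float(curves.var(axis=0).mean() / mean_curve.var())
    return grid, curves, err, kept_bands


# ---------------------------------------------------------------------------
# synthetic crackling-noise generator (the module's principal oracle)

def sample_truncated_powerlaw(rng: np.random.Generator, exponent: float,
                              lo: float, hi: float, size: int) -> np.ndarray:
    """Exact inverse-CDF draws of a continuous power law x^-a on [lo, hi]."""
    u = rng.random(size)
    a = exponent
    if abs(a - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    p = 1.0 - a
    return (lo ** p + u * (hi ** p - lo ** p)) ** (1.0 / p)


def synthetic_crackling(rng: np.random.Generator, n_avalanches: int,
                        tau: float = 2.0, gamma: float = 2.0,
                        t_range=(2, 2000), amplitude: float = 20.0,
                        delta: float = 1.0, poisson_noise: bool = True
                        ) -> AvalancheSet:
    """Avalanche ensemble with planted exponents tau, gamma (and hence alpha).

    Durations are drawn from a truncated power law T^-tau; each avalanche
    carries a parabolic excursion profile V(t) = A T^{gamma-1} u(1-u) scaled
    so that S ~ T^gamma, with optional Poisson bin noise (floored at one
    spike per bin so the run stays unbroken).  The implied size exponent is
    alpha = 1 + (tau-1)/gamma, so extraction + fitting round-trips all
    three exponents and the crackling scaling relation exactly.
    """
    T = np.floor(sample_truncated_powerlaw(
        rng, tau, t_range[0], t_range[1] + 1, n_avalanches)).astype(np.int64)
    T = np.clip(T, 1, None)
    sizes = np.empty(n_avalanches, dtype=np.int64)
    profs = []
    for i, nb in enumerate(T):
        u = (np.arange(nb) + 0.5) / nb
        lam = amplitude * nb ** (gamma - 1.0) * 6.0 * u * (1.0 - u)
        if poisson_noise:
            prof = np.maximum(1, rng.poisson(lam))
        else:
            prof = np.maximum(1, np.rint(lam).astype(np.int64))
        profs.append(prof)
        sizes[i] = prof.sum()
    pv = np.concatenate(profs)
    po = np.concatenate(([0], np.cumsum(T)))
    return AvalancheSet(sizes=sizes, durations=T, delta=delta, n_sites=1,
                        profile_values=pv, profile_offsets=po)
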