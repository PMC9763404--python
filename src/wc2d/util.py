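"""Small shared numerics: log-log slope fits and sliding-window exponents."""

from __future__ import annotations

import numpy as np

__all__ = ["loglog_slope", "sliding_window_slope"]


def loglog_slope(x, y, lo: float, hi: float) -> tuple[float, float, int]:
    """OLS slope of log y vs log x restricted to lo <= x <= hi.

    Returns (slope, stderr, n_points).  Points with nonpositive y are
    dropped.  The band is an explicit input; nothing is auto-selected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if lo >= hi:
        raise ValueError("need lo < hi")
    m = (x >= lo) & (x <= hi) & (y > 0) & (x > 0)
    n = int(m.sum())
    if n < 3:
        raise ValueError(f"only {n} points in fit band [{lo:g}, {hi:g}]")
    lx, ly = np.log(x[m]), np.log(y[m])
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, *_ = np.linalg.lstsq(A, ly, rcond=None)
    slope = float(coef[0])
    if n > 2 and res.size:
        s2 = float(res[0]) / (n - 2)
        sxx = float(((lx - lx.mean()) ** 2).sum())
        se = (s2 / sxx) ** 0.5
    else:
        se = 0.0
    return slope, se, n


def sliding_window_slope(x, y, window_factor: float = 10.0,
                         min_points: int = 3):
    """Slope of log y vs log x in windows [x0, window_factor*x0].

    Returns (anchors, slopes); windows with fewer than ``min_points`` points
    are skipped.  Used both for the avalanche <S>(T) exponent and for the
    spectral exponent diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    order = np.argsort(x)
    x, y = x[order], y[order]
    anchors, slopes = [], []
    for x0 in x:
        m = (x >= x0) & (x <= window_factor * x0)
        if int(m.sum()) < min_points:
            continue
        lx, ly = np.log(x[m]), np.log(y[m])
        slope = np.polyfit(lx, ly, 1)[0]
        anchors.append(x0)
        slopes.append(float(slope))
    return np.asarray(anchors), np.asarray(slopes)
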