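"""Signal-quality and accuracy statistics.

* fidelity index — peak of the normalized cross-correlation between a
  sensor signal and the reference joint-angle waveform, searched over all
  lags; 1.0 means the sensor reproduces the movement shape exactly up to
  amplitude scaling and delay.
* hysteresis error — maximum loading-unloading output discrepancy of a
  strain sensor, as a percentage of full-scale output.
* MAPE / RMSE — the standard estimation-accuracy summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate


@dataclass(frozen=True)
class FidelityResult:
    """Peak normalized cross-correlation with its lag; ``negative_peak``
    notes when the extreme correlation is anti-phase."""

    value: float
    lag: int
    negative_peak: bool = False

    def __float__(self) -> float:
        return self.value


def fidelity_index(signal, reference, full: bool = False):
    """Peak of the normalized cross-correlation between signal and reference.

    Both series are mean-removed and normalized by their global standard
    deviations (whole-series statistics, not per-lag windows); the
    cross-correlation is searched over all lags.  Returns a float in
    [-1, 1] (or a :class:`FidelityResult` when ``full=True``); constant
    series have no defined correlation and raise.
    """
    x = np.asarray(signal, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.size != y.size:
        raise ValueError("signal and reference must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("fidelity undefined for constant series")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    c = correlate(x, y, mode="full") / x.size
    i_max = int(np.argmax(c))
    peak = float(c[i_max])
    neg = bool(np.max(np.abs(c)) > abs(peak) + 1e-15)
    result = FidelityResult(value=peak, lag=i_max - (x.size - 1), negative_peak=neg)
    return result if full else result.value


def hysteresis_error(loading, unloading) -> float:
    """Loading-unloading discrepancy as percent of full-scale output.

    Each branch is an (strain, output) pair of 1-D arrays with monotone
    strain.  The branches are interpolated onto their common strain range
    and the maximum absolute output difference is referenced to the output
    span of the loading branch.  Symmetric in branch order.
    """
    (s_l, y_l), (s_u, y_u) = [(np.asarray(s, float), np.asarray(y, float))
                              for s, y in (loading, unloading)]
    for s in (s_l, s_u):
        d = np.diff(s)
        if not (np.all(d >= 0) or np.all(d <= 0)):
            raise ValueError("branch strain must be monotone")
    lo = max(s_l.min(), s_u.min())
    hi = min(s_l.max(), s_u.max())
    if hi <= lo:
        raise ValueError("branches span non-overlapping strain ranges")
    grid = np.linspace(lo, hi, 512)
    yl = np.interp(grid, *_ascending(s_l, y_l))
    yu = np.interp(grid, *_ascending(s_u, y_u))
    full_scale = np.ptp(y_l)
    if full_scale == 0:
        raise ValueError("loading branch has zero output span")
    return float(np.max(np.abs(yu - yl)) / full_scale * 100.0)


def _ascending(s, y):
    order = np.argsort(s)
    return s[order], y[order]


def mape(pred, truth) -> float:
    """Mean absolute percentage error, in percent; truth must be nonzero."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal shape")
    zeros = np.flatnonzero(t == 0)
    if zeros.size:
        raise ValueError(f"MAPE undefined: zero truth entries at indices {zeros.tolist()}")
    return float(np.mean(np.abs((p - t) / t)) * 100.0)


def rmse(pred, truth) -> float:
    """Root mean square error, in the units of the inputs."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal shape")
    return float(np.sqrt(np.mean((p - t) ** 2)))
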