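"""Per-window decomposition of raw TEG channels into (V1, V2, f).

Each non-overlapping, half-open 2 s window [t, t+2) of a recording is
reduced to the quantities the analytic sensing model consumes:

* f — the gait frequency: the dominant periodogram frequency of the
  detrended window within the human-cadence band 0.5-4 Hz (hann window,
  zero-padded FFT), refined by a least-squares sinusoid fit around the
  peak.  The refinement matters: a 2 s window at 3 km/h holds barely two
  gait cycles, where the raw periodogram peak is pulled several percent
  low by interference with its negative-frequency image — and f enters
  the thigh AC equation cubed;
* V1 — the DC level.  For inactive windows, the plain window mean.  For
  active windows the mean is contaminated by the oscillation (a window
  holds a non-integer number of cycles, so it does not average out); V1
  is the intercept, at the window centre, of the harmonic regression
  x ~ b0 + b1 t + bs sin(2 pi f t) + bc cos(2 pi f t);
* V2 — the amplitude of the gait-locked oscillation, taken from the same
  harmonic regression as hypot(bs, bc).  A robust percentile-span
  alternative (:func:`ac_amplitude`, unbiased for a sinusoid, tolerant of
  non-sinusoidal waveforms) is kept isolated for swap-out — on windows
  this short its uneven phase coverage biases it by several percent;
* active — whether the accelerometer variance in the window exceeds a
  threshold, the cue the power manager uses to switch modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend

from .session import SessionRecording

log = logging.getLogger(__name__)

#: Span of a unit-amplitude sinusoid between its 5th and 95th percentiles.
_SINE_P5_P95_SPAN = 2.0 * np.sin(0.45 * np.pi)

#: Human-cadence search band (Hz) for the gait-frequency estimator.
GAIT_BAND = (0.5, 4.0)

#: Default summed per-axis acceleration variance ((m/s^2)^2) separating
#: quiescence from activity; generated rest segments sit near 0.0075 and
#: the slowest walking segments near 1.5, so 0.1 splits them with margin.
ACTIVITY_THRESHOLD = 0.1

FEATURE_COLUMNS = ["t_start", "Vs1", "Vs2", "Vt1", "Vt2", "fs", "ft",
                   "Tair", "active", "valid"]


@dataclass(frozen=True)
class WindowFeatures:
    """Decomposed features of one 2 s analysis window."""

    t_start: float
    Vs1: float
    Vs2: float
    Vt1: float
    Vt2: float
    fs: float
    ft: float
    Tair: float
    active: bool
    valid: bool = True


def ac_amplitude(x) -> float:
    """Robust peak-type amplitude of a detrended oscillation.

    Half the 5th-95th percentile span, scaled to be unbiased for a
    sinusoid sampled over uniform phase.
    """
    x = np.asarray(x, dtype=float)
    p5, p95 = np.percentile(x, [5.0, 95.0])
    return float((p95 - p5) / _SINE_P5_P95_SPAN)


def dominant_frequency(x, rate: float, band=GAIT_BAND, nfft: int = 8192) -> float:
    """Dominant periodogram frequency of x within ``band`` (Hz)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    w = np.hanning(x.size)
    power = np.abs(np.fft.rfft(x * w, max(nfft, x.size))) ** 2
    freqs = np.fft.rfftfreq(max(nfft, x.size), 1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[mask][np.argmax(power[mask])])


def _harmonic_fit(x, rate: float, f: float):
    """LSQ fit x ~ b0 + b1 t + bs sin(2 pi f t) + bc cos(2 pi f t) with t
    centred; returns (dc_level, amplitude, rss)."""
    t = np.arange(x.size) / rate
    t = t - t.mean()
    design = np.column_stack([np.ones_like(t), t,
                              np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t)])
    beta, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    return float(beta[0]), float(np.hypot(beta[2], beta[3])), float(resid @ resid)


def refine_frequency(x, rate: float, f0: float, halfwidth: float = 0.25,
                     band=GAIT_BAND) -> float:
    """Refine a coarse frequency estimate by minimizing the harmonic-fit
    residual over f in [f0 - halfwidth, f0 + halfwidth] (within band)."""
    from scipy.optimize import minimize_scalar

    x = np.asarray(x, dtype=float)
    lo = max(band[0], f0 - halfwidth)
    hi = min(band[1], f0 + halfwidth)
    res = minimize_scalar(lambda f: _harmonic_fit(x, rate, f)[2],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def dc_level(x, rate: float, f: float | None = None) -> float:
    """DC level of a window, robust to a gait-locked oscillation at f.

    With ``f`` given, the harmonic-regression intercept at the window
    centre; without f, the plain mean.
    """
    x = np.asarray(x, dtype=float)
    if f is None or f <= 0:
        return float(x.mean())
    return _harmonic_fit(x, rate, f)[0]


def detect_activity(accel_window, threshold: float = ACTIVITY_THRESHOLD) -> bool:
    """True iff the summed per-axis acceleration variance exceeds threshold.

    ``accel_window`` is an (n, 3) array (or any 2-D array of axis columns).
    """
    a = np.atleast_2d(np.asarray(accel_window, dtype=float))
    if a.size == 0:
        raise ValueError("empty accelerometer window")
    return bool(np.sum(np.var(a, axis=0)) > threshold)


def extract_features(recording: SessionRecording, window: float = 2.0,
                     activity_threshold: float = ACTIVITY_THRESHOLD) -> pd.DataFrame:
    """Decompose a recording into per-window features.

    Returns a DataFrame with one row per non-overlapping window (columns
    per :data:`FEATURE_COLUMNS`).  Windows containing NaNs are flagged
    invalid and counted in the log; gait frequencies are reported as 0 for
    inactive windows.
    """
    df = recording.df
    rate = recording.raw_rate
    n_per = int(round(window * rate))
    if len(df) < n_per:
        raise ValueError("recording shorter than one analysis window")
    n_win = len(df) // n_per

    # a channel that is NaN over the whole recording is absent, not invalid:
    # its features come out NaN but the window itself stays usable
    absent = {col for col in ("Vs_raw", "Vt_raw") if df[col].isna().all()}
    check_cols = [c for c in ("Vs_raw", "Vt_raw", "ax", "ay", "az", "Tair")
                  if c not in absent]

    rows = []
    n_invalid = 0
    for k in range(n_win):
        sl = slice(k * n_per, (k + 1) * n_per)
        chunk = df.iloc[sl]
        if chunk[check_cols].isna().any().any():
            n_invalid += 1
            rows.append(WindowFeatures(t_start=k * window, Vs1=np.nan, Vs2=np.nan,
                                       Vt1=np.nan, Vt2=np.nan, fs=0.0, ft=0.0,
                                       Tair=np.nan, active=False, valid=False))
            continue
        active = detect_activity(chunk[["ax", "ay", "az"]].to_numpy(), activity_threshold)
        feats = {}
        for leg, col in (("s", "Vs_raw"), ("t", "Vt_raw")):
            if col in absent:
                feats[f"V{leg}1"], feats[f"V{leg}2"], feats[f"f{leg}"] = np.nan, np.nan, 0.0
                continue
            x = chunk[col].to_numpy()
            if active:
                resid = detrend(x, type="linear")
                f = refine_frequency(x, rate, dominant_frequency(resid, rate))
                v1, v2, _ = _harmonic_fit(x, rate, f)
            else:
                f = 0.0
                v1 = dc_level(x, rate)
                v2 = ac_amplitude(detrend(x, type="linear"))
            feats[f"V{leg}1"], feats[f"V{leg}2"], feats[f"f{leg}"] = v1, v2, f
        rows.append(WindowFeatures(t_start=k * window, Tair=float(chunk["Tair"].mean()),
                                   active=active, valid=True, **feats))
    if n_invalid:
        log.warning("%d of %d windows contained NaNs and were flagged invalid",
                    n_invalid, n_win)
    return pd.DataFrame([r.__dict__ for r in rows], columns=FEATURE_COLUMNS)
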