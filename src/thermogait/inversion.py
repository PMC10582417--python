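"""Inversion of the King's-law sensing model per analysis window.

Each leg carries two calibrated channels (DC level and AC amplitude)
driven by the same skin-air temperature difference dT and gait frequency
f.  Taking the ratio of the two channel equations eliminates dT exactly —
and f as well when both channels share the same frequency exponent:

    (V1 / V2)^2 * f^(n1 - n2) = (I1 + J1 v^m1) / (I2 + J2 v^m2)

leaving a one-dimensional root-finding problem in the speed v.  Because
the exponents are small integers, clearing the denominator turns the
ratio equation into a polynomial of degree <= 3 whose real roots in the
speed bracket are extracted exactly (companion-matrix eigenvalues); this
is complete where a bracketing scan can miss twin roots that sit between
scan points near an extremum of the channel ratio.  Speed in
hand, dT follows by back-substitution into the DC equation and the skin
temperature as Tair + dT.  This elimination scheme is deterministic and
cheap — the shape of computation an ultra-low-power microcontroller can
afford — and is cross-checked in the test suite against a brute-force
joint grid minimization over (v, dT).

Inactive (resting) windows carry no gait information: speed is reported
as 0 and temperatures come from inverting the static DC response
V1 = dT sqrt(I).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IdentifiabilityError

log = logging.getLogger(__name__)

#: Admissible speed bracket (km/h) for inverted estimates.
SPEED_BRACKET = (0.0, 12.0)
XTOL = 1e-6


@dataclass(frozen=True)
class HealthEstimate:
    """Per-window estimate of locomotion speed and skin temperatures."""

    t_start: float
    v_hat: float
    Ts_hat: float
    Tt_hat: float
    v_hat_shank: float
    v_hat_thigh: float
    valid: bool


def _ratio_speed(V1, V2, f, model1, model2, prev_v=None):
    """Solve (V1/V2)^2 f^(n1-n2) = (I1+J1 v^m1)/(I2+J2 v^m2) for v.

    Clearing the denominator gives the polynomial

        (I1 - lhs I2) + J1 v^m1 - lhs J2 v^m2 = 0

    whose real roots inside the speed bracket are extracted exactly.
    With multiple roots, prefers the one nearest the previous window's
    estimate (temporal continuity), else the smallest.  Returns None when
    no root exists in the bracket.
    """
    if model2.J == 0 and model1.J == 0:
        raise IdentifiabilityError("speed unidentifiable: both channel slopes J are zero")
    lhs = (V1 / V2) ** 2 * f ** (model1.n - model2.n)

    deg = max(model1.m, model2.m)
    coeffs = np.zeros(deg + 1)          # index = power of v
    coeffs[0] = model1.I - lhs * model2.I
    coeffs[model1.m] += model1.J
    coeffs[model2.m] -= lhs * model2.J
    poly = np.trim_zeros(coeffs[::-1], "f")   # highest power first
    if poly.size <= 1:
        return None
    candidates = np.roots(poly)
    real = candidates[np.abs(candidates.imag) < 1e-9].real
    real = real[(real >= SPEED_BRACKET[0] - XTOL) & (real <= SPEED_BRACKET[1] + XTOL)]
    roots = sorted(float(np.clip(r, *SPEED_BRACKET)) for r in real)
    if not roots:
        return None
    if len(roots) > 1 and prev_v is not None:
        return min(roots, key=lambda r: abs(r - prev_v))
    return min(roots)


def solve_speed_shank(Vs1, Vs2, fs, calib, prev_v=None):
    """Leg speed (km/h) from the shank channel pair; f cancels when the
    two shank exponents n coincide (the default)."""
    if not (Vs2 > 0 and fs > 0):
        raise IdentifiabilityError("Vs2 and fs must be positive to invert")
    return _ratio_speed(Vs1, Vs2, fs, calib["shank_dc"], calib["shank_ac"], prev_v)


def solve_speed_thigh(Vt1, Vt2, ft, calib, prev_v=None):
    """Leg speed (km/h) from the thigh channel pair; the measured ft enters
    through the exponent gap (n1 - n2 = -2 by default, the f^3 AC term)."""
    if not (Vt2 > 0 and ft > 0):
        raise IdentifiabilityError("Vt2 and ft must be positive to invert")
    return _ratio_speed(Vt1, Vt2, ft, calib["thigh_dc"], calib["thigh_ac"], prev_v)


def _delta_t(V1, f, v, model):
    """Back-substituted dT = V1 sqrt(f^n / (I + J v^m))."""
    return V1 * np.sqrt(f ** model.n / (model.I + model.J * v ** model.m))


def estimate_window(row, calib, fusion_weights=(0.5, 0.5), prev_v=None) -> HealthEstimate:
    """Invert one feature window to (speed, shank temp, thigh temp).

    ``row`` is a mapping with the feature columns (Vs1, Vs2, Vt1, Vt2, fs,
    ft, Tair, active, valid, t_start).  Active windows fuse the two
    leg-wise speeds by weighted mean; inactive windows report v = 0 and
    temperatures from the static DC inversion.  Any failed sub-solver
    flags the whole estimate invalid — never silently interpolated.
    """
    t0 = float(row["t_start"])
    Tair = float(row["Tair"])
    nan = float("nan")
    if not row.get("valid", True):
        return HealthEstimate(t0, nan, nan, nan, nan, nan, valid=False)

    if not row["active"]:
        Ts = Tair + row["Vs1"] / np.sqrt(calib["shank_dc"].I)
        Tt = Tair + row["Vt1"] / np.sqrt(calib["thigh_dc"].I)
        return HealthEstimate(t0, 0.0, float(Ts), float(Tt), 0.0, 0.0, valid=True)

    try:
        v_s = solve_speed_shank(row["Vs1"], row["Vs2"], row["fs"], calib, prev_v)
        v_t = solve_speed_thigh(row["Vt1"], row["Vt2"], row["ft"], calib, prev_v)
    except IdentifiabilityError as err:
        log.debug("window t=%.1f s not invertible: %s", t0, err)
        return HealthEstimate(t0, nan, nan, nan, nan, nan, valid=False)
    if v_s is None or v_t is None:
        return HealthEstimate(t0, nan, nan, nan, nan, nan, valid=False)

    w_s, w_t = fusion_weights
    v_hat = (w_s * v_s + w_t * v_t) / (w_s + w_t)
    dTs = _delta_t(row["Vs1"], row["fs"], v_hat, calib["shank_dc"])
    dTt = _delta_t(row["Vt1"], row["ft"], v_hat, calib["thigh_dc"])
    return HealthEstimate(t0, float(v_hat), float(Tair + dTs), float(Tair + dTt),
                          float(v_s), float(v_t), valid=True)


def estimate_session(features: pd.DataFrame, calib,
                     fusion_weights=(0.5, 0.5)) -> pd.DataFrame:
    """Invert every window of a feature table, threading the continuity
    rule (previous valid speed seeds root selection)."""
    rows = []
    prev_v = None
    for _, row in features.iterrows():
        est = estimate_window(row, calib, fusion_weights, prev_v)
        if est.valid and est.v_hat > 0:
            prev_v = est.v_hat
        rows.append(est.__dict__)
    n_bad = sum(1 for r in rows if not r["valid"])
    if n_bad:
        log.warning("%d of %d windows not invertible", n_bad, len(rows))
    return pd.DataFrame(rows)
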