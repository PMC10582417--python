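"""Synthetic treadmill-session generator.

Emulates the measurement protocol the sensing stack is designed for: a
subject walks/runs at 3-8 km/h in 1 km/h steps, 30 s per step, six
repeated sessions.  Every recording carries the raw sensor channels a
leg-worn unit would see — composite TEG voltages on shank and thigh
(DC thermal level plus a gait-locked oscillation), a knee-angle-driven
fabric strain-gauge signal with configurable hysteresis, tri-axial shank
acceleration — together with the ground-truth labels used to synthesize
them (speed, skin temperatures, gait frequency, metabolic rate), so every
downstream stage can be tested without external data.

The waveforms are statistical stand-ins, not validated biomechanics: a
two-hump knee-flexion template per gait cycle, harmonic accelerometer
waveforms with impact transients, and a monotone speed -> metabolic-rate
map with autocorrelated physiological noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import DomainError
from .teg import channel_response, static_response, default_generator_models

log = logging.getLogger(__name__)

SESSION_COLUMNS = [
    "time", "v_true", "gait_f", "knee_angle", "Ts_true", "Tt_true", "Tair",
    "Vs_raw", "Vt_raw", "strain", "ax", "ay", "az", "met_true",
]

UNITS = {
    "time": "s", "v_true": "km/h", "gait_f": "Hz", "knee_angle": "deg",
    "Ts_true": "degC", "Tt_true": "degC", "Tair": "degC",
    "Vs_raw": "mV", "Vt_raw": "mV", "strain": "dR/R",
    "ax": "m/s^2", "ay": "m/s^2", "az": "m/s^2", "met_true": "W/kg",
}


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class ProtocolConfig:
    """Treadmill protocol: speed staircase, dwell per speed, session count."""

    speeds: tuple = (3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    dwell: float = 30.0
    n_sessions: int = 6
    raw_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell <= 0:
            raise DomainError("dwell must be positive")
        if self.raw_rate < 10:
            raise DomainError("raw_rate must be >= 10 Hz")
        if np.any(np.diff(self.speeds) <= 0):
            raise DomainError("speeds must be strictly increasing")

    @property
    def duration(self) -> float:
        return len(self.speeds) * self.dwell


@dataclass(frozen=True)
class GaitConfig:
    """Cadence map and limb waveform shape parameters.

    Cadence follows f = intercept + slope * v (Hz), shared by both legs,
    with seeded per-window jitter emulating stride-to-stride variability.
    """

    cadence_intercept: float = 0.5
    cadence_slope: float = 0.15
    cadence_jitter_sd: float = 0.08
    f_band: tuple = (0.5, 4.0)
    knee_baseline_deg: float = 5.0
    knee_amp_intercept: float = 30.0
    knee_amp_slope: float = 4.0
    knee_amp_max: float = 65.0
    accel_amp_intercept: float = 0.8
    accel_amp_slope: float = 0.3

    def cadence(self, v):
        return self.cadence_intercept + self.cadence_slope * np.asarray(v, dtype=float)

    def knee_amplitude(self, v):
        v = np.asarray(v, dtype=float)
        amp = np.minimum(self.knee_amp_max, self.knee_amp_intercept + self.knee_amp_slope * v)
        return np.where(v > 0, amp, 0.0)


@dataclass(frozen=True)
class ThermalConfig:
    """Skin/air temperature trajectory: shank warmer than thigh, slow warm-up ramp."""

    Ts0: float = 34.2
    Tt0: float = 32.8
    Tair: float = 26.0
    shank_ramp: float = 0.8   # degC gained linearly over the session
    thigh_ramp: float = 0.6

    def __post_init__(self) -> None:
        if self.Ts0 <= self.Tair or self.Tt0 <= self.Tair:
            raise DomainError("skin temperatures must exceed Tair (dT > 0)")
        if max(abs(self.shank_ramp), abs(self.thigh_ramp)) > 1.0:
            raise DomainError("warm-up ramp bounded at 1 degC per session")


@dataclass(frozen=True)
class StrainSensorConfig:
    """Fabric strain gauge: linear response, small loading/unloading hysteresis.

    ``hysteresis_width`` is the maximum loading-unloading output separation
    as a fraction of full-scale output; the default 0.028 reproduces a 2.8%
    hysteresis error.  ``R0`` is the nominal sensor resistance (Ohm).
    """

    gauge_linear_slope: float = 1.0     # dR/R per unit strain
    max_strain: float = 0.40
    hysteresis_width: float = 0.028
    R0: float = 15000.0
    angle_full_scale_deg: float = 175.0  # angle mapping: strain = angle / this

    def __post_init__(self) -> None:
        if not (0.0 <= self.hysteresis_width <= 0.1):
            raise DomainError("hysteresis_width must lie in [0, 0.1]")
        if self.max_strain > 0.40:
            log.warning("max_strain %.3f exceeds the 0.40 characterised range",
                        self.max_strain)


@dataclass(frozen=True)
class MetabolicConfig:
    """Ground-truth metabolic-rate model: quadratic-in-speed base level plus
    AR(1) physiological noise, smoothed by a first-order 20 s lag."""

    base_intercept: float = 2.0    # W/kg
    base_linear: float = 0.9       # W/kg per km/h
    base_quadratic: float = 0.05   # W/kg per (km/h)^2
    ar_rho: float = 0.9            # AR(1) coefficient at 1 Hz
    ar_sd: float = 0.15            # innovation SD, W/kg
    lag_tau: float = 20.0          # s, first-order response time

    def base(self, v):
        v = np.asarray(v, dtype=float)
        return self.base_intercept + self.base_linear * v + self.base_quadratic * v ** 2


@dataclass(frozen=True)
class NoiseConfig:
    """Additive Gaussian measurement noise per channel.

    Voltage noise SD = ``voltage_abs_sd + voltage_rel_sd * |clean|`` per
    sample (the relative term dominates by default: 2% of signal level).
    """

    voltage_rel_sd: float = 0.02
    voltage_abs_sd: float = 0.0
    accel_sd: float = 0.05         # m/s^2
    strain_sd: float = 0.002       # dR/R


# ---------------------------------------------------------------------------
# Waveform primitives

def _gait_template(phase_cycles):
    """Normalized knee-flexion waveform over one gait cycle (peak ~1).

    Two unequal flexion events: a small stance-phase bump and the large
    swing-phase peak, built from wrapped Gaussians.
    """
    phi = np.asarray(phase_cycles, dtype=float) % 1.0
    out = np.zeros_like(phi)
    for center, width, amp in ((0.15, 0.08, 0.20), (0.72, 0.16, 1.0)):
        for wrap in (-1.0, 0.0, 1.0):
            out += amp * np.exp(-(((phi - center + wrap) / width) ** 2))
    return out


def knee_angle_waveform(v, t, seed=None, gait: GaitConfig | None = None):
    """Knee joint angle (degrees) over time grid t at constant speed v.

    Periodic double-bump flexion waveform whose cadence and amplitude both
    grow with speed; at rest the knee holds a constant small angle.
    """
    gait = gait or GaitConfig()
    t = np.asarray(t, dtype=float)
    if v < 0:
        raise DomainError("v must be non-negative")
    if v == 0:
        return np.full_like(t, gait.knee_baseline_deg)
    f = float(gait.cadence(v))
    if seed is not None:
        f = f + float(np.random.default_rng(seed).normal(0.0, gait.cadence_jitter_sd))
        f = float(np.clip(f, *gait.f_band))
    amp = float(gait.knee_amplitude(v))
    return gait.knee_baseline_deg + amp * _gait_template(f * t)


def angle_to_strain(angle_deg, cfg: StrainSensorConfig | None = None):
    """Map knee angle (degrees) to gauge strain (fraction of unit length)."""
    cfg = cfg or StrainSensorConfig()
    return np.asarray(angle_deg, dtype=float) / cfg.angle_full_scale_deg


def strain_transduce(strain, cfg: StrainSensorConfig | None = None):
    """Transduce a strain series to gauge output dR/R with hysteresis.

    The response is linear in strain; loading and unloading branches are
    separated by a lens-shaped offset that vanishes at the travel endpoints
    and peaks at ``hysteresis_width`` x full-scale output mid-travel
    (unloading reads high, loading reads low).  Strain above ``max_strain``
    is clipped with a logged warning.
    """
    cfg = cfg or StrainSensorConfig()
    s = np.asarray(strain, dtype=float)
    n_over = int(np.sum(s > cfg.max_strain))
    if n_over:
        log.warning("%d strain samples above max_strain %.2f clipped", n_over, cfg.max_strain)
        s = np.minimum(s, cfg.max_strain)
    full_scale = cfg.gauge_linear_slope * cfg.max_strain
    # direction: +1 loading (strain increasing), -1 unloading; holds carry forward
    ds = np.diff(s, prepend=s[:1])
    direction = np.sign(ds)
    for i in range(1, direction.size):
        if direction[i] == 0:
            direction[i] = direction[i - 1]
    lens = np.sin(np.pi * s / cfg.max_strain)
    offset = -direction * 0.5 * cfg.hysteresis_width * full_scale * lens
    return cfg.gauge_linear_slope * s + offset


# ---------------------------------------------------------------------------
# Session synthesis

@dataclass
class SessionRecording:
    """Multi-channel synchronized recording with ground-truth annotations.

    ``df`` holds one row per sample with the documented column schema;
    ``meta`` records configs, seed, units and schema version.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def raw_rate(self) -> float:
        return float(self.meta["raw_rate"])

    @property
    def n_samples(self) -> int:
        return len(self.df)

    @property
    def duration(self) -> float:
        return self.n_samples / self.raw_rate


def _window_index(t, window=2.0):
    return np.floor(np.asarray(t) / window).astype(int)


def generate_session(protocol: ProtocolConfig | None = None,
                     models: dict | None = None,
                     thermal: ThermalConfig | None = None,
                     gait: GaitConfig | None = None,
                     strain_cfg: StrainSensorConfig | None = None,
                     metabolic: MetabolicConfig | None = None,
                     noise: NoiseConfig | None = None,
                     session_index: int = 0,
                     window: float = 2.0) -> SessionRecording:
    """Synthesize one treadmill session; pure function of configs and seed.

    The composite TEG voltage per leg is the DC-channel response plus a
    gait-locked sinusoid with the AC-channel response as amplitude, driven
    by the same phase track as the knee angle and accelerometer.  Gait
    frequency is piecewise-constant per analysis window (cadence map plus
    seeded jitter) so each window has a well-defined ground-truth f.
    """
    protocol = protocol or ProtocolConfig()
    models = models or default_generator_models()
    thermal = thermal or ThermalConfig()
    gait = gait or GaitConfig()
    strain_cfg = strain_cfg or StrainSensorConfig()
    metabolic = metabolic or MetabolicConfig()
    noise = noise if noise is not None else NoiseConfig()

    rng = np.random.default_rng(np.random.SeedSequence([int(protocol.seed), int(session_index)]))
    dt = 1.0 / protocol.raw_rate
    n = int(round(protocol.duration * protocol.raw_rate))
    t = np.arange(n) * dt

    # speed staircase
    seg = np.minimum((t // protocol.dwell).astype(int), len(protocol.speeds) - 1)
    v = np.asarray(protocol.speeds, dtype=float)[seg]

    # per-window gait frequency: cadence map + jitter, zero at rest
    widx = _window_index(t, window)
    n_win = widx.max() + 1
    jitter = rng.normal(0.0, gait.cadence_jitter_sd, n_win)
    f_win = np.zeros(n_win)
    for k in range(n_win):
        vw = v[widx == k].mean()
        if vw > 0:
            f_win[k] = np.clip(gait.cadence(vw) + jitter[k], *gait.f_band)
    gait_f = f_win[widx]
    phase = 2.0 * np.pi * np.cumsum(gait_f) * dt

    # thermal trajectories
    frac = t / protocol.duration
    Ts = thermal.Ts0 + thermal.shank_ramp * frac
    Tt = thermal.Tt0 + thermal.thigh_ramp * frac
    Tair = np.full(n, thermal.Tair)
    dTs, dTt = Ts - Tair, Tt - Tair
    if np.any(dTs <= 0) or np.any(dTt <= 0):
        raise DomainError("thermal config yields non-positive skin-air dT")

    # composite TEG voltages (clean)
    moving = gait_f > 0
    def _composite(dT, dc_model, ac_model):
        out = np.asarray(static_response(dc_model, dT), dtype=float).copy()
        if np.any(moving):
            dc = channel_response(dc_model, dT[moving], v[moving], gait_f[moving])
            ac = channel_response(ac_model, dT[moving], v[moving], gait_f[moving])
            out[moving] = dc + ac * np.sin(phase[moving])
        return out

    Vs_clean = _composite(dTs, models["shank_dc"], models["shank_ac"])
    Vt_clean = _composite(dTt, models["thigh_dc"], models["thigh_ac"])

    # knee angle and strain channel
    knee = gait.knee_baseline_deg + gait.knee_amplitude(v) * _gait_template(phase / (2 * np.pi))
    strain_clean = strain_transduce(angle_to_strain(knee, strain_cfg), strain_cfg)

    # tri-axial shank acceleration: gait-locked harmonics + impact transients
    amp = np.where(v > 0, gait.accel_amp_intercept + gait.accel_amp_slope * v, 0.0)
    ax_c = amp * (np.sin(phase) + 0.45 * np.sin(2 * phase + 0.6)
                  + 1.2 * np.maximum(0.0, np.sin(phase + 0.25)) ** 8)
    ay_c = 0.6 * amp * (np.cos(phase) + 0.30 * np.sin(2 * phase + 1.1))
    az_c = 0.8 * amp * (np.sin(phase + 1.9) + 0.50 * np.sin(2 * phase + 0.3)
                        + 0.8 * np.maximum(0.0, np.sin(phase + 2.2)) ** 6)

    # metabolic ground truth: base(v) + AR(1) at 1 Hz, then 20 s first-order lag
    n_sec = int(np.ceil(protocol.duration)) + 1
    innov = rng.normal(0.0, metabolic.ar_sd, n_sec)
    ar = lfilter([1.0], [1.0, -metabolic.ar_rho], innov)
    ar_raw = np.interp(t, np.arange(n_sec, dtype=float), ar)
    met0 = metabolic.base(v) + ar_raw
    a = dt / metabolic.lag_tau
    met = lfilter([a], [1.0, a - 1.0], met0, zi=[(1 - a) * met0[0]])[0]

    # measurement noise
    def _vnoise(clean):
        sd = noise.voltage_abs_sd + noise.voltage_rel_sd * np.abs(clean)
        return clean + rng.normal(0.0, 1.0, n) * sd

    df = pd.DataFrame({
        "time": t, "v_true": v, "gait_f": gait_f, "knee_angle": knee,
        "Ts_true": Ts, "Tt_true": Tt, "Tair": Tair,
        "Vs_raw": _vnoise(Vs_clean), "Vt_raw": _vnoise(Vt_clean),
        "strain": strain_clean + rng.normal(0.0, noise.strain_sd, n),
        "ax": ax_c + rng.normal(0.0, noise.accel_sd, n),
        "ay": ay_c + rng.normal(0.0, noise.accel_sd, n),
        "az": az_c + rng.normal(0.0, noise.accel_sd, n),
        "met_true": met,
    }, columns=SESSION_COLUMNS)

    meta = {
        "schema_version": 1,
        "seed": int(protocol.seed),
        "session_index": int(session_index),
        "raw_rate": protocol.raw_rate,
        "window": window,
        "units": dict(UNITS),
        "protocol": asdict(protocol),
        "thermal": asdict(thermal),
        "gait": asdict(gait),
        "strain_sensor": asdict(strain_cfg),
        "metabolic": asdict(metabolic),
        "noise": asdict(noise),
        "teg_models": {cid: m.to_dict() for cid, m in models.items()},
    }
    return SessionRecording(df=df, meta=meta)


def generate_sessions(protocol: ProtocolConfig | None = None, **kwargs) -> list:
    """Generate ``protocol.n_sessions`` independent sessions (one subject,
    repeated runs): same protocol and truth configs, distinct noise and
    gait-jitter realizations per session index."""
    protocol = protocol or ProtocolConfig()
    return [generate_session(protocol, session_index=k, **kwargs)
            for k in range(protocol.n_sessions)]
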