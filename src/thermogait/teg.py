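"""Forward model of a leg-worn flexible thermoelectric generator (TEG).

A TEG strapped to the shank or thigh converts the skin-air temperature
difference into a millivolt signal via the Seebeck effect.  Convective
cooling by the air flow that locomotion induces modulates that signal, so
the same element doubles as a zero-power motion sensor.  The steady-state
response of one channel follows a King's-law calibration extended with the
gait frequency f::

    (V / dT)^2 * f^n = I + J * v^m

i.e.  V = dT * sqrt((I + J v^m) / f^n)

with V the channel output (mV), dT the skin-air temperature difference
(degC), v the locomotion speed (km/h), f the gait frequency (Hz), and
(I, J, m, n) per-channel calibration coefficients with integer exponents.
Four channels are modelled: the DC level and the gait-locked AC amplitude
of the shank and thigh elements.  The thigh AC channel carries n = 3; the
other three carry n = 1.

Units package-wide: mV, degC, km/h, Hz, uW.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, RangeError

CHANNEL_IDS = ("shank_dc", "shank_ac", "thigh_dc", "thigh_ac")

#: Default exponent n per channel: the thigh AC equation carries f cubed.
DEFAULT_N = {"shank_dc": 1, "shank_ac": 1, "thigh_dc": 1, "thigh_ac": 3}


@dataclass(frozen=True)
class TEGChannelModel:
    """Calibrated King's-law coefficients of one TEG sensing channel.

    I is the zero-speed intercept (mV^2 Hz^n), J the convective slope
    (mV^2 Hz^n per (km/h)^m), and m, n small positive integer exponents.
    """

    channel_id: str
    I: float
    J: float
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.channel_id not in CHANNEL_IDS:
            raise DomainError(f"unknown channel_id {self.channel_id!r}")
        if not self.I > 0:
            raise DomainError(f"I must be positive, got {self.I}")
        if self.J < 0:
            raise DomainError(f"J must be non-negative, got {self.J}")
        if self.m not in (1, 2, 3) or self.n not in (1, 2, 3):
            raise DomainError(f"exponents m, n must be in {{1,2,3}}, got m={self.m}, n={self.n}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TEGChannelModel":
        return cls(channel_id=d["channel_id"], I=float(d["I"]), J=float(d["J"]),
                   m=int(d["m"]), n=int(d["n"]))


@dataclass(frozen=True)
class ThermalState:
    """Skin and air temperatures (degC); dT fields are derived exactly."""

    Ts: float
    Tt: float
    Tair: float

    @property
    def dTs(self) -> float:
        return self.Ts - self.Tair

    @property
    def dTt(self) -> float:
        return self.Tt - self.Tair


@dataclass(frozen=True)
class GaitState:
    """Locomotion speed (km/h) and per-leg gait frequencies (Hz)."""

    v: float
    fs: float
    ft: float


def channel_response(model: TEGChannelModel, dT, v, f):
    """Channel output voltage V = dT * sqrt((I + J v^m) / f^n), in mV.

    Parameters are scalars or broadcastable arrays; dT and f must be
    strictly positive, v non-negative.
    """
    dT = np.asarray(dT, dtype=float)
    v = np.asarray(v, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(dT <= 0):
        raise DomainError("dT must be strictly positive")
    if np.any(f <= 0):
        raise DomainError("f must be strictly positive")
    if np.any(v < 0):
        raise DomainError("v must be non-negative")
    out = dT * np.sqrt((model.I + model.J * v ** model.m) / f ** model.n)
    return float(out) if out.ndim == 0 else out


def static_response(model: TEGChannelModel, dT):
    """Output at rest (v = 0, no gait): V = dT * sqrt(I).

    The gait term of the locomotion model is undefined without a stride
    cycle; at rest only the DC thermal pathway remains, equivalent to
    ``channel_response(model, dT, 0, 1)``.
    """
    dT = np.asarray(dT, dtype=float)
    if np.any(dT <= 0):
        raise DomainError("dT must be strictly positive")
    out = dT * np.sqrt(model.I)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Harvested power

#: Anchors (km/h, uW) of the default harvested-power curve: 60 uW at rest,
#: >300 uW once walking, 1600 uW at the 9 km/h top of the characterised range.
DEFAULT_HARVEST_ANCHORS = ((0.0, 60.0), (3.0, 300.0), (9.0, 1600.0))


@dataclass(frozen=True)
class HarvestCurve:
    """Monotone speed -> harvested electrical power map (uW), PCHIP through anchors."""

    anchors: tuple = DEFAULT_HARVEST_ANCHORS

    def __call__(self, v):
        return harvested_power(v, self)


def harvested_power(v, curve: HarvestCurve | None = None):
    """Harvested TEG power (uW) at locomotion speed v in [0, 9] km/h.

    Monotone non-decreasing interpolation through the curve anchors.
    """
    curve = curve or HarvestCurve()
    v = np.asarray(v, dtype=float)
    xs = np.array([a[0] for a in curve.anchors])
    ys = np.array([a[1] for a in curve.anchors])
    if np.any(v < xs[0]) or np.any(v > xs[-1]):
        raise RangeError(f"v must lie within [{xs[0]}, {xs[-1]}] km/h")
    out = PchipInterpolator(xs, ys)(v)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Calibration files

def save_calibration(models: dict, path) -> None:
    """Write a four-channel calibration as JSON keyed by channel_id.

    Absent channels may be marked with ``None``.
    """
    payload = {}
    for cid, model in models.items():
        payload[cid] = None if model is None else model.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_calibration(path) -> dict:
    """Read a calibration JSON written by :func:`save_calibration`."""
    payload = json.loads(Path(path).read_text())
    out = {}
    for cid, d in payload.items():
        out[cid] = None if d is None else TEGChannelModel.from_dict(d)
    return out


def default_generator_models() -> dict:
    """The 'true' channel coefficients the synthetic generator uses.

    Chosen so that, over the treadmill envelope (skin-air dT of roughly
    6-9 degC, speeds 3-8 km/h at the default cadence map), every channel
    output stays inside the characterised 20-90 mV span, and so that the
    AC/DC channel pair of each leg gives a speed-sensitive voltage ratio.
    """
    return {
        "shank_dc": TEGChannelModel("shank_dc", I=9.0, J=6.0, m=1, n=1),
        "shank_ac": TEGChannelModel("shank_ac", I=6.0, J=2.2, m=2, n=1),
        "thigh_dc": TEGChannelModel("thigh_dc", I=12.0, J=8.0, m=1, n=1),
        "thigh_ac": TEGChannelModel("thigh_ac", I=8.0, J=3.0, m=2, n=3),
    }


def default_calibration() -> dict:
    """Shipped four-channel calibration, fitted on the default synthetic
    fixture (six sessions, seed 0) with the calibration module."""
    from importlib.resources import files

    path = files("thermogait").joinpath("data/default_calibration.json")
    payload = json.loads(path.read_text())
    return {cid: (None if d is None else TEGChannelModel.from_dict(d))
            for cid, d in payload.items()}
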