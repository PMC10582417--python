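"""Data-driven fitting of the King's-law channel coefficients.

For a candidate integer exponent pair (m, n) the model

    (V / dT)^2 * f^n = I + J * v^m

is linear in (I, J): regressing y = (V/dT)^2 f^n on x = v^m by ordinary
least squares gives the closed-form coefficient estimates.  The exponent
pair is selected by exhaustive search over a small grid (default
{1,2,3} x {1,2,3}), keeping the candidate with the smallest residual sum
of squares; ties break toward the simpler model (smaller m + n).
Candidates with a non-positive fitted intercept are rejected with a
warning — a negative I has no physical reading (it is the squared static
thermal response).

Fitting rows pair each window's measured voltage feature with the
ground-truth speed and skin-air temperature difference of that window;
:func:`calibration_table` builds them from a recording plus its features,
and :func:`calibrate_all` runs the whole four-channel calibration over a
set of sessions (pooled fitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IdentifiabilityError
from .features import extract_features
from .session import SessionRecording
from .teg import CHANNEL_IDS, TEGChannelModel

log = logging.getLogger(__name__)

#: feature column and truth dT source per channel
_CHANNEL_SOURCES = {
    "shank_dc": ("Vs1", "fs", "dTs"),
    "shank_ac": ("Vs2", "fs", "dTs"),
    "thigh_dc": ("Vt1", "ft", "dTt"),
    "thigh_ac": ("Vt2", "ft", "dTt"),
}


@dataclass
class FitCandidate:
    m: int
    n: int
    I: float
    J: float
    rss: float
    r2: float
    rejected: str | None = None


@dataclass
class FitReport:
    """Per-candidate diagnostics of one channel fit."""

    channel_id: str
    candidates: list = field(default_factory=list)
    best: FitCandidate | None = None
    n_rows: int = 0

    def to_dict(self) -> dict:
        return {
            "channel_id": self.channel_id,
            "n_rows": self.n_rows,
            "best": None if self.best is None else vars(self.best),
            "candidates": [vars(c) for c in self.candidates],
        }


def fit_channel(rows: pd.DataFrame, channel_id: str,
                m_grid=(1, 2, 3), n_grid=(1, 2, 3)) -> tuple:
    """Fit (I, J, m, n) for one channel from windows with ground truth.

    ``rows`` must carry columns V (mV), dT (degC), v (km/h), f (Hz).
    Returns ``(TEGChannelModel, FitReport)``.
    """
    V = rows["V"].to_numpy(dtype=float)
    dT = rows["dT"].to_numpy(dtype=float)
    v = rows["v"].to_numpy(dtype=float)
    f = rows["f"].to_numpy(dtype=float)
    if np.any(dT <= 0):
        raise IdentifiabilityError("all dT must be positive for fitting")
    if np.unique(np.round(v, 6)).size < 2:
        raise IdentifiabilityError(
            f"{channel_id}: J is unidentifiable from a single speed")

    report = FitReport(channel_id=channel_id, n_rows=len(rows))
    for m in m_grid:
        for n in n_grid:
            y = (V / dT) ** 2 * f ** n
            X = np.column_stack([np.ones_like(v), v ** m])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss = float(resid @ resid)
            tss = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - rss / tss if tss > 0 else float("nan")
            cand = FitCandidate(m=m, n=n, I=float(beta[0]), J=float(beta[1]),
                                rss=rss, r2=r2)
            if cand.I <= 0:
                cand.rejected = "non-positive intercept"
                log.warning("%s: candidate (m=%d, n=%d) rejected, fitted I=%.3g <= 0",
                            channel_id, m, n, cand.I)
            elif cand.J < 0:
                cand.rejected = "negative slope"
            report.candidates.append(cand)

    admissible = [c for c in report.candidates if c.rejected is None]
    if not admissible:
        raise IdentifiabilityError(f"{channel_id}: no admissible (m, n) candidate")
    best = min(admissible, key=lambda c: (c.rss, c.m + c.n))
    report.best = best
    model = TEGChannelModel(channel_id=channel_id, I=best.I, J=best.J,
                            m=best.m, n=best.n)
    return model, report


def calibration_table(recording: SessionRecording, features: pd.DataFrame | None = None,
                      window: float = 2.0) -> dict:
    """Per-channel fitting rows (V, dT, v, f) from one annotated recording.

    Uses measured window features for V and f, and window means of the
    ground-truth labels for v and dT.  Only valid, active windows with a
    constant protocol speed enter the table.  Channels whose feature
    columns are entirely missing/NaN map to ``None`` (absent marker).
    """
    if features is None:
        features = extract_features(recording, window=window)
    df = recording.df
    rate = recording.raw_rate
    n_per = int(round(window * rate))

    truth = []
    for k in range(len(features)):
        sl = slice(k * n_per, (k + 1) * n_per)
        chunk = df.iloc[sl]
        v_vals = chunk["v_true"].to_numpy()
        truth.append({
            "v": float(v_vals.mean()),
            "v_pure": bool(np.ptp(v_vals) == 0),
            "dTs": float((chunk["Ts_true"] - chunk["Tair"]).mean()),
            "dTt": float((chunk["Tt_true"] - chunk["Tair"]).mean()),
        })
    truth = pd.DataFrame(truth)

    usable = features["valid"] & features["active"] & truth["v_pure"]
    out = {}
    for cid in CHANNEL_IDS:
        vcol, fcol, dtcol = _CHANNEL_SOURCES[cid]
        if vcol not in features.columns or features.loc[usable, vcol].isna().all():
            out[cid] = None
            continue
        out[cid] = pd.DataFrame({
            "V": features.loc[usable, vcol].to_numpy(),
            "dT": truth.loc[usable, dtcol].to_numpy(),
            "v": truth.loc[usable, "v"].to_numpy(),
            "f": features.loc[usable, fcol].to_numpy(),
        })
    return out


def calibrate_all(sessions, window: float = 2.0,
                  m_grid=(1, 2, 3), n_grid=(1, 2, 3)) -> tuple:
    """Pooled four-channel calibration over a list of sessions.

    Returns ``(models, reports)`` dicts keyed by channel_id; channels with
    no usable data are marked ``None`` in both (explicit absent marker).
    Fitting errors are re-raised with the channel id as context.
    """
    pooled: dict = {cid: [] for cid in CHANNEL_IDS}
    for rec in sessions:
        table = calibration_table(rec, window=window)
        for cid in CHANNEL_IDS:
            if table[cid] is not None:
                pooled[cid].append(table[cid])

    models, reports = {}, {}
    for cid in CHANNEL_IDS:
        if not pooled[cid]:
            models[cid], reports[cid] = None, None
            log.warning("channel %s absent from all sessions; marked None", cid)
            continue
        rows = pd.concat(pooled[cid], ignore_index=True)
        try:
            models[cid], reports[cid] = fit_channel(rows, cid, m_grid, n_grid)
        except IdentifiabilityError as err:
            raise IdentifiabilityError(f"channel {cid}: {err}") from err
    return models, reports
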