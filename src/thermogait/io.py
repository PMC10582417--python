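"""Session/feature/estimate file plumbing with schema validation.

Sessions are stored as human-inspectable CSV time series (one row per
sample, fixed column order) with a JSON sidecar carrying configs, seed,
units and schema version.  Readers validate the header and the units
contract before returning data; floats are written with shortest-repr
formatting so a write-read round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import SchemaError
from .session import SESSION_COLUMNS, UNITS, SessionRecording


def _meta_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_name(p.stem + ".meta.json")


def write_session(rec: SessionRecording, csv_path) -> None:
    """Write a recording as ``<name>.csv`` + ``<name>.meta.json``."""
    csv_path = Path(csv_path)
    # 17 significant digits guarantee a bit-exact float64 round trip
    rec.df.to_csv(csv_path, index=False, float_format="%.17g")
    _meta_path(csv_path).write_text(json.dumps(rec.meta, indent=2) + "\n")


def read_session(csv_path) -> SessionRecording:
    """Read a session, validating header, units and NaN policy."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    try:
        df = df.astype(float)  # schema is all-float; integers are rendered floats
    except ValueError as err:
        raise SchemaError(f"non-numeric values in session file: {err}") from err
    if list(df.columns) != SESSION_COLUMNS:
        missing = [c for c in SESSION_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in SESSION_COLUMNS]
        raise SchemaError(
            f"session header mismatch: missing {missing}, unexpected {extra}")
    bad = [c for c in df.columns if df[c].isna().any()]
    if bad:
        raise SchemaError(f"NaNs present in columns {bad}")
    meta_file = _meta_path(csv_path)
    if not meta_file.exists():
        raise SchemaError(f"missing metadata sidecar {meta_file.name}")
    meta = json.loads(meta_file.read_text())
    units = meta.get("units")
    if units is None:
        raise SchemaError("metadata lacks required 'units' field")
    wrong = {c: u for c, u in units.items() if UNITS.get(c) != u}
    if wrong:
        raise SchemaError(f"unit contract violated: {wrong} (expected {UNITS})")
    if "raw_rate" not in meta:
        raise SchemaError("metadata lacks required 'raw_rate' field")
    return SessionRecording(df=df, meta=meta)


def read_sessions(directory, pattern: str = "session_*.csv") -> list:
    """Read all sessions matching ``pattern`` under ``directory``, sorted."""
    paths = sorted(Path(directory).glob(pattern))
    if not paths:
        raise SchemaError(f"no sessions matching {pattern!r} in {directory}")
    return [read_session(p) for p in paths]


def write_sessions(recs, directory) -> list:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, rec in enumerate(recs):
        p = directory / f"session_{k}.csv"
        write_session(rec, p)
        paths.append(p)
    return paths


def write_manifest(outdir, seed, configs: dict | None = None) -> Path:
    """Reproducibility manifest: seed, configs and package version."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps({
        "package": "thermogait",
        "version": __version__,
        "seed": int(seed),
        "configs": configs or {},
    }, indent=2, default=str) + "\n")
    return path
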