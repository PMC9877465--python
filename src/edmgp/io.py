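"""Record readers/writers and a documented simple preprocessor.

The primary on-disk format is CSV with a header row (columns ``time``,
``fhr_bpm``, ``ua``; UTF-8, comma-separated, NaN or empty cell = missing).
PhysioNet WFDB reading is available only when the optional ``wfdb`` package
is installed.

Preprocessing (a deliberately simple, fully documented pipeline):
1. FHR samples equal to 0 or outside the physiological display range
   [50, 210] bpm are marked missing;
2. gaps no longer than a threshold (default 5 s) are linearly interpolated;
   longer gaps are left missing for the imputation module;
3. optional truncation to the first 30 minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .series import TimeSeries

__all__ = ["CTGRecord", "PreprocessConfig", "read_record", "write_record", "preprocess"]

logger = logging.getLogger("edmgp")

FHR_VALID_RANGE = (50.0, 210.0)


@dataclass
class CTGRecord:
    record_id: str
    fhr: TimeSeries
    ua: Optional[TimeSeries] = None
    clinical: Dict[str, float] = field(default_factory=dict)

    def require_ua(self) -> TimeSeries:
        if self.ua is None or self.ua.missing.all():
            raise ValueError(
                f"record {self.record_id!r} has no usable UA channel; "
                "this operation requires UA"
            )
        return self.ua


@dataclass
class PreprocessConfig:
    valid_range: tuple = FHR_VALID_RANGE
    interp_gap_s: float = 5.0
    truncate_min: Optional[float] = None  # e.g. 30.0 for the first 30 minutes


def read_record(path, fmt: str = "csv", fs: float = 4.0) -> CTGRecord:
    """Load a CTG record from disk.

    CSV needs columns ``fhr_bpm`` (and optionally ``time``, ``ua``); extra
    numeric columns are passed through as clinical scalars if constant.
    """
    path = Path(path)
    if fmt == "wfdb":
        return _read_wfdb(path)
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise ValueError(f"could not parse {path}: {err}") from err
    if "fhr_bpm" not in df.columns:
        raise ValueError(f"{path}: missing required column 'fhr_bpm'")
    if "time" in df.columns and len(df) > 1:
        dt = np.diff(df["time"].to_numpy())
        if dt.size and np.nanmedian(dt) > 0:
            fs = 1.0 / float(np.nanmedian(dt))
    fhr = TimeSeries(df["fhr_bpm"].to_numpy(float), fs=fs, name="fhr_bpm")
    ua = None
    if "ua" in df.columns:
        ua = TimeSeries(df["ua"].to_numpy(float), fs=fs, name="ua")
    clinical = {}
    for col in df.columns:
        if col in ("time", "fhr_bpm", "ua"):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.nunique(dropna=True) == 1:
            clinical[col] = float(vals.dropna().iloc[0])
    return CTGRecord(record_id=path.stem, fhr=fhr, ua=ua, clinical=clinical)


def _read_wfdb(path: Path) -> CTGRecord:  # pragma: no cover - optional dependency
    try:
        import wfdb
    except ImportError as err:
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "convert the record to CSV or install wfdb"
        ) from err
    rec = wfdb.rdrecord(str(path))
    names = [n.upper() for n in rec.sig_name]
    fs = float(rec.fs)
    sig = rec.p_signal

    def channel(keys):
        for k in keys:
            if k in names:
                return sig[:, names.index(k)]
        return None

    fhr_v = channel(["FHR", "FHR1"])
    if fhr_v is None:
        raise ValueError(f"{path}: no FHR channel found")
    ua_v = channel(["UC", "UA", "TOCO"])
    fhr = TimeSeries(np.asarray(fhr_v, float), fs=fs, name="fhr_bpm")
    ua = TimeSeries(np.asarray(ua_v, float), fs=fs, name="ua") if ua_v is not None else None
    return CTGRecord(record_id=path.stem, fhr=fhr, ua=ua)


def write_record(record: CTGRecord, path) -> None:
    """Write a record as CSV (time, fhr_bpm[, ua]); NaN cells mark missing."""
    path = Path(path)
    data = {"time": record.fhr.times, "fhr_bpm": record.fhr.values}
    if record.ua is not None:
        data["ua"] = record.ua.values
    df = pd.DataFrame(data)
    df.to_csv(path, index=False, float_format="%.6g")


def _interpolate_short_gaps(ts: TimeSeries, max_gap_s: float) -> tuple[TimeSeries, int]:
    v = ts.values.copy()
    miss = np.isnan(v)
    if not miss.any():
        return TimeSeries(v, fs=ts.fs, name=ts.name), 0
    max_len = int(round(max_gap_s * ts.fs))
    filled = 0
    i = 0
    n = v.size
    while i < n:
        if not miss[i]:
            i += 1
            continue
        j = i
        while j < n and miss[j]:
            j += 1
        gap = j - i
        # interior gaps only: need observed anchors on both sides
        if gap <= max_len and i > 0 and j < n:
            v[i:j] = np.interp(np.arange(i, j), [i - 1, j], [v[i - 1], v[j]])
            filled += gap
        i = j
    return TimeSeries(v, fs=ts.fs, name=ts.name), filled


def preprocess(record: CTGRecord, config: Optional[PreprocessConfig] = None) -> CTGRecord:
    """Apply the documented simple preprocessing pipeline (idempotent)."""
    cfg = config or PreprocessConfig()
    fhr = record.fhr.copy()
    lo, hi = cfg.valid_range
    v = fhr.values
    bad = (~np.isnan(v)) & ((v == 0) | (v < lo) | (v > hi))
    if bad.any():
        logger.info("record %s: %d samples outside [%g, %g] bpm marked missing",
                    record.record_id, int(bad.sum()), lo, hi)
    v[bad] = np.nan
    fhr = TimeSeries(v, fs=fhr.fs, name=fhr.name)
    fhr, filled = _interpolate_short_gaps(fhr, cfg.interp_gap_s)
    if filled:
        logger.info("record %s: %d samples in short gaps interpolated",
                    record.record_id, filled)
    ua = record.ua.copy() if record.ua is not None else None
    if cfg.truncate_min is not None:
        n = int(round(cfg.truncate_min * 60 * fhr.fs))
        fhr = TimeSeries(fhr.values[:n], fs=fhr.fs, name=fhr.name)
        if ua is not None:
            ua = TimeSeries(ua.values[:n], fs=ua.fs, name=ua.name)
    return CTGRecord(record.record_id, fhr, ua, dict(record.clinical))
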