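"""Uniformly sampled time series with an explicit missing-sample mask.

The whole package works on signals sampled on a regular grid (CTG devices
record fetal heart rate and uterine activity at 4 Hz).  Missing samples are
stored as NaN in ``values`` and mirrored in ``missing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values:
        Sample values; NaN marks a missing sample.
    fs:
        Sampling rate in Hz.
    name:
        Optional channel name (e.g. ``"fhr_bpm"``).
    """

    values: np.ndarray
    fs: float = 4.0
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the sample is missing."""
        return np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from the start of the record."""
        return np.arange(self.n) / self.fs

    def copy(self) -> "TimeSeries":
        return TimeSeries(self.values.copy(), fs=self.fs, name=self.name)

    def require_complete(self, context: str = "this operation") -> np.ndarray:
        if self.missing.any():
            raise ValueError(
                f"series has {self.n_missing} missing samples; {context} requires a "
                "complete series (impute or interpolate first)"
            )
        return self.values

    def standardized(self) -> "TimeSeries":
        """Zero-mean, unit-variance copy (missing samples ignored in the moments)."""
        v = self.values
        mu = np.nanmean(v)
        sd = np.nanstd(v)
        if sd == 0:
            sd = 1.0
        return TimeSeries((v - mu) / sd, fs=self.fs, name=self.name)


def as_series(x, fs: float = 4.0, name: str = "") -> TimeSeries:
    if isinstance(x, TimeSeries):
        return x
    return TimeSeries(np.asarray(x, dtype=float), fs=fs, name=name)
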