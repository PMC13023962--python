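"""Core containers shared by every stage of the pipeline.

A :class:`TimeSeries` is one channel of a uniformly sampled recording plus
its provenance (subject, region, channel, demographics).  A :class:`Band`
is a closed frequency interval on which a power law is fitted.  The two
analysis bands used throughout — a low scale-free band below the alpha
rhythm and a high (gamma) band above the beta rhythm — are exposed as
module constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

__all__ = ["TimeSeries", "Band", "LOW_BAND", "HIGH_BAND", "GAMMA_BAND"]


def _require(condition: bool, field_name: str, message: str) -> None:
    """Raise a ValueError naming the offending field."""
    if not condition:
        raise ValueError(f"{field_name}: {message}")


@dataclass
class TimeSeries:
    """One channel of a uniformly sampled signal.

    Parameters
    ----------
    samples : array-like of float
        Signal values in arbitrary units (conventionally microvolts).
    fs : float
        Sampling rate in Hz.
    subject_id, region, channel_id : str, optional
        Provenance labels used by the hierarchical cohort statistics.
    age : float, optional
        Subject age in years.
    sex : str, optional
        Subject sex, free-form categorical (e.g. ``"M"`` / ``"F"``).
    meta : dict
        Free-form provenance, e.g. the filter applied by
        :func:`scalefree.filtering.apply_filter`.
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None
    region: str | None = None
    channel_id: str | None = None
    age: float | None = None
    sex: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        _require(self.samples.ndim == 1, "samples", "must be one-dimensional")
        _require(self.samples.size >= 2, "samples", "need at least 2 samples")
        _require(np.all(np.isfinite(self.samples)), "samples",
                 "contains non-finite values")
        _require(self.fs > 0, "fs", "sampling rate must be positive")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0

    def with_samples(self, samples: np.ndarray,
                     extra_meta: Mapping[str, Any] | None = None) -> "TimeSeries":
        """Copy of this series with new sample values (same provenance)."""
        new = replace(self, samples=np.asarray(samples, dtype=np.float64),
                      meta=dict(self.meta))
        if extra_meta:
            new.meta.update(extra_meta)
        return new


@dataclass(frozen=True)
class Band:
    """Closed frequency interval ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        _require(self.f_lo > 0, "f_lo", "must be positive (DC is never fitted)")
        _require(self.f_hi > self.f_lo, "f_hi", "must exceed f_lo")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of grid frequencies inside the closed interval."""
        freqs = np.asarray(freqs, dtype=float)
        return (freqs >= self.f_lo) & (freqs <= self.f_hi)


#: Low scale-free band, below the delta/theta oscillatory range.
LOW_BAND = Band("low", 0.5, 4.0)

#: High scale-free band; identical to the gamma range used for band power.
HIGH_BAND = Band("high", 33.0, 80.0)

#: Alias used when averaging normalized power ("gamma band power").
GAMMA_BAND = Band("gamma", 33.0, 80.0)
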