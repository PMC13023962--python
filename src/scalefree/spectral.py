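"""Welch power spectral density estimation and band utilities.

The PSD of each (possibly band-isolated) channel is estimated with
Welch's method: Hamming-windowed overlapping segments, 2048-point FFT by
default, which at a 200 Hz sampling rate corresponds to ~10 s segments
and a frequency resolution of ~0.098 Hz.  Band utilities slice the
one-sided spectrum to a closed frequency interval and compute the mean
(optionally total-power-normalized) band power used for the gamma-band
power statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import signal

from .containers import Band, TimeSeries, _require

__all__ = ["SpectrumEstimate", "BandPower", "welch_psd", "band_slice",
           "mean_band_power", "full_band"]


@dataclass
class SpectrumEstimate:
    """One-sided PSD on a uniform frequency grid.

    ``psd`` is density-scaled (signal-units²/Hz).  ``settings`` records
    how the estimate was produced; ``meta`` carries channel provenance,
    including any :class:`~scalefree.filtering.FilterSpec` applied before
    estimation (needed for response compensation during fitting).
    """

    freqs: np.ndarray
    psd: np.ndarray
    settings: dict[str, Any] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.psd = np.asarray(self.psd, dtype=np.float64)
        _require(self.freqs.shape == self.psd.shape, "psd",
                 "freqs and psd must have equal length")
        _require(self.freqs.size >= 2, "freqs", "need at least two bins")
        _require(np.all(np.diff(self.freqs) > 0), "freqs", "must be ascending")
        _require(np.all(self.psd >= 0), "psd", "PSD values must be non-negative")

    @property
    def df(self) -> float:
        """Frequency grid spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class BandPower:
    """Mean (optionally normalized) PSD over a band."""

    value: float
    band: Band
    normalization: str


def welch_psd(ts: TimeSeries, nperseg: int = 2048, nfft: int | None = None,
              overlap: float = 0.5, window: str = "hamming",
              detrend: str = "constant") -> SpectrumEstimate:
    """Welch PSD of a channel.

    Parameters
    ----------
    ts : TimeSeries
    nperseg : int
        Segment length in samples (default 2048 ≈ 10 s at 200 Hz).
    nfft : int, optional
        FFT length; defaults to ``nperseg`` (no zero padding).
    overlap : float
        Fractional segment overlap in [0, 1), default 0.5.
    window, detrend : str
        Taper (default Hamming) and per-segment detrending mode
        (default constant, i.e. mean removal).

    Returns
    -------
    SpectrumEstimate
        One-sided, density-scaled, with DC included; resolution ``fs/nfft``.
    """
    nperseg = int(nperseg)
    _require(nperseg >= 8, "nperseg", "unreasonably short segment")
    _require(0 <= overlap < 1, "overlap", "must be in [0, 1)")
    if nfft is None:
        nfft = nperseg
    _require(nfft >= nperseg, "nfft", "must be >= nperseg")
    if ts.n < nperseg:
        raise ValueError(
            f"samples: signal of {ts.n} samples is shorter than one Welch "
            f"segment (nperseg={nperseg}); need at least {nperseg} samples")
    noverlap = int(round(nperseg * overlap))
    freqs, psd = signal.welch(
        ts.samples, fs=ts.fs, window=signal.get_window(window, nperseg),
        nperseg=nperseg, noverlap=noverlap, nfft=nfft, detrend=detrend,
        return_onesided=True, scaling="density")
    settings = {"nperseg": nperseg, "nfft": int(nfft), "overlap": overlap,
                "window": window, "detrend": detrend, "fs": ts.fs}
    meta = dict(ts.meta)
    meta.update({"subject_id": ts.subject_id, "region": ts.region,
                 "channel_id": ts.channel_id})
    return SpectrumEstimate(freqs, psd, settings=settings, meta=meta)


def band_slice(sp: SpectrumEstimate, band: Band) -> SpectrumEstimate:
    """Bins with ``f_lo <= f <= f_hi`` (closed interval, DC never included)."""
    mask = band.contains(sp.freqs) & (sp.freqs > 0)
    if not mask.any():
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz selects no bins "
            f"on a grid with spacing {sp.df:g} Hz")
    meta = dict(sp.meta)
    meta["band"] = band
    return SpectrumEstimate(sp.freqs[mask], sp.psd[mask],
                            settings=dict(sp.settings), meta=meta)


def full_band(sp: SpectrumEstimate, name: str = "full") -> Band:
    """Band covering the whole grid except DC."""
    positive = sp.freqs[sp.freqs > 0]
    return Band(name, float(positive[0]), float(sp.freqs[-1]))


def mean_band_power(sp: SpectrumEstimate, band: Band,
                    normalize: str = "unit_total") -> BandPower:
    """Arithmetic mean PSD over a band's bins.

    With ``normalize="unit_total"`` the spectrum is first rescaled so that
    its integral over (0, fs/2] equals one, making the band mean a
    dimensionless fraction-like quantity comparable across recordings;
    ``"none"`` averages the raw density.
    """
    _require(normalize in ("unit_total", "none"), "normalize",
             "must be 'unit_total' or 'none'")
    psd = sp.psd
    if normalize == "unit_total":
        total = float(np.sum(psd[sp.freqs > 0]) * sp.df)
        if total <= 0:
            raise ValueError("psd: zero total power, cannot normalize")
        psd = psd / total
    mask = band.contains(sp.freqs) & (sp.freqs > 0)
    if not mask.any():
        raise ValueError(f"band {band.name} selects no bins")
    return BandPower(float(np.mean(psd[mask])), band, normalize)
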