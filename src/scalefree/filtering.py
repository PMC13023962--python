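"""Butterworth band isolation.

Narrowband oscillations (most prominently the alpha rhythm at 8–12 Hz) sit
on top of the aperiodic 1/f^beta background and bias log-log slope fits.
The pipeline therefore isolates each analysis band with a Butterworth
filter before spectral estimation: a low-pass (default 7th order, 8 Hz)
for the low band and a high-pass (default 7th order, 33 Hz) for the high
band.  Filtering is zero-phase (forward-backward) by default, which is
appropriate for offline analysis and squares the magnitude response.

The filter's own in-band roll-off is deterministic; downstream fitting
divides it out of the PSD (see :func:`scalefree.powerlaw.compensate_filter`),
so the filter's only analytic role is suppressing out-of-band power and
its spectral leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import TimeSeries, _require

__all__ = [
    "FilterSpec",
    "DEFAULT_LOWPASS",
    "DEFAULT_HIGHPASS",
    "butterworth_gain",
    "design_sos",
    "filter_psd_attenuation",
    "apply_filter",
]

_KINDS = ("lowpass", "highpass")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter description.

    ``zero_phase=True`` applies the filter forward and backward
    (``sosfiltfilt``): zero phase lag, squared magnitude response.
    """

    kind: str
    order: int = 7
    cutoff_hz: float = 8.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        _require(self.kind in _KINDS, "kind", f"must be one of {_KINDS}")
        _require(int(self.order) >= 1, "order", "must be a positive integer")
        _require(self.cutoff_hz > 0, "cutoff_hz", "must be positive")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "order": self.order,
                "cutoff_hz": self.cutoff_hz, "zero_phase": self.zero_phase}

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(**d)


DEFAULT_LOWPASS = FilterSpec("lowpass", order=7, cutoff_hz=8.0)
DEFAULT_HIGHPASS = FilterSpec("highpass", order=7, cutoff_hz=33.0)


def butterworth_gain(spec: FilterSpec, freq):
    """Analog Butterworth magnitude response at ``freq`` (Hz).

    ``1/sqrt(1 + (f/fc)^2n)`` for a low-pass and ``1/sqrt(1 + (fc/f)^2n)``
    for a high-pass: unity deep in the passband, ``1/sqrt(2)`` (−3.01 dB)
    at the cutoff.  The high-pass limit at ``freq=0`` is defined as 0.

    This is the single-pass analog magnitude; it does not include the
    zero-phase squaring nor the bilinear-transform warping of the digital
    implementation (for those see :func:`filter_psd_attenuation`).
    """
    freq = np.asarray(freq, dtype=float)
    _require(np.all(freq >= 0), "freq", "must be non-negative")
    n = spec.order
    if spec.kind == "lowpass":
        ratio = freq / spec.cutoff_hz
        gain = 1.0 / np.sqrt(1.0 + ratio ** (2 * n))
    else:
        with np.errstate(divide="ignore"):
            ratio = np.where(freq > 0, spec.cutoff_hz / np.maximum(freq, 1e-300), np.inf)
        gain = np.where(freq > 0, 1.0 / np.sqrt(1.0 + ratio ** (2 * n)), 0.0)
    return gain if gain.ndim else float(gain)


def design_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Digital (bilinear) Butterworth design in second-order sections."""
    _require(spec.cutoff_hz < fs / 2, "cutoff_hz",
             f"must be below the Nyquist frequency {fs / 2:g} Hz")
    return signal.butter(spec.order, spec.cutoff_hz, btype=spec.kind,
                         fs=fs, output="sos")


def filter_psd_attenuation(spec: FilterSpec, freqs, fs: float) -> np.ndarray:
    """Multiplicative PSD attenuation of the digital filter at ``freqs``.

    Equals ``|H(f)|^2`` for single-pass filtering and ``|H(f)|^4`` for
    zero-phase (forward-backward) filtering, where ``H`` is the digital
    transfer function actually applied by :func:`apply_filter`.
    """
    sos = design_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs, float)), fs=fs)
    mag2 = np.abs(h) ** 2
    return mag2 ** 2 if spec.zero_phase else mag2


def _padlen(sos: np.ndarray) -> int:
    # same quantity scipy.signal.sosfiltfilt uses by default
    ntaps = 2 * sos.shape[0] + 1
    return 3 * ntaps


def apply_filter(ts: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Filter a time series, recording the filter in ``meta['filter']``.

    Raises if the cutoff is at/above Nyquist or the signal is too short
    for stable edge handling (odd-reflection padding of three times the
    filter's tap count).
    """
    sos = design_sos(spec, ts.fs)
    pad = _padlen(sos)
    _require(ts.n > pad, "samples",
             f"signal of {ts.n} samples too short to filter stably "
             f"(needs > {pad} samples for order {spec.order})")
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, ts.samples, padtype="odd", padlen=pad)
    else:
        out = signal.sosfilt(sos, ts.samples)
    return ts.with_samples(out, extra_meta={"filter": spec})
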