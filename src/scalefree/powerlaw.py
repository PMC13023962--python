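"""Power-law (1/f^beta) exponent estimation on log-log spectra.

The aperiodic exponent beta is the negated slope of a straight-line fit
to log10(PSD) versus log10(f) inside an analysis band.  Single channels
are fitted with unit weights; region-level mean spectra are fitted by
weighted least squares with per-bin weights ``w_i = 1/dy_i^2``, where
``dy_i`` is the cross-population standard deviation of the log-PSD at
bin ``i`` (obtained from the linear-domain SD by first-order error
propagation, ``dy_i = sigma_i / (psd_i * ln 10)``).

If the spectrum was produced from a filtered signal, the filter's known
magnitude response is divided out of the PSD inside the fit band before
the log transform, so the estimated slope reflects the signal, not the
filter skirt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .containers import Band, TimeSeries, _require
from .filtering import FilterSpec, apply_filter, filter_psd_attenuation
from .spectral import SpectrumEstimate, welch_psd

__all__ = ["LogLogPoints", "PowerLawFit", "DeltaBetaMap", "to_loglog",
           "wls_fit", "compensate_filter", "fit_band_exponent", "delta_beta"]

LN10 = math.log(10.0)

#: Attenuation below which filter-response compensation is refused: at
#: this depth the measured PSD is leakage/noise floor, not signal.
MIN_COMPENSATION_GAIN = 1e-10


@dataclass
class LogLogPoints:
    """Log-log regression inputs: x=log10(f), y=log10(PSD), optional dy."""

    x: np.ndarray
    y: np.ndarray
    dy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        _require(self.x.shape == self.y.shape, "y", "x and y lengths differ")
        _require(np.all(np.isfinite(self.x)), "x", "non-finite values")
        _require(np.all(np.isfinite(self.y)), "y", "non-finite values")
        if self.dy is not None:
            self.dy = np.asarray(self.dy, dtype=np.float64)
            _require(self.dy.shape == self.x.shape, "dy", "length differs from x")
            _require(np.all(np.isfinite(self.dy)), "dy", "non-finite values")
            _require(np.all(self.dy > 0), "dy", "uncertainties must be positive")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def weights(self) -> np.ndarray:
        """w_i = 1/dy_i^2, or unit weights when no uncertainties given."""
        if self.dy is None:
            return np.ones_like(self.x)
        return 1.0 / self.dy**2


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log straight-line fit.

    ``beta`` is the negated slope, stored signed: a decaying spectrum
    gives positive beta.  ``abs_beta`` is the magnitude conventionally
    reported.  The intercept is in log10(PSD) units at log10(f)=0,
    i.e. at 1 Hz.
    """

    beta: float
    intercept: float
    se_beta: float
    se_intercept: float
    band: Band
    n_points: int
    r_squared: float

    @property
    def abs_beta(self) -> float:
        return abs(self.beta)


@dataclass(frozen=True)
class DeltaBetaMap:
    """Min-max normalized exponents across regions, each in [0, 1]."""

    values: Mapping[str, float]
    beta_min: float
    beta_max: float


def to_loglog(sp: SpectrumEstimate, band: Band,
              sigma: np.ndarray | None = None,
              sigma_is_log: bool = False) -> LogLogPoints:
    """Log-transform a band of the spectrum for straight-line fitting.

    Parameters
    ----------
    sp : SpectrumEstimate
    band : Band
    sigma : ndarray, optional
        Per-bin uncertainty on the same grid as ``sp.freqs``.  By default
        interpreted as a standard deviation in linear PSD units and
        propagated to log10 units as ``dy = sigma/(psd * ln 10)``; pass
        ``sigma_is_log=True`` if it is already the SD of log10(PSD).

    Raises
    ------
    ValueError
        If any in-band PSD value is not strictly positive (cannot be
        log-transformed; symptomatic of fitting inside a filter stopband).
    """
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=np.float64)
        _require(sigma.shape == sp.freqs.shape, "sigma",
                 "must be on the same grid as the spectrum")
    mask = band.contains(sp.freqs) & (sp.freqs > 0)
    if not mask.any():
        raise ValueError(f"band {band.name} selects no bins")
    psd = sp.psd[mask]
    if np.any(psd <= 0):
        raise ValueError(
            f"psd: {int(np.sum(psd <= 0))} non-positive PSD bins inside band "
            f"{band.name}; cannot log-transform")
    x = np.log10(sp.freqs[mask])
    y = np.log10(psd)
    dy = None
    if sigma is not None:
        s = sigma[mask]
        _require(np.all(s > 0), "sigma", "in-band uncertainties must be positive")
        dy = s if sigma_is_log else s / (psd * LN10)
    return LogLogPoints(x, y, dy)


def wls_fit(points: LogLogPoints, band: Band | None = None) -> PowerLawFit:
    """Weighted least-squares straight line through log-log points.

    Solves the two-parameter weighted normal equations in closed form.
    Standard errors come from the weighted parameter covariance scaled by
    the weighted residual mean square (so an exactly collinear input has
    zero standard errors regardless of the weights' overall scale).
    """
    if points.n < 3:
        raise ValueError(f"n_points: need at least 3 points, got {points.n}")
    w = points.weights
    _require(np.all(w > 0), "weights", "must be strictly positive")
    x, y = points.x, points.y
    sw = np.sum(w)
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx <= 0:
        raise ValueError("x: zero spread in log-frequency; cannot fit a slope")
    sxy = np.sum(w * (x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    dof = points.n - 2
    mse = ss_res / dof
    se_slope = math.sqrt(max(mse / sxx, 0.0))
    se_intercept = math.sqrt(max(mse * (1.0 / sw + xbar**2 / sxx), 0.0))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if band is None:
        band = Band("fit", 10 ** float(x.min()), 10 ** float(x.max()))
    return PowerLawFit(beta=-slope, intercept=intercept, se_beta=se_slope,
                       se_intercept=se_intercept, band=band,
                       n_points=points.n, r_squared=r2)


def _passband_restriction(sp: SpectrumEstimate, band: Band) -> Band:
    """Intersect a fit band with the recorded filter's nominal passband.

    Bins beyond the cutoff sit in the filter's stopband where the
    measured PSD is dominated by spectral leakage rather than attenuated
    signal, so response compensation cannot recover them; they are
    excluded from the fit instead.
    """
    filt = sp.meta.get("filter")
    if filt is None:
        return band
    if isinstance(filt, dict):
        filt = FilterSpec.from_dict(filt)
    if filt.kind == "lowpass":
        f_lo, f_hi = band.f_lo, min(band.f_hi, filt.cutoff_hz)
    else:
        f_lo, f_hi = max(band.f_lo, filt.cutoff_hz), band.f_hi
    if not f_lo < f_hi:
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz lies outside the "
            f"{filt.kind} passband (cutoff {filt.cutoff_hz} Hz)")
    if (f_lo, f_hi) == (band.f_lo, band.f_hi):
        return band
    return Band(band.name, f_lo, f_hi)


def compensate_filter(sp: SpectrumEstimate, band: Band) -> tuple[np.ndarray, np.ndarray]:
    """In-band PSD with the recorded filter's response divided out.

    Returns ``(attenuation, psd_compensated)`` on the *full* grid, with
    the attenuation set to 1 outside the requested band (compensating a
    deep stopband would only amplify the leakage floor).  If no filter is
    recorded in ``sp.meta`` the PSD is returned unchanged.
    """
    filt = sp.meta.get("filter")
    if filt is None:
        return np.ones_like(sp.psd), sp.psd
    if isinstance(filt, dict):
        filt = FilterSpec.from_dict(filt)
    fs = sp.settings.get("fs", 2.0 * sp.freqs[-1])
    att = np.ones_like(sp.psd)
    mask = band.contains(sp.freqs) & (sp.freqs > 0)
    att[mask] = filter_psd_attenuation(filt, sp.freqs[mask], fs)
    if np.any(att[mask] < MIN_COMPENSATION_GAIN):
        raise ValueError(
            f"band {band.name} reaches {filt.kind} attenuation below "
            f"{MIN_COMPENSATION_GAIN:g}; the band is incompatible with the filter")
    return att, sp.psd / att


def fit_band_exponent(data: TimeSeries | SpectrumEstimate, band: Band,
                      filter_spec: FilterSpec | None = None,
                      sigma: np.ndarray | None = None,
                      sigma_is_log: bool = False,
                      compensate: bool = True,
                      **welch_kwargs) -> PowerLawFit:
    """Estimate the aperiodic exponent of one band.

    For a :class:`TimeSeries` this composes the full single-channel
    pipeline: optional band-isolation filter, Welch PSD, filter-response
    compensation, log-log transform (unit weights) and least squares.
    For a :class:`SpectrumEstimate` (e.g. a region's mean spectrum) the
    filtering stage is skipped and ``sigma`` supplies the per-bin
    population SD for the weighted fit.

    ``welch_kwargs`` are forwarded to :func:`scalefree.spectral.welch_psd`.
    """
    if isinstance(data, TimeSeries):
        ts = apply_filter(data, filter_spec) if filter_spec is not None else data
        sp = welch_psd(ts, **welch_kwargs)
    else:
        if filter_spec is not None:
            raise ValueError(
                "filter_spec: cannot filter an already-estimated spectrum; "
                "filter the time series instead")
        sp = data
    if compensate:
        band = _passband_restriction(sp, band)
        att, psd = compensate_filter(sp, band)
        sp = SpectrumEstimate(sp.freqs, psd, settings=dict(sp.settings),
                              meta={k: v for k, v in sp.meta.items()
                                    if k != "filter"})
        if sigma is not None and not sigma_is_log:
            sigma = np.asarray(sigma, dtype=np.float64) / att
    points = to_loglog(sp, band, sigma=sigma, sigma_is_log=sigma_is_log)
    return wls_fit(points, band=band)


def delta_beta(betas: Mapping[str, float]) -> DeltaBetaMap:
    """Min-max normalization of region exponents onto [0, 1].

    ``delta_beta_i = (beta_i - beta_min) / (beta_max - beta_min)``; the
    smallest-exponent region maps to 0, the largest to 1.
    """
    if len(betas) < 2:
        raise ValueError("betas: need at least two regions")
    vals = np.array(list(betas.values()), dtype=float)
    _require(np.all(np.isfinite(vals)), "betas", "non-finite exponent")
    bmin, bmax = float(vals.min()), float(vals.max())
    if bmax <= bmin:
        raise ValueError("betas: all exponents equal; normalization range is "
                         "degenerate")
    return DeltaBetaMap(
        values={k: (float(v) - bmin) / (bmax - bmin) for k, v in betas.items()},
        beta_min=bmin, beta_max=bmax)
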