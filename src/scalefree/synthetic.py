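"""Synthetic signals and cohorts with known spectral ground truth.

The analysis pipeline is validated end-to-end on surrogate data whose
aperiodic exponents are known by construction:

* Gaussian white noise (flat PSD, beta = 0);
* Brownian noise, the cumulative sum of i.i.d. Gaussian increments
  (a random walk, theoretical 1/f^2 spectrum);
* arbitrary 1/f^beta noise synthesized in the frequency domain by
  shaping white spectra with amplitude f^(-beta/2) and uniform random
  phases (the expected one-sided PSD is then proportional to f^-beta by
  construction, which makes exponent-recovery oracles exact);
* narrowband oscillatory "peaks" (e.g. an alpha bump at 10 Hz) added on
  top of the background, emulating the rhythms that bias slope fits;
* hierarchical cohorts (region -> subject -> channel) in which each
  subject perturbs the region's true exponent and each channel perturbs
  the subject's, so that between-subject variability exceeds
  within-subject variability, as observed in resting-state intracranial
  recordings.

The default recording format is 60 s at 200 Hz (12 000 samples),
matching typical resting-state stereo-EEG atlas segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import Band, HIGH_BAND, LOW_BAND, TimeSeries, _require

__all__ = ["NoiseSpec", "PeakSpec", "CohortSpec", "Cohort",
           "gen_white_noise", "gen_brownian_noise", "gen_powerlaw_noise",
           "gen_band_powerlaw_noise", "add_oscillatory_peak", "gen_cohort"]

logger = logging.getLogger(__name__)

_NOISE_KINDS = ("white", "brownian", "powerlaw")

#: Default recording length/rate: 60 s at 200 Hz.
DEFAULT_FS = 200.0
DEFAULT_N = 12000


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of a single synthetic noise channel.

    ``sigma`` is the standard deviation of the generating increments for
    white/Brownian noise and the output standard deviation for shaped
    1/f^beta noise.  ``beta_true`` is only meaningful for
    ``kind="powerlaw"``.
    """

    kind: str
    n_samples: int = DEFAULT_N
    fs: float = DEFAULT_FS
    mu: float = 0.0
    sigma: float = 1.0
    beta_true: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.kind in _NOISE_KINDS, "kind",
                 f"must be one of {_NOISE_KINDS}")
        _require(int(self.n_samples) >= 2, "n_samples", "must be >= 2")
        _require(self.fs > 0, "fs", "must be positive")
        _require(self.sigma >= 0, "sigma", "must be non-negative")
        _require(int(self.seed) >= 0, "seed", "must be non-negative")
        if self.kind == "powerlaw":
            _require(self.beta_true is not None
                     and np.isfinite(self.beta_true), "beta_true",
                     "must be finite for kind='powerlaw'")
            _require(self.beta_true >= 0, "beta_true", "must be >= 0")


@dataclass(frozen=True)
class PeakSpec:
    """Narrowband oscillatory bump riding on the aperiodic background.

    The bump's PSD is Gaussian in frequency, centred at ``center_freq``
    with full width at half maximum ``bandwidth``; ``amplitude`` is the
    bump's peak PSD expressed as a multiple of the background PSD at the
    centre frequency (0 disables the peak).
    """

    center_freq: float = 10.0
    bandwidth: float = 2.0
    amplitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.center_freq > 0, "center_freq", "must be positive")
        _require(self.bandwidth > 0, "bandwidth", "must be positive")
        _require(self.amplitude >= 0, "amplitude", "must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Hierarchical multi-region cohort specification.

    ``regions`` maps a region label either to a single true exponent
    (same power law in every band) or to a mapping band-name -> exponent
    for the bands in ``bands``.  Subject- and channel-level exponents are
    drawn as ``beta_subject = beta_region + N(0, between_subject_sd^2)``
    and ``beta_channel = beta_subject + N(0, within_subject_sd^2)``; a
    subject's (channel's) offset is shared across bands, modelling a
    global spectral tilt.  Negative draws are clipped to 0 with a logged
    warning.
    """

    regions: Mapping[str, float | Mapping[str, float]]
    n_subjects_per_region: int = 10
    n_channels_per_subject: int = 3
    between_subject_sd: float = 0.3
    within_subject_sd: float = 0.1
    duration_s: float = 60.0
    fs: float = DEFAULT_FS
    peak: PeakSpec | None = None
    bands: tuple[Band, ...] = (LOW_BAND, HIGH_BAND)
    age_range: tuple[float, float] = (18.0, 65.0)
    age_mean: float = 33.1
    age_sd: float = 10.8
    male_fraction: float = 54.0 / 106.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.regions) >= 1, "regions", "must be non-empty")
        _require(self.n_subjects_per_region >= 1, "n_subjects_per_region",
                 "must be >= 1")
        _require(self.n_channels_per_subject >= 1, "n_channels_per_subject",
                 "must be >= 1")
        _require(self.between_subject_sd >= 0, "between_subject_sd",
                 "must be non-negative")
        _require(self.within_subject_sd >= 0, "within_subject_sd",
                 "must be non-negative")
        _require(self.duration_s * self.fs >= 2, "duration_s", "too short")
        for label, beta in self.regions.items():
            vals = beta.values() if isinstance(beta, Mapping) else [beta]
            for b in vals:
                _require(b >= 0, "regions", f"true beta for {label} must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def region_betas(self, label: str) -> dict[str, float]:
        """Per-band true exponents for one region."""
        spec = self.regions[label]
        if isinstance(spec, Mapping):
            missing = [b.name for b in self.bands if b.name not in spec]
            _require(not missing, "regions",
                     f"{label} lacks exponents for bands {missing}")
            return {b.name: float(spec[b.name]) for b in self.bands}
        return {b.name: float(spec) for b in self.bands}


@dataclass
class Cohort:
    """Hierarchy of channels with per-channel ground truth.

    ``truth`` is a tidy table with one row per channel: subject_id,
    region, channel, age, sex and the true per-band exponents
    (``true_beta_<band>`` columns).
    """

    channels: list[TimeSeries]
    truth: pd.DataFrame
    spec: CohortSpec | None = None

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def regions(self) -> list[str]:
        return sorted({ts.region for ts in self.channels})

    def by_region(self) -> dict[str, list[TimeSeries]]:
        out: dict[str, list[TimeSeries]] = {}
        for ts in self.channels:
            out.setdefault(ts.region, []).append(ts)
        return out

    def by_subject(self) -> dict[tuple[str, str], list[TimeSeries]]:
        """Channels grouped by (region, subject_id)."""
        out: dict[tuple[str, str], list[TimeSeries]] = {}
        for ts in self.channels:
            out.setdefault((ts.region, ts.subject_id), []).append(ts)
        return out


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_white_noise(spec: NoiseSpec) -> TimeSeries:
    """I.i.d. Gaussian samples with mean ``mu`` and SD ``sigma`` (beta=0)."""
    _require(spec.kind == "white", "kind", "expected kind='white'")
    rng = _rng(spec.seed)
    x = spec.mu + spec.sigma * rng.standard_normal(spec.n_samples)
    return TimeSeries(x, spec.fs, meta={"noise": "white", "seed": spec.seed})


def gen_brownian_noise(spec: NoiseSpec) -> TimeSeries:
    """Random walk: cumulative sum of zero-mean N(0, sigma^2) increments.

    The first difference of the output (prepending zero) reproduces the
    white-noise sequence drawn with the same seed.  No 1/sqrt(n)
    normalization is applied: the log-log slope is invariant under
    rescaling, so the estimated exponent is unaffected.
    """
    _require(spec.kind == "brownian", "kind", "expected kind='brownian'")
    rng = _rng(spec.seed)
    increments = spec.sigma * rng.standard_normal(spec.n_samples)
    x = spec.mu + np.cumsum(increments)
    return TimeSeries(x, spec.fs, meta={"noise": "brownian", "seed": spec.seed})


def _shaped_noise(freqs: np.ndarray, amplitude: np.ndarray, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Real signal whose one-sided expected PSD follows ``amplitude**2``.

    Spectral synthesis: the rFFT amplitude profile is multiplied by unit
    random phases and inverse-transformed.  The DC term is zero.
    """
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = amplitude * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = np.real(spectrum[-1])  # Nyquist bin must be real
    return np.fft.irfft(spectrum, n)


def gen_powerlaw_noise(spec: NoiseSpec) -> TimeSeries:
    """1/f^beta noise via spectral synthesis, rescaled to SD ``sigma``.

    The rFFT amplitudes are shaped as ``f^(-beta/2)`` with uniform random
    phases, so the expected one-sided PSD is proportional to
    ``f^-beta_true`` on (0, fs/2] exactly; ``beta_true=0`` reduces to
    (phase-randomized) white noise.
    """
    _require(spec.kind == "powerlaw", "kind", "expected kind='powerlaw'")
    rng = _rng(spec.seed)
    n = spec.n_samples
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-spec.beta_true / 2.0)
    x = _shaped_noise(freqs, amp, n, rng)
    sd = x.std()
    if sd > 0 and spec.sigma > 0:
        x = x * (spec.sigma / sd)
    else:
        x = np.zeros(n)
    return TimeSeries(x + spec.mu, spec.fs,
                      meta={"noise": "powerlaw", "beta_true": spec.beta_true,
                            "seed": spec.seed})


def gen_band_powerlaw_noise(betas: Mapping[str, float], bands: Sequence[Band],
                            n_samples: int = DEFAULT_N, fs: float = DEFAULT_FS,
                            sigma: float = 1.0,
                            seed=0) -> TimeSeries:
    """Noise with band-specific exponents (piecewise power-law spectrum).

    The log-amplitude profile is piecewise linear in log-frequency:
    below the break between two consecutive bands (placed at the
    geometric mean of the inner band edges) the slope is set by the
    lower band's exponent, above it by the upper band's, with the
    amplitude kept continuous at each break.  With equal exponents in
    all bands this reduces to a single pure power law.
    """
    _require(len(bands) >= 1, "bands", "need at least one band")
    ordered = sorted(bands, key=lambda b: b.f_lo)
    exps = []
    for b in ordered:
        _require(b.name in betas, "betas", f"missing exponent for band {b.name}")
        _require(betas[b.name] >= 0, "betas", f"beta for {b.name} must be >= 0")
        exps.append(float(betas[b.name]))
    breaks = [np.sqrt(ordered[i].f_hi * ordered[i + 1].f_lo)
              for i in range(len(ordered) - 1)]
    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    log_amp = np.zeros_like(freqs)
    pos = freqs > 0
    logf = np.log10(freqs[pos])
    # piecewise-linear log-amplitude, continuous at the breaks
    la = -exps[0] / 2.0 * logf
    offset = 0.0
    for k, fb in enumerate(breaks):
        lb = np.log10(fb)
        offset += (-exps[k] / 2.0) * lb - (-exps[k + 1] / 2.0) * lb
        above = logf > lb
        la[above] = offset - exps[k + 1] / 2.0 * logf[above]
    log_amp[pos] = la
    amp = np.zeros_like(freqs)
    amp[pos] = 10.0 ** log_amp[pos]
    x = _shaped_noise(freqs, amp, n_samples, rng)
    sd = x.std()
    if sd > 0 and sigma > 0:
        x = x * (sigma / sd)
    else:
        x = np.zeros(n_samples)
    return TimeSeries(x, fs, meta={"noise": "band_powerlaw",
                                   "beta_true": dict(betas), "seed": seed})


def add_oscillatory_peak(ts: TimeSeries, peak: PeakSpec) -> TimeSeries:
    """Add a narrowband oscillatory component to a signal.

    The component is spectrally shaped noise with a Gaussian PSD bump
    centred at ``peak.center_freq`` whose peak height equals
    ``peak.amplitude`` times the background PSD at the centre frequency
    (estimated from ``ts`` by Welch plus log-log interpolation).  With
    ``amplitude=0`` the input is returned unchanged.
    """
    _require(peak.center_freq < ts.nyquist, "center_freq",
             f"must be below the Nyquist frequency {ts.nyquist:g} Hz")
    if peak.amplitude == 0:
        return ts
    from .spectral import welch_psd  # local import avoids a cycle at import time

    nperseg = min(2048, ts.n)
    sp = welch_psd(ts, nperseg=nperseg)
    pos = sp.freqs > 0
    background = 10.0 ** np.interp(np.log10(peak.center_freq),
                                   np.log10(sp.freqs[pos]),
                                   np.log10(np.maximum(sp.psd[pos], 1e-300)))
    sigma_f = peak.bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> SD
    freqs = np.fft.rfftfreq(ts.n, 1.0 / ts.fs)
    target_psd = (peak.amplitude * background
                  * np.exp(-((freqs - peak.center_freq) ** 2)
                           / (2.0 * sigma_f**2)))
    # one-sided PSD -> rFFT amplitude: |X_k|^2 = PSD_k * fs * n / 2
    amp = np.sqrt(target_psd * ts.fs * ts.n / 2.0)
    bump = _shaped_noise(freqs, amp, ts.n, _rng(peak.seed))
    return ts.with_samples(ts.samples + bump, extra_meta={"peak": peak})


def _child_seed(base: int, *key: int) -> np.random.SeedSequence:
    """Deterministic sub-seed for a (region, subject, channel) index."""
    return np.random.SeedSequence(entropy=int(base), spawn_key=tuple(key))


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate a hierarchical cohort with known per-channel ground truth.

    Deterministic for a fixed seed: each subject and channel derives its
    random stream from a seed keyed on (region index, subject index,
    channel index), so changing cohort dimensions never reshuffles the
    other channels.
    """
    channels: list[TimeSeries] = []
    rows = []
    n_clipped = 0
    for ri, label in enumerate(spec.regions):
        base_betas = spec.region_betas(label)
        for si in range(spec.n_subjects_per_region):
            srng = _rng(_child_seed(spec.seed, ri, si))
            subj_offset = srng.normal(0.0, spec.between_subject_sd)
            age = float(np.clip(srng.normal(spec.age_mean, spec.age_sd),
                                *spec.age_range))
            sex = "M" if srng.uniform() < spec.male_fraction else "F"
            subject_id = f"{label}_s{si:02d}"
            for ci in range(spec.n_channels_per_subject):
                crng = _rng(_child_seed(spec.seed, ri, si, ci))
                chan_offset = crng.normal(0.0, spec.within_subject_sd)
                betas = {}
                for bname, b0 in base_betas.items():
                    b = b0 + subj_offset + chan_offset
                    if b < 0:
                        n_clipped += 1
                        b = 0.0
                    betas[bname] = b
                ts = gen_band_powerlaw_noise(
                    betas, spec.bands, n_samples=spec.n_samples, fs=spec.fs,
                    seed=_child_seed(spec.seed, ri, si, ci, 1))
                if spec.peak is not None and spec.peak.amplitude > 0:
                    child = np.random.SeedSequence(
                        entropy=spec.peak.seed, spawn_key=(ri, si, ci))
                    peak = PeakSpec(spec.peak.center_freq, spec.peak.bandwidth,
                                    spec.peak.amplitude,
                                    seed=int(child.generate_state(1)[0] >> 1))
                    ts = add_oscillatory_peak(ts, peak)
                ts.subject_id = subject_id
                ts.region = label
                ts.channel_id = f"{subject_id}_c{ci:02d}"
                ts.age = age
                ts.sex = sex
                channels.append(ts)
                row = {"subject_id": subject_id, "region": label,
                       "channel": ts.channel_id, "age": age, "sex": sex,
                       "fs": spec.fs}
                row.update({f"true_beta_{k}": v for k, v in betas.items()})
                rows.append(row)
    if n_clipped:
        logger.warning("gen_cohort: clipped %d negative channel exponents to 0",
                       n_clipped)
    return Cohort(channels=channels, truth=pd.DataFrame(rows), spec=spec)
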