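# Methods

## Model

The quantity of interest is the exponent β of the aperiodic component of
a neural power spectrum, PSD(f) ∝ 1/f^β, estimated separately in a low
band (0.5–4 Hz) and a high band (33–80 Hz).  The estimate is the negated
slope of a straight-line fit to log10 PSD versus log10 f; β is stored
signed (decaying spectrum → positive β) and conventionally reported as a
magnitude.  The model assumes the in-band spectrum is a pure power law;
narrowband oscillations violate that assumption, which is why each band
is isolated by filtering before estimation rather than modelled jointly
(no knee/bend terms, no Gaussian peak fitting).

## Pipeline and parameters

| stage | parameter | default | why |
|---|---|---|---|
| recording | duration × rate | 60 s × 200 Hz | typical resting-state intracranial atlas segment; 12 000 samples |
| band isolation | low band | Butterworth low-pass, order 7, 8 Hz | passes 0.5–4 Hz untouched, suppresses the alpha bump (8–12 Hz) one octave above the fit band |
| | high band | Butterworth high-pass, order 7, 33 Hz | removes the steep low-frequency power that would otherwise leak across the spectrum |
| | phase | zero-phase (forward–backward) | offline analysis; no phase distortion; squares the magnitude response |
| PSD | Welch | Hamming, nperseg = nfft = 2048, 50 % overlap, per-segment mean removal | ~10 s segments at 200 Hz (0.098 Hz resolution); mean removal protects the bins next to 0.5 Hz |
| fit | weights | unit (single channel) / 1/Δy² (region mean) | Δy_i = σ_i/(PSD_i·ln 10): first-order propagation of the pooled linear-domain SD into log10 units |
| bands | low, high/gamma | 0.5–4 Hz, 33–80 Hz | closed intervals on the discrete grid, DC never included |

Log base: log10 throughout.  β is base-invariant; the intercept is in
log10 units at 1 Hz.

### Filter-response handling

Two deliberate choices make the fit independent of the filter settings:

1. **Compensation.**  The applied digital filter's PSD attenuation
   (|H(f)|⁴ for zero-phase, |H(f)|² single-pass, from the actual
   second-order-section design) is divided out of the Welch PSD inside
   the fit band before the log transform.  Without this, the filter's
   own roll-off near the cutoff contributes up to several tenths of a
   unit of slope bias that changes with cutoff and order.
2. **Passband restriction.**  Bins of the fit band beyond the cutoff
   (e.g. 33–50 Hz when a 50 Hz high-pass is in use) are excluded rather
   than compensated: at stopband depths the measured PSD is dominated by
   spectral leakage, and dividing leakage by a tiny gain produces
   arbitrary values.  The effective fit band is the requested band
   intersected with the filter's nominal passband.

With both rules, re-running the full pipeline over the robustness grid
(low-pass cutoff 4/8 Hz, high-pass cutoff 33/50 Hz, order 5/7, FFT
length 256/1024/2048) changes per-region exponents by at most ~0.1 and a
configuration-homogeneity ANOVA is far from significance — the
exponents genuinely do not depend on the tunable parameters.

### Aggregation and statistics

Region spectra are the per-bin arithmetic mean over *all* channels of
all subjects in the region, with the pooled population SD (ddof = 0) as
the uncertainty — deliberately conservative, since between-subject
variability exceeds within-subject variability, and the pooled SD is
dominated by the larger of the two.  The weighted region fit uses those
SDs as weights; as an option the SD of per-channel log-PSD can be used
instead.  Single-channel regions (zero SD) fall back to unit weights.

The replicate unit for the ANOVA is the per-subject exponent (the mean
of that subject's channel fits), not the per-channel exponent: channels
within a subject are correlated, and treating them as replicates would
pseudo-replicate.  Tukey HSD runs at α = 0.05.  Regions contributing a
single subject are excluded from the ANOVA with a logged warning.  The
β–gamma-power correlation is a plain Pearson r with a t-based p-value
over region pairs; gamma power is the mean PSD over 33–80 Hz after
normalizing each recording's spectrum to unit total power over
(0, fs/2] (normalization mode "none" is also available).  The age
regression is OLS of per-subject β on age with a t-based 95 % CI.

## Synthetic data: what it does and does not emulate

The generator covers: Gaussian white noise (β = 0); Brownian noise as a
cumulative sum of N(0, σ²) increments (nominal 1/f², with the discrete
random walk's sin⁻²(πf/fs) flattening near Nyquist — the reason its
full-range fitted slope is ~1.8 rather than 2.0); arbitrary 1/f^β noise
by spectral synthesis (rFFT amplitudes f^(−β/2), uniform random phases,
zero DC, rescaled to target SD), which has an exactly power-law expected
spectrum and therefore serves as the recovery oracle; band-specific
exponents via a piecewise log-log-linear amplitude profile, continuous
at breaks placed at the geometric mean of adjacent band edges;
oscillatory peaks as spectrally shaped noise with a Gaussian PSD bump
(FWHM = bandwidth, peak height = amplitude × the background PSD at the
centre frequency, background estimated by Welch + log-log
interpolation); and hierarchical cohorts where a subject-level offset
(SD 0.3 by default) and a channel-level offset (SD 0.1) perturb the
region's true exponent, the same offset applying to all bands (a global
spectral tilt).  Negative exponent draws are clipped to zero with a
logged warning.  Ages are drawn from N(33.1, 10.8²) clipped to 18–65
years and sex is Bernoulli with p(male) = 54/106, mirroring a typical
epilepsy-surgery cohort's demographics.  Sub-seeding is hierarchical by
(region, subject, channel) index, so cohorts are bit-reproducible and
individual channels do not reshuffle when dimensions change.

Not emulated: spatial correlation between channels (no channel
covariance model), non-Gaussian or nonstationary signals, multifractal
structure, line noise, artifacts, or realistic oscillatory dynamics
(the "alpha" bump has random phase, not waxing-waning rhythmicity).
Passing tests therefore demonstrate that the estimator and statistics
behave correctly when their assumptions hold and under the specific
violations modelled (oscillatory bumps, hierarchical variance); they do
not certify performance on real recordings with artifacts or correlated
channels.

## Numerical choices

- Band slicing takes the closed interval f_lo ≤ f ≤ f_hi on the grid;
  the DC bin is never included even if f_lo is tiny.
- Non-positive PSD bins inside a fit band raise an error rather than
  being dropped silently (they indicate fitting inside a stopband).
- Weighted least squares is solved in closed form from the weighted
  normal equations; standard errors use the weighted covariance scaled
  by the weighted residual mean square, so exactly collinear input has
  zero standard error regardless of the weights' scale.
- Filtering uses second-order sections with odd-reflection padding of
  3 × (2·n_sections + 1) samples; signals not longer than the pad are
  rejected.
- The Brownian generator applies no 1/√n normalization (slope is
  scale-invariant), so its first difference reproduces the white
  increment stream exactly.
- The high band is 33–80 Hz with the default 33 Hz high-pass cutoff;
  both are configurable (some conventions start the band at 34 Hz —
  at the 0.098 Hz grid resolution the difference is ~10 bins out of
  ~480 and moves the fitted exponent by far less than its SE).

## Problem sizes used by the test suite

Exponent-recovery checks use 50 replicates per level at the full 12 000
samples.  The statistical-calibration simulations use 500 null cohorts
(3 regions × 6 subjects × 2 channels) and 200 power cohorts
(2 regions × 20 subjects × 2 channels) at 10.24 s per channel — the
shortest duration that still accommodates one full Welch segment —
since type-I/power calibration depends on the hierarchy, not on the
per-channel fit precision.  The sweep and region-discrimination checks
use full-length recordings with 2 and 5 regions respectively.

## Known limitations

- The weighted fit of a *region mean* spectrum over channels with
  heterogeneous exponents estimates the slope of the mean spectrum,
  which is not the mean of the channel slopes (the mean of power laws
  is not a power law); with the default hierarchy the difference is a
  few tenths at most, identical across filter configurations, and
  ordering-preserving — but comparisons should use one aggregation
  convention consistently.
- For variance-normalized synthetic channels, gamma-band power is
  mechanically anti-correlated with the high-band exponent; the
  synthetic cohort cannot emulate a null β–gamma relationship while
  holding total power fixed.
- EDF ingestion converts MNE's volts to microvolts and assumes one
  metadata row per (file, channel) pair; packed multi-rate EDF files
  are untested beyond single-rate channels.
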