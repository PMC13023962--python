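# scalefree

Estimation and comparison of the scale-free (aperiodic, 1/f^β) component
of neural power spectra across brain regions.

Resting-state intracranial EEG shows, besides its oscillatory rhythms, an
aperiodic background whose power spectral density follows a power law,
PSD(f) ∝ 1/f^β — a straight line of slope −β in log-log coordinates.
The exponent β behaves differently in two frequency ranges (a low band,
0.5–4 Hz, and a high/gamma band, 33–80 Hz) and, in the high band, can
differ systematically between brain regions, making it a candidate
functional fingerprint for region classification.  This package is for
researchers who want to estimate those exponents from multichannel
recordings — or from synthetic signals with known ground truth — and run
the region-discrimination statistics on top of them.

## What it computes

For each channel (60 s at 200 Hz by default):

1. **Band isolation** — zero-phase Butterworth filtering (7th-order
   low-pass at 8 Hz for the low band; 7th-order high-pass at 33 Hz for
   the high band) to suppress oscillatory peaks such as the 8–12 Hz
   alpha rhythm, which otherwise bias the slope;
2. **Welch PSD** — Hamming window, 2048-point FFT (~10 s segments, 50 %
   overlap);
3. **Log-log fit** — least squares on (log10 f, log10 PSD) inside the
   band, with the filter's known magnitude response divided out first;
   β = −slope.

Channels aggregate hierarchically: region-level mean spectra carry the
pooled cross-subject/channel standard deviation, which enters the
region fit as weights w_i = 1/Δy_i² (Δy_i = σ_i /(PSD_i · ln 10)).
Per-subject exponents feed a one-way region ANOVA with Tukey HSD
post-hocs, a min-max normalized exponent map
Δβ_i = (β_i − β_min)/(β_max − β_min), a Pearson correlation between β
and mean normalized gamma-band power ⟨PSD(f)⟩_γ, and an age regression.
A robustness sweep re-runs everything over a grid of filter/FFT
configurations.

The `scalefree.synthetic` module generates white noise, Brownian noise
(random walks), arbitrary 1/f^β noise with band-specific exponents,
narrowband oscillatory bumps, and hierarchical region→subject→channel
cohorts with known ground truth, so every pipeline stage is verifiable
without any external data.

## Worked example

```python
import numpy as np
from scalefree import (NoiseSpec, gen_brownian_noise, gen_white_noise,
                       welch_psd, fit_band_exponent, full_band)

for kind, gen in (("white", gen_white_noise), ("brownian", gen_brownian_noise)):
    slopes = []
    for seed in range(3):
        sp = welch_psd(gen(NoiseSpec(kind, seed=seed)))
        slopes.append(fit_band_exponent(sp, full_band(sp)).abs_beta)
    print(kind, np.round(np.mean(slopes), 3))
```

prints

```
white 0.012
brownian 1.801
```

i.e. white noise is spectrally flat (|β| ≈ 0) while the random walk
shows a single power-law regime over the whole range with |β| ≈ 1.8
(slightly below the nominal 2 because the discrete random walk's
spectrum flattens towards the Nyquist frequency).  The same computation
is available from the shell as `scalefree noise-check`.

The numbered scripts under `analysis/` are narrative drivers for the
full study: simulated-noise exponents, alpha-peak bias and its removal,
the parameter-robustness sweep, the region-discrimination run (ANOVA,
Tukey, Δβ map, β–gamma correlation) and the statistical calibration of
those tests.  Each writes its tables under `results/`.  For example:

```sh
$ python analysis/04_region_discrimination.py
low-band region ANOVA: F(4,35) = 0.38, p = 0.82
high-band region ANOVA: F(4,35) = 31.69, p = 3.4e-11
```

— a synthetic cohort whose regions differ only in the high-band exponent
is discriminated by the high-band fit and, correctly, not by the
low-band fit.

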