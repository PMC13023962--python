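#!/usr/bin/env python
"""How an alpha-band oscillatory peak biases slope fits, and how band
isolation removes the bias.

A 10 Hz bump is superimposed on 1/f^1.5 backgrounds.  A naive fit over
0.5-12 Hz (which includes the bump) underestimates the exponent badly; a
fit restricted to 0.5-4 Hz after a 7th-order 8 Hz low-pass recovers it.
Writes results/alpha_peak_bias.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scalefree import (Band, DEFAULT_LOWPASS, LOW_BAND, NoiseSpec, PeakSpec,
                       add_oscillatory_peak, fit_band_exponent,
                       gen_powerlaw_noise)

OUT = Path(__file__).resolve().parent.parent / "results"
BETA_TRUE = 1.5
N_REPS = 20


def main(seed: int = 0) -> None:
    rows = []
    for i in range(N_REPS):
        ts = gen_powerlaw_noise(NoiseSpec("powerlaw", beta_true=BETA_TRUE,
                                          seed=seed + i))
        ts = add_oscillatory_peak(ts, PeakSpec(10.0, 2.0, amplitude=5.0,
                                               seed=777 + i))
        rows.append({
            "realization": i,
            "filtered_low_band":
                fit_band_exponent(ts, LOW_BAND,
                                  filter_spec=DEFAULT_LOWPASS).beta,
            "naive_wide_band":
                fit_band_exponent(ts, Band("wide", 0.5, 12.0)).beta})
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "alpha_peak_bias.csv", index=False)
    f, n = df["filtered_low_band"].mean(), df["naive_wide_band"].mean()
    print(df.round(3).to_string(index=False))
    print(f"\ntrue beta = {BETA_TRUE}")
    print(f"band-isolated fit:  mean beta = {f:.3f} (bias {f - BETA_TRUE:+.3f})")
    print(f"naive wide-band fit: mean beta = {n:.3f} (bias {n - BETA_TRUE:+.3f})")


if __name__ == "__main__":
    main()
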