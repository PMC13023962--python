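#!/usr/bin/env python
"""Robustness of the fitted exponents to the tunable pipeline parameters.

Re-runs the fits on a beta=2 synthetic cohort over the full configuration
grid (low-pass cutoff 4/8 Hz, high-pass cutoff 33/50 Hz, filter order 5/7,
FFT length 256/1024/2048) and summarizes the per-region spread and a
config-homogeneity ANOVA.  Writes results/sweep_regions.csv and
results/sweep_summary.csv.
"""

from pathlib import Path

from scalefree import CohortSpec, gen_cohort, robustness_sweep

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 31) -> None:
    cohort = gen_cohort(CohortSpec(regions={"R1": 2.0, "R2": 2.0},
                                   n_subjects_per_region=6,
                                   n_channels_per_subject=2,
                                   duration_s=60.0, seed=seed))
    res = robustness_sweep(cohort)
    OUT.mkdir(exist_ok=True)
    res.region_table.to_csv(OUT / "sweep_regions.csv", index=False)
    res.summary.to_csv(OUT / "sweep_summary.csv", index=False)
    print(res.summary.round(4).to_string(index=False))
    if bool(res.summary["homogeneous"].all()):
        print("\nno configuration-dependent differences in the exponent "
              "(all homogeneity tests non-significant at alpha=0.05)")
    else:
        print("\nWARNING: some configurations disagree; inspect "
              "results/sweep_regions.csv")


if __name__ == "__main__":
    main()
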