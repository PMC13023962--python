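#!/usr/bin/env python
"""Region discrimination by the high-band exponent on a synthetic cohort.

Five regions share the same low-band exponent (1.0) but differ in the
high band (1.5 .. 2.5).  The full pipeline is expected to find no region
effect in the low band and a strong effect in the high band, with the
min-max-normalized exponent map ordering the regions correctly.  Note
that for these variance-normalized synthetic channels the mean gamma
power is mechanically anti-correlated with the high-band exponent (a
steeper spectrum concentrates the fixed total power at low frequencies),
so a strong negative correlation here is a construction artifact, not a
finding about neural data.  Runs through the same run_pipeline entry
point the CLI uses; outputs land in results/region_run/.
"""

import json
from pathlib import Path

from scalefree import CohortSpec, RunConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "region_run"
HIGH_TRUTH = {"r1": 1.5, "r2": 1.75, "r3": 2.0, "r4": 2.25, "r5": 2.5}


def main(seed: int = 42) -> None:
    spec = CohortSpec(
        regions={r: {"low": 1.0, "high": b} for r, b in HIGH_TRUTH.items()},
        n_subjects_per_region=8, n_channels_per_subject=2,
        between_subject_sd=0.2, within_subject_sd=0.1,
        duration_s=60.0, seed=seed)
    out = run_pipeline(RunConfig(source=spec, out_dir=str(OUT), seed=seed))
    summary = json.loads((out / "summary.json").read_text())
    for band in ("low", "high"):
        a = summary["stats"][band]["anova"]
        print(f"{band}-band region ANOVA: F({a['df_between']},{a['df_within']})"
              f" = {a['F']:.2f}, p = {a['p_value']:.2g}")
    corr = summary["stats"].get("beta_gamma_correlation")
    if corr:
        print(f"beta vs gamma power: r = {corr['r']:.3f}, "
              f"p = {corr['p_value']:.2g} (n = {corr['n']} regions)")
    print(f"tables in {out}")


if __name__ == "__main__":
    main()
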