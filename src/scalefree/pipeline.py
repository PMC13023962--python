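"""End-to-end run orchestration.

A :class:`RunConfig` pairs each analysis band with its band-isolation
filter, fixes the Welch settings and the statistics to run, and points
at either a synthetic cohort specification or a cohort directory.
:func:`run_pipeline` executes the stages — filter, Welch, region
aggregation, weighted fits, per-subject fits, ANOVA, Tukey HSD,
exponent map, gamma-power correlation, age regression — and writes
tidy CSV tables plus a machine-readable manifest into the run
directory.  Runs are deterministic for a fixed seed and never mutate
their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import Band, GAMMA_BAND, HIGH_BAND, LOW_BAND
from .filtering import DEFAULT_HIGHPASS, DEFAULT_LOWPASS, FilterSpec, apply_filter
from .cohort_stats import (aggregate_region, beta_age_regression,
                           beta_gamma_correlation, per_subject_betas,
                           region_anova, region_band_fit, tukey_hsd)
from .io import read_channel_table
from .powerlaw import delta_beta
from .spectral import mean_band_power, welch_psd
from .synthetic import Cohort, CohortSpec, gen_cohort

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


def _default_bands() -> dict:
    return {"low": (LOW_BAND, DEFAULT_LOWPASS),
            "high": (HIGH_BAND, DEFAULT_HIGHPASS)}


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``source`` is a :class:`~scalefree.synthetic.CohortSpec` (synthetic
    run) or a path to a cohort directory.  ``bands`` maps a band name to
    a ``(Band, FilterSpec)`` pair; the low band must pair with a
    low-pass and the high band with a high-pass filter.
    """

    source: CohortSpec | str
    out_dir: str = "run"
    bands: dict = field(default_factory=_default_bands)
    nperseg: int = 2048
    nfft: int | None = None
    overlap: float = 0.5
    window: str = "hamming"
    run_anova: bool = True
    run_tukey: bool = True
    run_correlation: bool = True
    run_age_regression: bool = True
    gamma_band: Band = GAMMA_BAND
    delta_beta_band: str = "high"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (band, filt) in self.bands.items():
            low_kind = band.f_hi <= filt.cutoff_hz
            if filt.kind == "lowpass" and not low_kind:
                raise ValueError(f"bands: band {name!r} extends above the "
                                 f"low-pass cutoff {filt.cutoff_hz} Hz")
            if filt.kind == "highpass" and band.f_lo < filt.cutoff_hz:
                raise ValueError(f"bands: band {name!r} extends below the "
                                 f"high-pass cutoff {filt.cutoff_hz} Hz")

    def to_jsonable(self) -> dict:
        d = {"out_dir": self.out_dir, "nperseg": self.nperseg,
             "nfft": self.nfft, "overlap": self.overlap, "window": self.window,
             "seed": self.seed, "delta_beta_band": self.delta_beta_band,
             "run": {"anova": self.run_anova, "tukey": self.run_tukey,
                     "correlation": self.run_correlation,
                     "age_regression": self.run_age_regression},
             "bands": {name: {"f_lo": b.f_lo, "f_hi": b.f_hi,
                              "filter": f.to_dict()}
                       for name, (b, f) in self.bands.items()}}
        if isinstance(self.source, CohortSpec):
            src = dataclasses.asdict(self.source)
            src["regions"] = {k: v for k, v in self.source.regions.items()}
            src["bands"] = [b.name for b in self.source.bands]
            src["peak"] = dataclasses.asdict(self.source.peak) if self.source.peak else None
            d["source"] = {"synthetic": src}
        else:
            d["source"] = {"directory": str(self.source)}
        return d

    @property
    def config_hash(self) -> str:
        # identifies the analysis configuration; the output location is
        # deliberately excluded
        d = self.to_jsonable()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (see docs/methods.md for keys)."""
    raw = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    src = raw.get("source", {})
    if "directory" in src:
        kwargs["source"] = src["directory"]
    elif "synthetic" in src:
        s = dict(src["synthetic"])
        if "peak" in s and s["peak"] is not None:
            from .synthetic import PeakSpec
            s["peak"] = PeakSpec(**s["peak"])
        kwargs["source"] = CohortSpec(**s)
    else:
        raise ValueError("source: config needs source.directory or "
                         "source.synthetic")
    if "bands" in raw:
        bands = {}
        for name, b in raw["bands"].items():
            bands[name] = (Band(name, b["f_lo"], b["f_hi"]),
                           FilterSpec.from_dict(b["filter"]))
        kwargs["bands"] = bands
    for key in ("out_dir", "nperseg", "nfft", "overlap", "window", "seed",
                "run_anova", "run_tukey", "run_correlation",
                "run_age_regression", "delta_beta_band"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _write_table(df: pd.DataFrame, path: Path, units: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def _load_cohort(config: RunConfig) -> Cohort:
    if isinstance(config.source, CohortSpec):
        spec = config.source
        if spec.seed != config.seed:
            spec = dataclasses.replace(spec, seed=config.seed)
        return gen_cohort(spec)
    return read_channel_table(config.source)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full cohort analysis; returns the run directory.

    Writes ``region_fits.csv``, ``subject_betas.csv``, per-band ANOVA and
    Tukey tables, ``delta_beta.csv``, ``summary.json`` and
    ``manifest.json``.  Identical config and seed give identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    cohort = _load_cohort(config)
    logger.info("pipeline: cohort with %d channels in %d regions",
                cohort.n_channels, len(cohort.regions))

    h = config.config_hash
    region_fit_rows, subject_frames = [], []
    region_betas_by_band: dict[str, dict[str, float]] = {}
    for name, (band, fspec) in config.bands.items():
        logger.info("pipeline: band %s [%g, %g] Hz", name, band.f_lo, band.f_hi)
        by_region = cohort.by_region()
        betas = {}
        for region, chans in sorted(by_region.items()):
            spectra = [welch_psd(apply_filter(ts, fspec),
                                 nperseg=config.nperseg, nfft=config.nfft,
                                 overlap=config.overlap, window=config.window)
                       for ts in chans]
            summary = aggregate_region(spectra, region=region)
            fit = region_band_fit(summary, band)
            betas[region] = fit.beta
            region_fit_rows.append({
                "region": region, "band": name, "beta": fit.beta,
                "se_beta": fit.se_beta, "intercept": fit.intercept,
                "se_intercept": fit.se_intercept, "n_points": fit.n_points,
                "r_squared": fit.r_squared, "n_channels": summary.n_channels,
                "n_subjects": summary.n_subjects})
        region_betas_by_band[name] = betas
        subject_frames.append(per_subject_betas(
            cohort, band, filter_spec=fspec, nperseg=config.nperseg,
            nfft=config.nfft, overlap=config.overlap, window=config.window))

    _write_table(pd.DataFrame(region_fit_rows), out / "region_fits.csv",
                 "beta: dimensionless exponent; intercept: log10(uV^2/Hz)", h)
    subjects = pd.concat(subject_frames, ignore_index=True)
    _write_table(subjects, out / "subject_betas.csv",
                 "beta_hat: dimensionless exponent", h)

    summary: dict = {"config_hash": h, "n_channels": cohort.n_channels,
                     "regions": cohort.regions, "stats": {}}
    for name in config.bands:
        sub = subjects[subjects["band"] == name]
        band_stats: dict = {}
        counts = sub.groupby("region").size()
        usable = counts[counts >= 2].index
        if len(usable) < len(counts):
            dropped = sorted(set(counts.index) - set(usable))
            warnings.append(f"band {name}: regions {dropped} excluded from "
                            "ANOVA (single subject)")
        anova_sub = sub[sub["region"].isin(usable)]
        if config.run_anova and len(usable) >= 2:
            res = region_anova(anova_sub)
            band_stats["anova"] = dataclasses.asdict(res)
        if config.run_tukey and len(usable) >= 2:
            tk = tukey_hsd(anova_sub)
            _write_table(tk, out / f"tukey_{name}.csv",
                         "mean_diff: dimensionless exponent", h)
        if config.run_age_regression and sub["age"].notna().sum() >= 3 \
                and sub["age"].nunique() > 1:
            reg = beta_age_regression(sub)
            band_stats["age_regression"] = dataclasses.asdict(reg)
        summary["stats"][name] = band_stats

    db_band = config.delta_beta_band
    if db_band in region_betas_by_band and len(region_betas_by_band[db_band]) >= 2:
        betas = region_betas_by_band[db_band]
        try:
            dmap = delta_beta(betas)
            df = pd.DataFrame({"region": list(dmap.values),
                               "beta": [betas[r] for r in dmap.values],
                               "delta_beta": list(dmap.values.values())})
            _write_table(df, out / "delta_beta.csv",
                         "delta_beta: min-max normalized, dimensionless", h)
        except ValueError as exc:
            warnings.append(f"delta_beta skipped: {exc}")
    else:
        warnings.append(f"delta_beta skipped: band {db_band!r} not analyzed")

    if config.run_correlation and db_band in region_betas_by_band \
            and len(cohort.regions) >= 3:
        gamma = {}
        for region, chans in sorted(cohort.by_region().items()):
            vals = [mean_band_power(welch_psd(ts, nperseg=config.nperseg,
                                              nfft=config.nfft),
                                    config.gamma_band).value for ts in chans]
            gamma[region] = float(pd.Series(vals).mean())
        try:
            corr = beta_gamma_correlation(region_betas_by_band[db_band], gamma)
            summary["stats"]["beta_gamma_correlation"] = dataclasses.asdict(corr)
        except ValueError as exc:
            warnings.append(f"beta-gamma correlation skipped: {exc}")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest = {"config": config.to_jsonable(), "config_hash": h,
                "version": __version__, "seed": config.seed,
                "bands_analyzed": sorted(config.bands),
                "bands_omitted": sorted({"low", "high"} - set(config.bands)),
                "warnings": warnings,
                "outputs": sorted(p.name for p in out.iterdir())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
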