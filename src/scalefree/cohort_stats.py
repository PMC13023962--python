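"""Hierarchical aggregation and region-discrimination statistics.

Channels are aggregated into region-level mean spectra with a pooled
(cross-subject, cross-channel) standard deviation that serves as the
weight in the region's log-log fit — the conservative choice given that
between-subject exponent variability exceeds within-subject variability.
Per-subject exponents feed a one-way ANOVA across regions, Tukey HSD
post-hoc pairs, the exponent-versus-gamma-power Pearson correlation and
an exponent-versus-age regression.  A robustness sweep re-runs the fits
over a grid of filter/FFT configurations to verify that the estimated
exponents do not depend on the tunable parameters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Band, HIGH_BAND, LOW_BAND, _require
from .filtering import FilterSpec
from .powerlaw import PowerLawFit, fit_band_exponent
from .spectral import SpectrumEstimate, welch_psd
from .synthetic import Cohort

__all__ = ["RegionSummary", "AnovaResult", "CorrelationResult",
           "AgeRegression", "SweepResult", "aggregate_region",
           "region_band_fit", "per_subject_betas", "region_anova",
           "tukey_hsd", "beta_gamma_correlation", "beta_age_regression",
           "robustness_sweep"]

logger = logging.getLogger(__name__)


@dataclass
class RegionSummary:
    """Region-level mean spectrum with pooled per-bin SD and band fits."""

    region: str
    mean_psd: SpectrumEstimate
    global_sd: np.ndarray
    n_channels: int
    n_subjects: int
    fits: dict[str, PowerLawFit] = field(default_factory=dict)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AgeRegression:
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class SweepResult:
    """Per-config exponents and an invariance summary.

    ``region_table``: one row per (band, config, region) with the
    region-aggregate weighted-fit exponent.  ``subject_table``: one row
    per (band, config, region, subject).  ``summary``: per (band, region)
    the max pairwise spread of region exponents across configs and a
    one-way ANOVA homogeneity test treating config as the factor over
    per-subject exponents.
    """

    region_table: pd.DataFrame
    subject_table: pd.DataFrame
    summary: pd.DataFrame


def aggregate_region(spectra: Sequence[SpectrumEstimate],
                     region: str | None = None) -> RegionSummary:
    """Per-bin mean and pooled population SD over all channels of a region.

    The SD is taken over the pooled set of all channels of all subjects
    (``ddof=0``), not nested per subject.
    """
    spectra = list(spectra)
    _require(len(spectra) >= 1, "spectra", "need at least one spectrum")
    grid = spectra[0].freqs
    for sp in spectra[1:]:
        if sp.freqs.shape != grid.shape or not np.allclose(sp.freqs, grid):
            raise ValueError("spectra: frequency grids differ between channels")
    stack = np.vstack([sp.psd for sp in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    subjects = {sp.meta.get("subject_id") for sp in spectra}
    if region is None:
        region = spectra[0].meta.get("region")
    meta = {"region": region, "n_channels": len(spectra)}
    if "filter" in spectra[0].meta:
        meta["filter"] = spectra[0].meta["filter"]
    mean_sp = SpectrumEstimate(grid, mean, settings=dict(spectra[0].settings),
                               meta=meta)
    return RegionSummary(region=region, mean_psd=mean_sp, global_sd=sd,
                         n_channels=len(spectra),
                         n_subjects=len(subjects - {None}) or 1)


def region_band_fit(summary: RegionSummary, band: Band,
                    weighted: bool = True, sigma_is_log: bool = False,
                    compensate: bool = True) -> PowerLawFit:
    """Weighted fit of a region's mean spectrum in one band.

    Weights are ``1/dy_i^2`` with ``dy_i`` the pooled SD propagated into
    log10 units.  Bins where the pooled SD is zero (e.g. a single-channel
    region) fall back to an unweighted fit.
    """
    sigma = None
    if weighted and np.all(summary.global_sd[band.contains(summary.mean_psd.freqs)] > 0):
        sigma = summary.global_sd
    fit = fit_band_exponent(summary.mean_psd, band, sigma=sigma,
                            sigma_is_log=sigma_is_log, compensate=compensate)
    summary.fits[band.name] = fit
    return fit


def per_subject_betas(cohort: Cohort, band: Band,
                      filter_spec: FilterSpec | None = None,
                      compensate: bool = True,
                      **welch_kwargs) -> pd.DataFrame:
    """Per-subject exponents: mean and SE of the per-channel fits.

    Returns a tidy table with columns ``subject_id, region, band,
    beta_hat, within_subject_se, n_channels, age, sex``.  The within-
    subject SE is the SD of the subject's channel exponents divided by
    sqrt(n_channels); it is zero (flagged by ``n_channels == 1``) for
    single-channel subjects.
    """
    rows = []
    for (region, subject), chans in sorted(cohort.by_subject().items()):
        betas = [fit_band_exponent(ts, band, filter_spec=filter_spec,
                                   compensate=compensate, **welch_kwargs).beta
                 for ts in chans]
        betas = np.asarray(betas)
        se = (betas.std(ddof=1) / np.sqrt(len(betas))) if len(betas) > 1 else 0.0
        rows.append({"subject_id": subject, "region": region,
                     "band": band.name, "beta_hat": float(betas.mean()),
                     "within_subject_se": float(se),
                     "n_channels": len(betas),
                     "age": chans[0].age, "sex": chans[0].sex})
    return pd.DataFrame(rows)


def _anova_groups(records: pd.DataFrame, value_col: str,
                  group_col: str) -> list[np.ndarray]:
    groups = []
    for label, g in records.groupby(group_col):
        vals = np.asarray(g[value_col], dtype=float)
        if len(vals) < 2:
            raise ValueError(
                f"{group_col}: group {label!r} has fewer than 2 records")
        groups.append(vals)
    if len(groups) < 2:
        raise ValueError(f"{group_col}: need at least 2 groups")
    return groups


def region_anova(records: pd.DataFrame, value_col: str = "beta_hat",
                 group_col: str = "region") -> AnovaResult:
    """One-way fixed-effects ANOVA of per-subject exponents across regions."""
    groups = _anova_groups(records, value_col, group_col)
    F, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return AnovaResult(F=float(F), df_between=k - 1, df_within=n - k,
                       p_value=float(p))


def tukey_hsd(records: pd.DataFrame, alpha: float = 0.05,
              value_col: str = "beta_hat",
              group_col: str = "region") -> pd.DataFrame:
    """Tukey HSD pairwise region comparisons (studentized range).

    Returns one row per unordered pair: ``region_i, region_j, mean_diff,
    p_adj, significant`` (k groups -> k(k-1)/2 rows).
    """
    _anova_groups(records, value_col, group_col)  # shared validation
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(records[value_col], dtype=float),
                            np.asarray(records[group_col]), alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=[str(c) for c in res.summary().data[0]])
    return pd.DataFrame({
        "region_i": frame["group1"], "region_j": frame["group2"],
        "mean_diff": frame["meandiff"].astype(float),
        "p_adj": frame["p-adj"].astype(float),
        "significant": frame["reject"].astype(bool)})


def beta_gamma_correlation(region_betas: Mapping[str, float],
                           region_gamma: Mapping[str, float]) -> CorrelationResult:
    """Pearson correlation between region exponents and gamma band power."""
    keys = sorted(region_betas)
    _require(sorted(region_gamma) == keys, "region_gamma",
             "region labels must match region_betas")
    if len(keys) < 3:
        raise ValueError("region_betas: need at least 3 paired regions")
    x = np.array([region_betas[k] for k in keys], dtype=float)
    y = np.array([region_gamma[k] for k in keys], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("region_betas/region_gamma: zero variance, "
                         "correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=len(keys))


def beta_age_regression(records: pd.DataFrame, value_col: str = "beta_hat",
                        age_col: str = "age",
                        conf_level: float = 0.95) -> AgeRegression:
    """OLS regression of per-subject exponent on age, with a slope CI."""
    sub = records.dropna(subset=[age_col, value_col])
    if len(sub) < 3:
        raise ValueError("records: need at least 3 subjects with ages")
    ages = np.asarray(sub[age_col], dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("age: all ages identical, slope undefined")
    res = stats.linregress(ages, np.asarray(sub[value_col], dtype=float))
    dof = len(sub) - 2
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dof)
    half = tcrit * res.stderr
    return AgeRegression(slope=float(res.slope), intercept=float(res.intercept),
                         ci_low=float(res.slope - half),
                         ci_high=float(res.slope + half), n=len(sub))


# §-style default sweep grid: two cutoffs per band, two orders, three FFT sizes.
DEFAULT_SWEEP = {"low_cutoffs": (4.0, 8.0), "high_cutoffs": (33.0, 50.0),
                 "orders": (5, 7), "nffts": (256, 1024, 2048)}


def robustness_sweep(cohort: Cohort,
                     bands: Sequence[Band] = (LOW_BAND, HIGH_BAND),
                     low_cutoffs: Sequence[float] = DEFAULT_SWEEP["low_cutoffs"],
                     high_cutoffs: Sequence[float] = DEFAULT_SWEEP["high_cutoffs"],
                     orders: Sequence[int] = DEFAULT_SWEEP["orders"],
                     nffts: Sequence[int] = DEFAULT_SWEEP["nffts"],
                     alpha: float = 0.05) -> SweepResult:
    """Re-fit exponents over the filter/FFT configuration grid.

    For each band, every combination of cutoff x order x FFT length is
    run through the full pipeline (filter, Welch, response-compensated
    weighted region fit, per-subject fits).  Configurations whose FFT
    length exceeds the signal length are skipped with a warning.  The
    homogeneity test is a one-way ANOVA of per-subject exponents with
    configuration as the factor, per region.
    """
    _require(cohort.n_channels >= 1, "cohort", "must be non-empty")
    n_sig = min(ts.n for ts in cohort.channels)
    region_rows, subject_rows = [], []
    for band in bands:
        kind = "lowpass" if band.name == "low" or band.f_hi <= 20 else "highpass"
        cutoffs = low_cutoffs if kind == "lowpass" else high_cutoffs
        for cutoff, order, nfft in itertools.product(cutoffs, orders, nffts):
            if nfft > n_sig:
                logger.warning("sweep: skipping nfft=%d > signal length %d",
                               nfft, n_sig)
                continue
            fspec = FilterSpec(kind, order=int(order), cutoff_hz=float(cutoff))
            cfg = {"band": band.name, "cutoff_hz": float(cutoff),
                   "order": int(order), "nfft": int(nfft)}
            for region, chans in sorted(cohort.by_region().items()):
                spectra = []
                for ts in chans:
                    from .filtering import apply_filter
                    spectra.append(welch_psd(apply_filter(ts, fspec),
                                             nperseg=nfft, nfft=nfft))
                summary = aggregate_region(spectra, region=region)
                fit = region_band_fit(summary, band)
                region_rows.append({**cfg, "region": region,
                                    "beta_hat": fit.beta,
                                    "se_beta": fit.se_beta})
            subj = per_subject_betas(cohort, band, filter_spec=fspec,
                                     nperseg=nfft, nfft=nfft)
            for _, row in subj.iterrows():
                subject_rows.append({**cfg, "region": row["region"],
                                     "subject_id": row["subject_id"],
                                     "beta_hat": row["beta_hat"]})
    region_table = pd.DataFrame(region_rows)
    subject_table = pd.DataFrame(subject_rows)
    if region_table.empty:
        return SweepResult(region_table=region_table,
                           subject_table=subject_table,
                           summary=pd.DataFrame())
    summary_rows = []
    for (band_name, region), grp in region_table.groupby(["band", "region"]):
        spread = float(grp["beta_hat"].max() - grp["beta_hat"].min())
        sub = subject_table[(subject_table["band"] == band_name)
                            & (subject_table["region"] == region)]
        configs = [g["beta_hat"].to_numpy()
                   for _, g in sub.groupby(["cutoff_hz", "order", "nfft"])]
        if len(configs) >= 2 and all(len(c) >= 2 for c in configs):
            F, p = stats.f_oneway(*configs)
        else:
            F, p = np.nan, np.nan
        summary_rows.append({"band": band_name, "region": region,
                             "max_abs_delta": spread,
                             "homogeneity_F": float(F),
                             "homogeneity_p": float(p),
                             "homogeneous": bool(p > alpha) if np.isfinite(p)
                             else None})
    return SweepResult(region_table=region_table, subject_table=subject_table,
                       summary=pd.DataFrame(summary_rows))
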