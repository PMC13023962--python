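"""Region aggregation, ANOVA/Tukey, correlations, robustness sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scalefree import (HIGH_BAND, LOW_BAND, SpectrumEstimate,
                       aggregate_region, beta_age_regression,
                       beta_gamma_correlation, per_subject_betas,
                       region_anova, region_band_fit, robustness_sweep,
                       tukey_hsd)
from scalefree.synthetic import Cohort


def _random_spectra(rng, n=30, bins=64):
    freqs = np.linspace(0, 100, bins)
    return [SpectrumEstimate(freqs, rng.uniform(0.5, 2.0, bins),
                             meta={"subject_id": f"s{i % 7}"})
            for i in range(n)]


def _records(groups):
    """Tidy per-subject table from a mapping region -> values."""
    rows = [{"region": g, "beta_hat": float(v), "subject_id": f"{g}{i}"}
            for g, vals in groups.items() for i, v in enumerate(vals)]
    return pd.DataFrame(rows)


class TestAggregateRegion:
    def test_single_spectrum(self, rng):
        sp = _random_spectra(rng, n=1)[0]
        summ = aggregate_region([sp], region="R")
        np.testing.assert_array_equal(summ.mean_psd.psd, sp.psd)
        assert np.all(summ.global_sd == 0.0)
        assert summ.n_channels == 1

    def test_identical_spectra_zero_sd(self, rng):
        sp = _random_spectra(rng, n=1)[0]
        summ = aggregate_region([sp, sp], region="R")
        assert np.all(summ.global_sd == 0.0)

    def test_matches_pooled_moment_oracle(self, rng):
        spectra = _random_spectra(rng, n=30)
        summ = aggregate_region(spectra, region="R")
        stack = np.vstack([sp.psd for sp in spectra])
        np.testing.assert_allclose(summ.mean_psd.psd, stack.mean(axis=0),
                                   atol=1e-12)
        np.testing.assert_allclose(summ.global_sd, stack.std(axis=0, ddof=0),
                                   atol=1e-12)

    def test_permutation_invariant(self, rng):
        spectra = _random_spectra(rng, n=10)
        a = aggregate_region(spectra, region="R")
        b = aggregate_region(spectra[::-1], region="R")
        np.testing.assert_allclose(a.mean_psd.psd, b.mean_psd.psd, rtol=1e-12)
        np.testing.assert_allclose(a.global_sd, b.global_sd, rtol=1e-9, atol=1e-12)

    def test_mismatched_grids_rejected(self, rng):
        a = _random_spectra(rng, n=1)[0]
        b = SpectrumEstimate(a.freqs * 2.0, a.psd)
        with pytest.raises(ValueError, match="grids differ"):
            aggregate_region([a, b])


class TestPerSubjectBetas:
    def test_single_channel_subject_has_zero_se(self, small_cohort):
        one = Cohort(channels=[small_cohort.channels[0]],
                     truth=small_cohort.truth.iloc[:1], spec=None)
        df = per_subject_betas(one, LOW_BAND)
        assert df.loc[0, "within_subject_se"] == 0.0
        assert df.loc[0, "n_channels"] == 1

    def test_identical_channels_zero_se(self, small_cohort):
        ts = small_cohort.channels[0]
        dup = Cohort(channels=[ts, ts.with_samples(ts.samples)],
                     truth=small_cohort.truth.iloc[:1], spec=None)
        df = per_subject_betas(dup, LOW_BAND)
        assert df.loc[0, "within_subject_se"] == 0.0
        assert df.loc[0, "n_channels"] == 2

    def test_intersubject_exceeds_intrasubject_variability(self, cohort_ab):
        df = per_subject_betas(cohort_ab, LOW_BAND)
        for region in ("A", "B"):
            grp = df[df["region"] == region]
            assert grp["within_subject_se"].mean() < grp["beta_hat"].std(ddof=1)


class TestRegionAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
        res = region_anova(_records({"A": a, "B": b}))
        t, _ = stats.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert (res.df_between, res.df_within) == (1, 15)

    @pytest.mark.parametrize("groups", [
        {"A": [1.0, 2.0]},                     # single group
        {"A": [1.0, 2.0], "B": [1.0]},         # group with < 2 records
    ])
    def test_degenerate_layouts_rejected(self, groups):
        with pytest.raises(ValueError, match="region"):
            region_anova(_records(groups))

    def test_agrees_with_permutation_reference(self, rng):
        agree = 0
        n_sets = 60
        for _ in range(n_sets):
            shift = rng.choice([0.0, 1.5])
            data = {g: rng.normal(shift if g == "C" else 0.0, 1.0, 6)
                    for g in "ABC"}
            rec = _records(data)
            p_f = region_anova(rec).p_value
            pooled = np.concatenate(list(data.values()))
            labels = np.repeat(list("ABC"), 6)
            obs = stats.f_oneway(*(pooled[labels == g] for g in "ABC"))[0]
            count = 0
            n_perm = 300
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                f = stats.f_oneway(*(perm[labels == g] for g in "ABC"))[0]
                count += f >= obs
            p_perm = (count + 1) / (n_perm + 1)
            agree += (p_f < 0.05) == (p_perm < 0.05)
        assert agree / n_sets >= 0.95


class TestTukey:
    def test_pair_count(self, rng):
        groups = {g: rng.normal(0, 1, 4) for g in "ABCDE"}
        table = tukey_hsd(_records(groups))
        assert len(table) == 10  # k(k-1)/2 for k=5

    def test_shifted_group_flagged(self, rng):
        hits = 0
        for _ in range(40):
            groups = {g: rng.normal(0, 1, 10) for g in "ABCD"}
            groups["D"] = groups["D"] + 5.0
            table = tukey_hsd(_records(groups))
            involving = table[(table.region_i == "D") | (table.region_j == "D")]
            others = table[(table.region_i != "D") & (table.region_j != "D")]
            hits += involving["significant"].all() and not others["significant"].any()
        assert hits / 40 >= 0.85

    def test_null_familywise_error_controlled(self, rng):
        fwer = 0
        n_sim = 300
        for _ in range(n_sim):
            groups = {g: rng.normal(0, 1, 6) for g in "ABCD"}
            fwer += tukey_hsd(_records(groups))["significant"].any()
        assert fwer / n_sim <= 0.07


class TestCorrelation:
    def test_exactly_linear(self):
        betas = {f"r{i}": 1.0 + 0.1 * i for i in range(6)}
        gamma = {f"r{i}": 0.2 + 0.05 * i for i in range(6)}
        res = beta_gamma_correlation(betas, gamma)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_matches_textbook_closed_form(self):
        x = np.array([1.2, 1.5, 1.9, 2.1, 2.6])
        y = np.array([0.3, 0.9, 0.4, 1.2, 0.8])
        res = beta_gamma_correlation({f"r{i}": v for i, v in enumerate(x)},
                                     {f"r{i}": v for i, v in enumerate(y)})
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert res.r == pytest.approx(r_hand, abs=1e-12)

    def test_null_p_values_uniform(self, rng):
        ps, rs = [], []
        for _ in range(500):
            betas = {f"r{i}": v for i, v in enumerate(rng.normal(2, 0.3, 37))}
            gamma = {f"r{i}": v for i, v in enumerate(rng.normal(1, 0.2, 37))}
            res = beta_gamma_correlation(betas, gamma)
            ps.append(res.p_value)
            rs.append(res.r)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert np.mean(np.abs(rs)) < 0.2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            beta_gamma_correlation({"a": 1.0, "b": 1.0, "c": 1.0},
                                   {"a": 0.1, "b": 0.2, "c": 0.3})


class TestAgeRegression:
    def test_exactly_linear_recovered(self):
        df = pd.DataFrame({"age": [20.0, 30, 40, 50],
                           "beta_hat": [1.0, 1.2, 1.4, 1.6]})
        res = beta_age_regression(df)
        assert res.slope == pytest.approx(0.02, abs=1e-12)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_underdetermined_rejected(self):
        df = pd.DataFrame({"age": [20.0, 30.0], "beta_hat": [1.0, 1.2]})
        with pytest.raises(ValueError, match="3 subjects"):
            beta_age_regression(df)

    def test_identical_ages_rejected(self):
        df = pd.DataFrame({"age": [30.0] * 5, "beta_hat": np.arange(5.0)})
        with pytest.raises(ValueError, match="age"):
            beta_age_regression(df)

    def test_null_slope_ci_coverage(self, rng):
        covered = 0
        n_sim = 500
        for _ in range(n_sim):
            df = pd.DataFrame({"age": rng.uniform(20, 60, 15),
                               "beta_hat": rng.normal(2.0, 0.3, 15)})
            res = beta_age_regression(df)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert 0.92 <= covered / n_sim <= 0.975


class TestRobustnessSweep:
    def test_grid_size_and_determinism(self, small_cohort):
        res = robustness_sweep(small_cohort, nffts=(256, 1024, 2048))
        n_regions = len(small_cohort.regions)
        for band in ("low", "high"):
            sub = res.region_table[res.region_table["band"] == band]
            assert len(sub) == 12 * n_regions  # 2 cutoffs x 2 orders x 3 nfft
        res2 = robustness_sweep(small_cohort, nffts=(256, 1024, 2048))
        pd.testing.assert_frame_equal(res.region_table, res2.region_table)

    def test_oversized_nfft_skipped_with_warning(self, small_cohort, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="scalefree.cohort_stats"):
            res = robustness_sweep(small_cohort, nffts=(4096,))
        assert res.region_table.empty
        assert any("skipping nfft" in r.message for r in caplog.records)

    def test_region_fit_weight_fallback_single_channel(self, small_cohort, rng):
        from scalefree import apply_filter, welch_psd, DEFAULT_HIGHPASS
        ts = small_cohort.channels[0]
        sp = welch_psd(apply_filter(ts, DEFAULT_HIGHPASS))
        summ = aggregate_region([sp], region="solo")
        fit = region_band_fit(summ, HIGH_BAND)
        assert np.isfinite(fit.beta)
        assert summ.fits["high"] is fit
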