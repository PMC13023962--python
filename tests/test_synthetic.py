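"""Generators: white/Brownian/1-over-f^beta noise, peaks, cohorts."""

import numpy as np
import pytest
from scipy import stats

from scalefree import (Band, CohortSpec, LOW_BAND, NoiseSpec, PeakSpec,
                       add_oscillatory_peak, fit_band_exponent,
                       gen_brownian_noise, gen_cohort, gen_powerlaw_noise,
                       gen_white_noise, welch_psd)


def _low_band_beta(ts, **kw):
    return fit_band_exponent(ts, LOW_BAND, **kw).beta


class TestWhiteNoise:
    def test_moments(self):
        spec = NoiseSpec("white", n_samples=12000, mu=0.0, sigma=1.0, seed=1)
        ts = gen_white_noise(spec)
        assert abs(ts.samples.mean()) < 4.0 / np.sqrt(12000)
        assert abs(ts.samples.std() - 1.0) < 0.05

    def test_degenerate_sigma_zero(self):
        ts = gen_white_noise(NoiseSpec("white", n_samples=50, mu=3.0, sigma=0.0))
        assert np.all(ts.samples == 3.0)

    def test_reproducible(self):
        a = gen_white_noise(NoiseSpec("white", seed=5))
        b = gen_white_noise(NoiseSpec("white", seed=5))
        assert np.array_equal(a.samples, b.samples)


@pytest.mark.parametrize("kwargs, field", [
    ({"kind": "pink"}, "kind"),
    ({"kind": "white", "n_samples": 1}, "n_samples"),
    ({"kind": "white", "fs": 0.0}, "fs"),
    ({"kind": "white", "sigma": -1.0}, "sigma"),
    ({"kind": "white", "seed": -1}, "seed"),
    ({"kind": "powerlaw"}, "beta_true"),
    ({"kind": "powerlaw", "beta_true": -0.5}, "beta_true"),
    ({"kind": "powerlaw", "beta_true": float("nan")}, "beta_true"),
])
def test_noise_spec_validation_names_field(kwargs, field):
    with pytest.raises(ValueError, match=field):
        NoiseSpec(**kwargs)


class TestBrownianNoise:
    def test_first_difference_is_white_sequence(self):
        w = gen_white_noise(NoiseSpec("white", mu=0.0, sigma=0.7, seed=3))
        b = gen_brownian_noise(NoiseSpec("brownian", sigma=0.7, seed=3))
        np.testing.assert_allclose(np.diff(b.samples, prepend=0.0), w.samples,
                                   rtol=0, atol=1e-12)

    def test_ensemble_variance_grows_linearly(self):
        # Var[B_k] = k * sigma^2 for a random walk
        walks = np.vstack([
            gen_brownian_noise(NoiseSpec("brownian", n_samples=400, seed=s)).samples
            for s in range(200)])
        var = walks.var(axis=0)
        k = np.arange(1, 401)
        r = stats.linregress(k, var)
        assert r.rvalue**2 > 0.95


class TestPowerlawNoise:
    def test_beta_zero_indistinguishable_from_white(self):
        # two-sample comparison of fitted exponents over 50 realizations
        pl = [_low_band_beta(gen_powerlaw_noise(
            NoiseSpec("powerlaw", beta_true=0.0, seed=s))) for s in range(50)]
        wh = [_low_band_beta(gen_white_noise(NoiseSpec("white", seed=1000 + s)))
              for s in range(50)]
        _, p = stats.ttest_ind(pl, wh)
        assert p > 0.01

    def test_fitted_exponent_monotone_in_beta_true(self):
        grid = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5]
        means = []
        for beta in grid:
            vals = [_low_band_beta(gen_powerlaw_noise(
                NoiseSpec("powerlaw", beta_true=beta, seed=s)))
                for s in range(8)]
            means.append(np.mean(vals))
        rho, _ = stats.spearmanr(grid, means)
        assert rho == 1.0

    def test_matches_brownian_in_deep_low_band(self):
        # Away from the Nyquist flattening of the discrete random walk,
        # the two beta=2 generators must agree.
        pl = np.mean([_low_band_beta(gen_powerlaw_noise(
            NoiseSpec("powerlaw", beta_true=2.0, seed=s))) for s in range(10)])
        br = np.mean([_low_band_beta(gen_brownian_noise(
            NoiseSpec("brownian", seed=s))) for s in range(10)])
        assert abs(pl - br) < 0.1

    def test_output_sd_matches_sigma(self):
        ts = gen_powerlaw_noise(NoiseSpec("powerlaw", beta_true=1.0,
                                          sigma=2.5, seed=0))
        assert np.isclose(ts.samples.std(), 2.5)

    def test_bias_shrinks_with_length(self):
        # white -> 0 and brownian -> ~2 as n grows, checked in the low band
        # with segments growing alongside n
        def mean_abs_white(n):
            return np.mean([abs(_low_band_beta(
                gen_white_noise(NoiseSpec("white", n_samples=n, seed=s)),
                nperseg=max(256, n // 8))) for s in range(6)])

        def abs_brownian_bias(n):
            return abs(np.mean([_low_band_beta(
                gen_brownian_noise(NoiseSpec("brownian", n_samples=n, seed=s)),
                nperseg=max(256, n // 8)) for s in range(6)]) - 2.0)

        white = [mean_abs_white(n) for n in (2_000, 20_000, 200_000)]
        brown = [abs_brownian_bias(n) for n in (2_000, 20_000, 200_000)]
        assert white[0] > white[1] > white[2]
        assert brown[0] > brown[1] > brown[2]


class TestOscillatoryPeak:
    def test_amplitude_zero_is_identity(self):
        ts = gen_powerlaw_noise(NoiseSpec("powerlaw", beta_true=1.0, seed=2))
        out = add_oscillatory_peak(ts, PeakSpec(amplitude=0.0))
        assert np.array_equal(out.samples, ts.samples)

    def test_rejects_peak_above_nyquist(self):
        ts = gen_powerlaw_noise(NoiseSpec("powerlaw", beta_true=1.0, seed=2))
        with pytest.raises(ValueError, match="center_freq"):
            add_oscillatory_peak(ts, PeakSpec(center_freq=150.0))

    def test_peak_rises_above_interpolated_background(self):
        ts = gen_powerlaw_noise(NoiseSpec("powerlaw", beta_true=1.0, seed=4))
        out = add_oscillatory_peak(ts, PeakSpec(10.0, 2.0, amplitude=10.0, seed=9))
        sp = welch_psd(out)

        def band_mean(f_lo, f_hi):
            m = (sp.freqs >= f_lo) & (sp.freqs <= f_hi)
            return np.log10(sp.psd[m]).mean()

        # log-linear interpolation of the background between 4 and 20 Hz
        y4, y20 = band_mean(3.8, 4.2), band_mean(19.5, 20.5)
        x = (np.log10(10) - np.log10(4)) / (np.log10(20) - np.log10(4))
        interp = y4 + x * (y20 - y4)
        assert band_mean(9, 11) > interp + 0.3

    def test_background_conserved_outside_peak(self):
        ts = gen_powerlaw_noise(NoiseSpec("powerlaw", beta_true=1.0, seed=4))
        out = add_oscillatory_peak(ts, PeakSpec(10.0, 2.0, amplitude=10.0, seed=9))
        before, after = welch_psd(ts), welch_psd(out)
        outside = ((after.freqs > 0) & ((after.freqs < 10 - 4)
                                        | (after.freqs > 10 + 4)))
        ratio = after.psd[outside].mean() / before.psd[outside].mean()
        assert abs(ratio - 1.0) < 0.05


class TestCohort:
    def test_counts_and_truth_table(self, small_cohort):
        spec = small_cohort.spec
        expected = (len(spec.regions) * spec.n_subjects_per_region
                    * spec.n_channels_per_subject)
        assert small_cohort.n_channels == expected
        assert len(small_cohort.truth) == expected
        assert {"true_beta_low", "true_beta_high"} <= set(small_cohort.truth)

    def test_fixed_seed_bit_identical(self):
        spec = CohortSpec(regions={"A": 1.0}, n_subjects_per_region=2,
                          n_channels_per_subject=2, duration_s=10.24, seed=3)
        a, b = gen_cohort(spec), gen_cohort(spec)
        for ts_a, ts_b in zip(a.channels, b.channels):
            assert np.array_equal(ts_a.samples, ts_b.samples)

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError, match="regions"):
            CohortSpec(regions={})

    def test_between_exceeds_within_variance(self):
        spec = CohortSpec(regions={"A": 1.5}, n_subjects_per_region=20,
                          n_channels_per_subject=5, between_subject_sd=0.3,
                          within_subject_sd=0.1, duration_s=60.0, seed=21)
        cohort = gen_cohort(spec)
        betas, groups = [], []
        for i, ((_, subj), chans) in enumerate(sorted(cohort.by_subject().items())):
            for ts in chans:
                betas.append(_low_band_beta(ts))
                groups.append(i)
        betas, groups = np.array(betas), np.array(groups)
        # one-way variance-components estimate on the fitted values
        k = len(np.unique(groups))
        n_per = 5
        grand = betas.mean()
        means = np.array([betas[groups == g].mean() for g in range(k)])
        msb = n_per * np.sum((means - grand) ** 2) / (k - 1)
        msw = np.sum((betas - means[groups]) ** 2) / (len(betas) - k)
        between_component = (msb - msw) / n_per
        assert between_component > msw

    def test_region_means_recovered(self, cohort_ab):
        from scalefree import per_subject_betas
        df = per_subject_betas(cohort_ab, LOW_BAND)
        spec = cohort_ab.spec
        # known-variance SE of the region mean from the generator's own
        # hierarchy: subject offsets plus channel offsets averaged per subject
        se = np.sqrt(spec.between_subject_sd**2
                     + spec.within_subject_sd**2 / spec.n_channels_per_subject
                     ) / np.sqrt(spec.n_subjects_per_region)
        for region, true_beta in (("A", 1.5), ("B", 2.0)):
            grp = df[df["region"] == region]["beta_hat"]
            assert abs(grp.mean() - true_beta) < 2 * se
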