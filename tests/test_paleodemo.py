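"""Mean-KDE estimation: clustering, bootstrap KDE properties, synthetic
date generation, recovery of a known occupation curve."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from ismpop import DatedSample, DensitySeries, cluster_dates, mean_kde, synthetic_dates
from ismpop.paleodemo import DEFAULT_TRIM, DEFAULT_WINDOW
from ismpop.synthetic import ScenarioSpec, make_density_scenario


def flat_curve():
    centers = np.arange(3985.0, 200.0, -30.0)
    return DensitySeries(bin_centers=centers, values=np.ones_like(centers))


class TestClusterDates:
    def test_single_linkage_cut(self):
        # brute force: 1000-1050 chain (gap 50 <= h); 1400 is 350 away
        s = [DatedSample("a", 1000, 10), DatedSample("a", 1050, 10), DatedSample("a", 1400, 10)]
        got = sorted(sorted(c) for c in cluster_dates(s, h=100))
        assert got == [[0, 1], [2]]

    def test_distinct_sites_never_merge(self):
        s = [DatedSample(f"s{i}", 1000.0, 5) for i in range(6)]
        assert sorted(len(c) for c in cluster_dates(s, h=100)) == [1] * 6

    def test_identical_ages_one_site_single_cluster(self):
        s = [DatedSample("a", 2000.0, 5) for _ in range(4)]
        assert [sorted(c) for c in cluster_dates(s, h=100)] == [[0, 1, 2, 3]]

    def test_empty_input(self):
        assert cluster_dates([], h=100) == []

    def test_chaining_behaviour(self):
        # consecutive gaps of 80 chain into one cluster even over 240 years
        s = [DatedSample("a", 1000 + 80 * i, 5) for i in range(4)]
        assert len(cluster_dates(s, h=100)) == 1


class TestMeanKDE:
    def test_single_sample_is_unit_gaussian_bump(self):
        k = mean_kde([DatedSample("x", 2000.0, 0.0)], n_iter=1, seed=0, trim=None)
        assert k.mean.sum() == pytest.approx(1.0, abs=1e-6)
        assert abs(k.bin_calBP[np.argmax(k.mean)] - 2000.0) <= 30.0

    def test_identical_seeds_identical_runs(self):
        sc = make_density_scenario(ScenarioSpec("bimodal_occupation", seed=1))
        dates = synthetic_dates(sc.series, n=120, seed=4)
        a = mean_kde(dates, n_iter=5, seed=11)
        b = mean_kde(dates, n_iter=5, seed=11)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.lo, b.lo)

    def test_order_invariance(self):
        sc = make_density_scenario(ScenarioSpec("bimodal_occupation", seed=1))
        dates = synthetic_dates(sc.series, n=80, seed=4)
        a = mean_kde(dates, n_iter=5, seed=11)
        b = mean_kde(dates[::-1], n_iter=5, seed=11)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)

    def test_envelope_brackets_mean(self):
        sc = make_density_scenario(ScenarioSpec("bimodal_occupation", seed=1))
        dates = synthetic_dates(sc.series, n=150, seed=4)
        k = mean_kde(dates, n_iter=30, seed=11)
        assert np.all(k.lo <= k.mean + 1e-12)
        assert np.all(k.mean <= k.hi + 1e-12)
        assert np.all(np.diff(k.bin_calBP) == -30.0)

    def test_trim_window(self):
        sc = make_density_scenario(ScenarioSpec("bimodal_occupation", seed=1))
        dates = synthetic_dates(sc.series, n=60, seed=4)
        k = mean_kde(dates, n_iter=2, seed=0)
        assert k.bin_calBP.max() <= DEFAULT_TRIM[0]
        assert k.bin_calBP.min() >= DEFAULT_TRIM[1]

    def test_oversampling_neutralized_by_clustering(self):
        """Piling extra dates within h onto one occupation leaves the
        expected clustered mean KDE (nearly) unchanged, while without
        clustering the oversampled episode dominates the curve."""
        base = [
            DatedSample("a", 3000.0, 0.0), DatedSample("a", 1500.0, 0.0),
            DatedSample("b", 2400.0, 0.0),
        ]
        extra = [DatedSample("a", 3000.0 + off, 0.0) for off in (-10.0, 5.0, 10.0)]
        oversampled = base + extra

        def expected(samples, h, n_seeds=200):
            return np.mean(
                [mean_kde(samples, n_iter=2, h=h, seed=s).mean for s in range(n_seeds)],
                axis=0,
            )

        ka = expected(base, h=100.0)
        kb = expected(oversampled, h=100.0)
        # clustered: weight per occupation unchanged; only a <=10 yr smear
        assert np.max(np.abs(ka - kb)) < 0.10 * ka.max()
        # degenerate clustering (h below the offsets): the 3000 cal BP
        # episode carries 4 of 6 clusters and its peak roughly doubles
        kc = expected(oversampled, h=1.0, n_seeds=20)
        peak_bin = np.argmax(ka)
        assert kc[peak_bin] > 1.5 * ka[peak_bin]

    def test_validation(self):
        with pytest.raises(ValueError):
            mean_kde([], n_iter=1)
        with pytest.raises(ValueError):
            mean_kde([DatedSample("a", 1000, 1)], n_iter=0)
        with pytest.raises(ValueError):
            mean_kde([DatedSample("a", 1000, 1)], bandwidth=0.0)

    def test_age_sampler_hook(self):
        """A custom per-sample age distribution replaces the Gaussian."""
        k = mean_kde(
            [DatedSample("x", 2000.0, 500.0)],
            n_iter=3, seed=0,
            age_sampler=lambda s, rng: 1000.0,
        )
        assert abs(k.bin_calBP[np.argmax(k.mean)] - 1000.0) <= 30.0


class TestSyntheticDates:
    def test_uniform_curve_uniform_histogram(self):
        """Inverse-CDF sampling from a flat curve passes a chi-square GOF."""
        dates = synthetic_dates(flat_curve(), n=5000, seed=3)
        ages = np.array([s.age for s in dates])
        hist, _ = np.histogram(ages, bins=10)
        assert chisquare(hist).pvalue > 0.01

    def test_single_record_in_window(self):
        (s,) = synthetic_dates(flat_curve(), n=1, seed=0)
        assert DEFAULT_WINDOW[1] <= s.age <= DEFAULT_WINDOW[0]

    def test_seed_reproducibility(self):
        a = synthetic_dates(flat_curve(), n=20, seed=9)
        b = synthetic_dates(flat_curve(), n=20, seed=9)
        assert a == b

    def test_preferential_attachment_oversamples(self):
        dates = synthetic_dates(flat_curve(), n=2000, n_sites=40, seed=1)
        counts = np.array(
            [sum(s.site == f"site{j:03d}" for s in dates) for j in range(40)]
        )
        assert counts.max() > 3 * np.median(counts[counts > 0])

    def test_zero_curve_rejected(self):
        curve = DensitySeries(
            bin_centers=np.arange(3985.0, 200.0, -30.0),
            values=np.zeros(len(np.arange(3985.0, 200.0, -30.0))),
        )
        with pytest.raises(ValueError):
            synthetic_dates(curve, n=5, seed=0)


class TestRecovery:
    def test_bimodal_occupation_recovered(self):
        """Mean KDE rank-correlates > 0.8 with the generating curve."""
        sc = make_density_scenario(ScenarioSpec("bimodal_occupation", seed=1))
        dates = synthetic_dates(sc.series, n=600, seed=2)
        k = mean_kde(dates, n_iter=60, bandwidth=50.0, h=100.0, seed=3)
        truth = np.interp(
            k.bin_calBP, sc.series.bin_centers[::-1], sc.series.values[::-1]
        )
        assert spearmanr(k.mean, truth).statistic > 0.8

    def test_forward_series_feeds_diagnostics(self):
        from ismpop import fit_logistic_trend

        # monotone growth toward the present -> positive fitted rate
        centers = np.arange(3985.0, 200.0, -30.0)
        curve = DensitySeries(
            bin_centers=centers,
            values=1.0 / (1 + np.exp((centers - 2000.0) / 300.0)),
        )
        dates = synthetic_dates(curve, n=500, seed=5)
        k = mean_kde(dates, n_iter=40, seed=6)
        fit = fit_logistic_trend(k.to_forward_series())
        assert fit.converged and fit.rate > 0
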