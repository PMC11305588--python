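"""Phase-plane diagnostics: growth, paths, transition/cycle detection,
recession summaries, logistic trend fitting."""

import numpy as np
import pytest

from ismpop import (
    DensitySeries,
    InfrastructureRegime,
    ISMParameters,
    PhasePath,
    ClimateModel,
    bin_trajectory,
    detect_cycles,
    detect_transitions,
    fit_logistic_trend,
    per_capita_growth,
    phase_path,
    recession_summary,
    simulate,
)
from ismpop.synthetic import ScenarioSpec, make_density_scenario


def series(values, start=0.0, step=1.0):
    values = np.asarray(values, dtype=float)
    return DensitySeries(
        bin_centers=start + step * np.arange(len(values)), values=values
    )


def ellipse_path(turns, n_per_turn=200, center=5.0, rx=2.0, ry=0.1):
    t = np.linspace(0, 2 * np.pi * turns, int(n_per_turn * turns) + 1)
    return PhasePath(
        density=center + rx * np.cos(t),
        growth=ry * np.sin(t),
        indices=np.arange(len(t)),
    )


class TestPerCapitaGrowth:
    def test_constant_series_is_zero(self):
        assert np.allclose(per_capita_growth(series([2.0] * 5)), 0.0)

    def test_log_identity(self):
        g = per_capita_growth(series([1.0, np.e, np.e**2]))
        np.testing.assert_allclose(g, [1.0, 1.0], atol=1e-12)

    def test_doubling(self):
        g = per_capita_growth(series([1, 2, 4, 8]))
        np.testing.assert_allclose(g, np.log(2.0), atol=1e-12)

    def test_exponential_growth_is_constant(self):
        v = 0.3 * np.exp(0.07 * np.arange(50))
        g = per_capita_growth(series(v))
        assert np.ptp(g) < 1e-12

    def test_zero_bins_flagged_not_fabricated(self):
        with pytest.warns(UserWarning, match="undefined"):
            g = per_capita_growth(series([1.0, 0.0, 2.0, 3.0]))
        assert np.isnan(g[0]) and np.isnan(g[1]) and np.isfinite(g[2])


class TestPhasePath:
    def test_logistic_path_endpoints(self):
        """Path runs from (~0, ~r) to (~p*, ~0) for a logistic run."""
        traj = simulate(
            ISMParameters(r=0.25, S=0.5, p0=0.001, dt=0.01, horizon=120.0), seed=0
        )
        pp = phase_path(bin_trajectory(traj))
        assert pp.density[0] < 0.01 and abs(pp.growth[0] - 0.25) < 0.03
        assert abs(pp.density[-1] - 0.5) < 0.01 and abs(pp.growth[-1]) < 1e-3

    def test_constant_series_sits_at_zero_growth(self):
        pp = phase_path(series([1.0] * 6))
        assert np.allclose(pp.growth, 0.0)

    def test_set2_path_has_hook(self, set2_A_runs):
        """Overshoot-recession shows as growth < 0 past the density maximum."""
        pp = phase_path(bin_trajectory(set2_A_runs[0]))
        assert (pp.growth[np.argmax(pp.density) :] < 0).any()

    def test_pairing_and_exclusions(self):
        with pytest.warns(UserWarning, match="excluding"):
            pp = phase_path(series([1.0, 2.0, 0.0, 4.0, 5.0]))
        # growth_t pairs with density_t; bins touching the zero are dropped
        assert list(pp.indices) == [0, 3]
        assert pp.density[0] == 1.0


class TestDetectTransitions:
    def test_monotone_logistic_has_none(self):
        sc = make_density_scenario(ScenarioSpec("logistic", n=120, seed=0))
        assert detect_transitions(phase_path(sc.series)) == []

    def test_two_epoch_jump_yields_one_event_at_jump(self):
        sc = make_density_scenario(ScenarioSpec("two_epoch_jump", n=120, seed=0))
        events = detect_transitions(phase_path(sc.series))
        assert len(events) == 1
        assert abs(events[0].peak - sc.truth["jump_bin"]) <= 3
        assert events[0].density_end > events[0].density_start

    def test_four_rung_ladder_yields_three(self, ladder_run):
        events = detect_transitions(phase_path(bin_trajectory(ladder_run)))
        assert len(events) == 3
        for a, b in zip(events[:-1], events[1:]):
            assert a.end <= b.start  # disjoint, chronological

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_constructed_jump_count_recovery(self, k):
        """k well-separated capacity jumps give exactly k events."""
        v = []
        p = 0.05
        caps = [1.0 * 2**i for i in range(k + 1)]
        for K in caps:
            for _ in range(40):
                p = p + 0.3 * p * (1 - p / K)
                v.append(p)
        events = detect_transitions(phase_path(series(v)))
        assert len(events) == k

    def test_scale_invariance(self, ladder_run):
        s = bin_trajectory(ladder_run)
        scaled = DensitySeries(bin_centers=s.bin_centers, values=s.values * 1e-4)
        a = detect_transitions(phase_path(s))
        b = detect_transitions(phase_path(scaled))
        assert [(e.start, e.peak, e.end) for e in a] == [
            (e.start, e.peak, e.end) for e in b
        ]


class TestDetectCycles:
    @pytest.mark.parametrize("turns", [1, 2, 4])
    def test_winding_number_recovered(self, turns):
        events = detect_cycles(ellipse_path(turns))
        assert len(events) == turns
        for e in events:
            assert abs(e.center_density - 5.0) < 0.2

    def test_monotone_path_has_none(self):
        pp = PhasePath(
            density=np.linspace(1, 2, 50),
            growth=np.full(50, 0.1),
            indices=np.arange(50),
        )
        assert detect_cycles(pp) == []

    def test_damped_hook_is_not_a_full_cycle(self, set2_A_runs):
        pp = phase_path(bin_trajectory(set2_A_runs[-1]))
        assert detect_cycles(pp) == []
        assert (pp.growth[np.argmax(pp.density) :] < 0).any()  # hook exists

    def test_scale_invariance(self):
        p1 = ellipse_path(2)
        p2 = PhasePath(density=p1.density * 1000, growth=p1.growth, indices=p1.indices)
        assert len(detect_cycles(p1)) == len(detect_cycles(p2))


class TestRecessionSummary:
    def test_plain_logistic_has_no_recession(self):
        traj = simulate(
            ISMParameters(r=0.25, S=0.5, p0=0.01, dt=0.01, horizon=150.0), seed=0
        )
        rs = recession_summary(traj)
        assert rs.overshoot < 1e-9
        assert rs.negative_fitness_duration == 0.0
        assert rs.equilibrium == pytest.approx(0.5)

    def test_started_at_equilibrium(self):
        traj = simulate(
            ISMParameters(r=0.25, S=0.5, p0=0.5, dt=0.01, horizon=50.0), seed=0
        )
        assert recession_summary(traj).overshoot == 0.0

    def test_larger_A_larger_overshoot(self, set2_A_runs):
        first = recession_summary(set2_A_runs[0])
        last = recession_summary(set2_A_runs[-1])
        assert last.overshoot > first.overshoot
        assert first.negative_fitness_duration > 0


class TestLogisticTrend:
    def test_noiseless_recovery(self):
        t = np.arange(100, dtype=float)
        v = 3.0 / (1 + np.exp(-0.2 * (t - 40.0)))
        fit = fit_logistic_trend(series(v))
        assert fit.converged
        assert fit.capacity == pytest.approx(3.0, rel=1e-2)
        assert fit.rate == pytest.approx(0.2, rel=1e-2)
        assert fit.midpoint == pytest.approx(40.0, rel=1e-2)

    def test_constant_series_degenerate(self):
        fit = fit_logistic_trend(series([2.0] * 10))
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_noisy_capacity_recovery(self, rng):
        """Median capacity error < 5% under 5% multiplicative-range noise."""
        errors = []
        t = np.arange(100, dtype=float)
        truth = 2.0 / (1 + np.exp(-0.15 * (t - 45.0)))
        for _ in range(60):
            noisy = np.clip(truth + rng.normal(0, 0.05 * np.ptp(truth), len(t)), 0, None)
            fit = fit_logistic_trend(series(noisy))
            if fit.converged:
                errors.append(abs(fit.capacity - 2.0) / 2.0)
        assert np.median(errors) < 0.05

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic_trend(series([1, 2, 3]))

    def test_mean_kde_trend_rate_positive_for_growth(self):
        """Monotone-increasing occupation implies a positive fitted rate."""
        t = np.arange(80, dtype=float)
        v = 1.0 / (1 + np.exp(-0.1 * (t - 30)))
        fit = fit_logistic_trend(series(v))
        assert fit.converged and fit.rate > 0
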