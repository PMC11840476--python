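"""Scenario generators: samplers, censoring solver, event-driven trials, truths."""

import numpy as np
import pytest

from nphtrial import (
    IllnessDeath,
    PiecewiseHazard,
    ScenarioSpec,
    delayed_scenario,
    null_scenario,
    sample_multistate,
    sample_piecewise,
    simulate_trial,
    solve_censoring_rate,
    subgroup_scenario,
    tmax_horizon,
    true_summaries,
)

LAM = np.log(2) / 12.0  # control hazard per month, median 12 months


class TestPiecewiseSampling:
    def test_exponential_mean_and_median(self):
        rng = np.random.default_rng(211)
        haz = PiecewiseHazard.exponential(0.693 / 12.0)
        t = sample_piecewise(haz, 100_000, rng)
        assert np.mean(t) == pytest.approx(12.0 / 0.693, rel=0.02)
        assert np.median(t) == pytest.approx(12.0, rel=0.02)

    def test_two_piece_survival_at_breakpoints(self):
        rng = np.random.default_rng(223)
        haz = PiecewiseHazard((0.0, 6.0), (0.02, 0.08))
        n = 100_000
        t = sample_piecewise(haz, n, rng)
        for point in (3.0, 6.0, 12.0, 20.0):
            s_true = float(haz.survival(point))
            emp = np.mean(t > point)
            assert abs(emp - s_true) < 4 * np.sqrt(s_true * (1 - s_true) / n)

    def test_inverse_cumhaz_round_trip(self):
        haz = PiecewiseHazard((0.0, 2.0, 8.0), (0.1, 0.0, 0.3))
        for h in (0.05, 0.2, 0.21, 1.5):
            t = haz.inverse_cumhaz(h)
            assert float(haz.cumhaz(t)) == pytest.approx(h, abs=1e-12)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sample_piecewise(PiecewiseHazard((0.0,), (0.0,)), 5, np.random.default_rng(1))


class TestMultistate:
    def test_no_progression_reduces_to_exponential(self):
        rng = np.random.default_rng(227)
        ms = IllnessDeath(h_prog=0.0, h_death_pre=0.05, h_death_post=0.1)
        os, prog = sample_multistate(ms, 50_000, rng)
        assert np.all(np.isnan(prog))
        assert np.mean(os) == pytest.approx(20.0, rel=0.02)

    def test_progression_proportion_closed_form(self):
        rng = np.random.default_rng(229)
        ms = IllnessDeath(h_prog=0.02, h_death_pre=0.06, h_death_post=0.1)
        _, prog = sample_multistate(ms, 100_000, rng)
        assert np.isfinite(prog).mean() == pytest.approx(0.25, abs=0.006)

    def test_overall_survival_matches_analytic_mixture(self):
        rng = np.random.default_rng(233)
        ms = IllnessDeath(h_prog=0.02, h_death_pre=0.04, h_death_post=0.12)
        n = 100_000
        os, _ = sample_multistate(ms, n, rng)
        for point in (6.0, 12.0, 24.0, 48.0):
            s_true = float(ms.survival(point))
            assert abs(np.mean(os > point) - s_true) < 4 * np.sqrt(
                s_true * (1 - s_true) / n
            )

    def test_analytic_survival_against_numeric_integration(self):
        # integrate the density of the two-path convolution mixture
        from scipy.integrate import quad

        ms = IllnessDeath(h_prog=0.03, h_death_pre=0.05, h_death_post=0.09)
        a, b, c = ms.h_prog, ms.h_death_pre, ms.h_death_post

        def os_density(t):
            direct = b * np.exp(-(a + b) * t)
            conv, _ = quad(
                lambda u: a * np.exp(-(a + b) * u) * c * np.exp(-c * (t - u)), 0, t
            )
            return direct + conv

        for point in (5.0, 15.0, 40.0):
            s_num, _ = quad(os_density, point, np.inf)
            assert float(ms.survival(point)) == pytest.approx(s_num, abs=1e-8)


class TestHorizonAndCensoring:
    def test_exponential_closed_form(self):
        haz = PiecewiseHazard.exponential(LAM)
        assert tmax_horizon(haz, haz) == pytest.approx(np.log(1e4) / LAM)
        assert tmax_horizon(haz, haz) == pytest.approx(12 * np.log(1e4) / np.log(2))

    def test_unequal_arms_take_larger_horizon(self):
        h0 = PiecewiseHazard.exponential(LAM)
        h1 = PiecewiseHazard.exponential(LAM / 2)
        assert tmax_horizon(h0, h1) == pytest.approx(np.log(1e4) / (LAM / 2))

    def test_zero_target_gives_zero_rate(self):
        h = PiecewiseHazard.exponential(LAM)
        assert solve_censoring_rate(h, h, 0.0).rate == 0.0

    def test_equal_exponential_arms_closed_form(self):
        h = PiecewiseHazard.exponential(LAM)
        spec = solve_censoring_rate(h, h, 0.10)
        assert spec.rate == pytest.approx(LAM * 0.1 / 0.9, rel=1e-10)

    def test_simulated_censoring_proportion_hits_target(self):
        # competing exponential censoring without administrative cutoff
        rng = np.random.default_rng(239)
        h = PiecewiseHazard.exponential(LAM)
        spec = solve_censoring_rate(h, h, 0.10)
        n = 200_000
        t = rng.exponential(1 / LAM, n)
        c = rng.exponential(1 / spec.rate, n)
        censored = np.mean((c < t) & (c < spec.tmax))
        assert censored == pytest.approx(0.10, abs=0.003)


class TestSimulateTrial:
    def test_no_censoring_all_events_when_target_is_n(self):
        spec = null_scenario(n=80, target_events=80, censor_prop=0.0)
        data = simulate_trial(spec, np.random.default_rng(241))
        assert len(data) == 80 and data.n_events == 80

    def test_event_count_equals_target(self):
        data = simulate_trial(null_scenario(), np.random.default_rng(251))
        assert data.n_events == 375

    def test_administrative_censoring_bookkeeping(self):
        data = simulate_trial(null_scenario(), np.random.default_rng(257))
        calendar_end = data.recruit_time + data.obs_time
        cutoff = calendar_end.max()
        # the cutoff is the calendar time of the target-th event
        event_cal = np.sort(calendar_end[data.event])
        assert cutoff == pytest.approx(event_cal[-1])
        admin = ~data.event & np.isclose(calendar_end, cutoff)
        assert admin.sum() > 0  # the null design always censors ongoing subjects
        assert np.all(calendar_end <= cutoff + 1e-9)

    def test_seeded_reproducibility(self):
        spec = delayed_scenario(4.0)
        a = simulate_trial(spec, np.random.default_rng(263))
        b = simulate_trial(spec, np.random.default_rng(263))
        np.testing.assert_array_equal(a.obs_time, b.obs_time)
        np.testing.assert_array_equal(a.event, b.event)
        np.testing.assert_array_equal(a.arm, b.arm)

    def test_unreachable_target_warns_and_returns_full_followup(self):
        spec = null_scenario(n=40, target_events=40, censor_prop=0.5)
        with pytest.warns(UserWarning, match="never reached"):
            data = simulate_trial(spec, np.random.default_rng(269))
        assert len(data) == 40

    def test_subgroup_labels_recorded(self):
        spec = subgroup_scenario(0.5, 0.3, n=200, target_events=150)
        data = simulate_trial(spec, np.random.default_rng(271))
        assert set(np.unique(data.subgroup)) == {"pos", "neg"}


class TestTrueSummaries:
    def test_null_scenario_all_zero(self):
        ts = true_summaries(null_scenario())
        assert ts["median_diff"] == 0.0
        for L in (6, 12, 24):
            assert ts[f"rmst_diff_{L}"] == 0.0
            assert ts[f"milestone_diff_{L}"] == 0.0
            assert ts[f"ahr_{L}"] == pytest.approx(1.0)

    def test_delayed_rmst_against_riemann_sum(self):
        spec = delayed_scenario(8.0)
        ts = true_summaries(spec, cutoffs=(24.0,))
        grid = np.linspace(0.0, 24.0, 2_000_001)
        s0 = spec.control.survival(grid)
        s1 = spec.treatment.survival(grid)
        riemann = np.trapezoid(s1 - s0, grid)
        assert ts["rmst_diff_24"] == pytest.approx(riemann, abs=1e-6)

    def test_subgroup_marginal_is_prevalence_weighted_mixture(self):
        spec = subgroup_scenario(0.3, 0.3)
        model = spec.treatment
        for t in (3.0, 10.0, 30.0):
            expected = 0.3 * model.pos.survival(t) + 0.7 * model.neg.survival(t)
            assert float(model.survival(t)) == pytest.approx(float(expected))

    def test_yaml_round_trip(self, tmp_path):
        spec = subgroup_scenario(0.5, 0.3)
        path = tmp_path / "scenario.yaml"
        spec.to_yaml(path)
        back = ScenarioSpec.from_yaml(path)
        assert back.to_dict() == spec.to_dict()
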