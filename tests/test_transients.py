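"""Integration, outcome classification, ghost diagnostics, debts, perturbations."""

import math

import numpy as np
import pytest

import sesdebt as sd
from sesdebt import bifurcation as bif
from sesdebt import transients as tr

EQ_FREE = np.array([700.0, 625.0, 2500.0 / 3.0])


class TestIntegrate:
    def test_fixed_point_is_held(self, params, fast_opts):
        traj = sd.integrate("extended", EQ_FREE, params.replace(h=0.0), (0.0, 10_000.0), fast_opts)
        assert np.max(np.abs(traj.y_end - EQ_FREE) / EQ_FREE) < 1e-6

    def test_richness_relaxation_matches_closed_form(self, params):
        """With frozen habitat, S(t) = Seq + (S0-Seq)*exp(-d t) exactly."""
        p = params.replace(c0=0.0, h=0.0)
        R0, S0 = 350.0, 100.0
        seq = float(sd.seq_of_resource(R0, p))
        traj = sd.integrate("extended", [R0, 0.0, S0], p, (0.0, 300.0))
        expected = seq + (S0 - seq) * np.exp(-p.d * traj.times)
        np.testing.assert_allclose(traj.S, expected, rtol=1e-8)

    def test_self_convergence_on_collapse_trajectory(self, params):
        p = params.replace(c0=0.0044, h=0.002)  # above the fold: collapse
        y0 = [400.0, 400.0, 600.0]
        ends = []
        for scale in (1.0, 0.5):
            opts = sd.IntegrateOptions(rtol=1e-8 * scale, atol=1e-10 * scale,
                                       max_step=None, dt=None)
            ends.append(sd.integrate("extended", y0, p, (0.0, 20_000.0), opts).y_end)
        assert np.max(np.abs(ends[0] - ends[1])) / np.max(np.abs(ends[0])) < 1e-6

    def test_collapse_terminates_before_leaving_the_orthant(self, params, fast_opts):
        p = params.replace(c0=0.0044, h=0.002)
        traj = sd.integrate("extended", [400.0, 400.0, 600.0], p, (0.0, 50_000.0), fast_opts)
        assert traj.termination == "collapse"
        assert traj.states.min() >= -10 * fast_opts.atol

    def test_invalid_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            sd.integrate("extended", [-1.0, 1.0, 1.0], params, (0.0, 10.0))
        with pytest.raises(ValueError):
            sd.integrate("extended", [1.0, 1.0, 1.0], params, (10.0, 10.0))
        with pytest.raises(ValueError):
            sd.integrate("nosuch", [1.0, 1.0], params, (0.0, 10.0))


class TestOutcomeClassification:
    def test_equilibrium_trajectory_is_sustainable(self, params, fast_opts):
        traj = sd.integrate("extended", EQ_FREE, params.replace(h=0.0), (0.0, 100.0), fast_opts)
        assert sd.classify_outcome(traj) == "sustainable"

    def test_above_fold_interior_start_collapses(self, params, fast_opts):
        p = params.replace(c0=0.0044, h=0.002)
        traj = sd.integrate("extended", [500.0, 300.0, 700.0], p, (0.0, 100_000.0), fast_opts)
        assert sd.classify_outcome(traj) == "collapse"

    def test_short_horizon_near_ghost_is_undecided(self, params, fast_opts):
        """Apparent stability near a ghost must not be labelled sustainable."""
        h = 0.005
        c0_fold = bif.fold_locus(params.replace(h=h), "c0_of_h")(h)
        p = params.replace(c0=c0_fold * (1 - 1e-4), h=h)
        traj = sd.integrate("extended", bif.ghost_state(p), p, (0.0, 500.0), fast_opts)
        assert sd.classify_outcome(traj) == "undecided"


class TestSpeedProfile:
    def test_constant_trajectory_has_zero_speed(self, params, fast_opts):
        traj = sd.integrate("extended", EQ_FREE, params.replace(h=0.0), (0.0, 50.0),
                            sd.IntegrateOptions(dt=1.0))
        assert np.allclose(sd.speed_profile(traj), 0.0, atol=1e-8)

    def test_speed_converges_under_grid_refinement(self, params):
        p = params.replace(c0=0.022, h=0.005)
        y0 = [600.0, 100.0, float(sd.seq_of_resource(600.0, p))]
        vals = []
        for dt in (1.0, 0.5):
            traj = sd.integrate("extended", y0, p, (0.0, 400.0),
                                sd.IntegrateOptions(dt=dt, max_step=None))
            sd.speed_profile(traj)
            vals.append(np.interp(200.0, traj.times[1:], traj.speed))
        assert abs(vals[0] - vals[1]) < 1e-3

    def test_minimum_speed_state_sits_on_the_ghost(self, params):
        h = 0.005
        c0_fold = bif.fold_locus(params.replace(h=h), "c0_of_h")(h)
        p = params.replace(c0=c0_fold * (1 - 1e-4), h=h)
        ghost = bif.ghost_state(p)
        probe = sd.integrate("extended", [600.0, 500.0, float(sd.seq_of_resource(600.0, p))],
                             p, (0.0, 1e7), sd.IntegrateOptions(max_step=None, dt=None))
        dt = probe.t_end / 4000.0
        traj = sd.integrate("extended", probe.states[0], p, (0.0, probe.t_end),
                            sd.IntegrateOptions(max_step=None, dt=dt))
        speed = sd.speed_profile(traj)
        state_at_min = traj.states[np.argmin(speed)]
        rel = np.linalg.norm(state_at_min - ghost) / np.linalg.norm(ghost)
        assert rel < 0.05

    def test_requires_uniform_grid(self, params, fast_opts):
        traj = sd.integrate("extended", [600.0, 100.0, 800.0],
                            params.replace(c0=0.022, h=0.005), (0.0, 1000.0), fast_opts)
        with pytest.raises(ValueError, match="uniform"):
            sd.speed_profile(traj)


class TestGhostTransit:
    def test_long_lingering_just_below_the_fold(self, params):
        h = 0.005
        c0_fold = bif.fold_locus(params.replace(h=h), "c0_of_h")(h)
        p = params.replace(c0=c0_fold * (1 - 1e-4), h=h)
        assert sd.ghost_transit_time(p) > 10.0 / params.r

    def test_transit_grows_as_the_fold_is_approached(self, params):
        h = 0.005
        c0_fold = bif.fold_locus(params.replace(h=h), "c0_of_h")(h)
        times = [
            sd.ghost_transit_time(params.replace(c0=c0_fold * (1 - eps), h=h))
            for eps in (2e-4, 1e-4)
        ]
        assert times[1] > times[0]

    def test_rejects_parameters_above_the_fold(self, bistable):
        with pytest.raises(ValueError, match="not below the fold"):
            sd.ghost_transit_time(bistable)


class TestDebtsAndRelaxation:
    def test_on_manifold_debts_vanish(self, params):
        R = 250.0
        state = [R, 10.0, float(sd.seq_of_resource(R, params))]
        m = sd.debt_metrics(state, params)
        assert m.extinction_debt == pytest.approx(0.0, abs=1e-12)
        assert m.service_debt == pytest.approx(0.0, abs=1e-12)

    def test_habitat_loss_leaves_extinction_debt(self, params):
        m = sd.debt_metrics([140.0, 0.0, 2500.0 / 3.0], params)
        assert m.extinction_debt == pytest.approx(2500.0 / 3.0 - 500.0, rel=1e-12)
        assert m.service_debt > 0

    def test_habitat_restoration_yields_immigration_credit(self, params):
        m = sd.debt_metrics([700.0, 0.0, 500.0], params)
        assert m.extinction_debt == pytest.approx(500.0 - 2500.0 / 3.0, rel=1e-12)
        assert m.service_debt < 0

    @pytest.mark.parametrize(
        "f, expected",
        [(0.5, 50.0), (0.99, -math.log(0.01) / (math.log(2.0) / 50.0)), (1e-9, 7.2e-8)],
    )
    def test_relaxation_times(self, params, f, expected):
        assert sd.relaxation_time(params, f) == pytest.approx(expected, rel=1e-2)

    def test_ninety_nine_percent_payoff_is_about_332_years(self, params):
        assert sd.relaxation_time(params, 0.99) == pytest.approx(332.19, abs=0.01)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_relaxation_fraction_domain(self, params, f):
        with pytest.raises(ValueError):
            sd.relaxation_time(params, f)


class TestPerturbationExperiment:
    def test_null_perturbation_reproduces_counterfactual(self, fast_opts):
        fx = tr.REVERSAL_FIXTURE
        p = sd.ModelParams(c0=fx["c0"], h=fx["h"])
        rec = sd.perturbation_experiment(
            p, [fx["R0"], fx["P0"], fx["S0"]], fx["t_pert"], 0.0, opts=fast_opts
        )
        np.testing.assert_array_equal(rec.post.states, rec.counterfactual_post.states)
        np.testing.assert_array_equal(rec.post.times, rec.counterfactual_post.times)

    def test_jump_creates_extinction_debt(self, fast_opts):
        fx = tr.REVERSAL_FIXTURE
        p = sd.ModelParams(c0=fx["c0"], h=fx["h"])
        rec = sd.perturbation_experiment(
            p, [fx["R0"], fx["P0"], fx["S0"]], fx["t_pert"], fx["phi"], opts=fast_opts
        )
        debt = sd.debt_metrics(rec.post.states[0], p)
        assert debt.extinction_debt > 0

    def test_pinned_reversal_case(self, fast_opts):
        """Debt-driven reversal: recovery then collapse; no-debt variant survives."""
        fx = tr.REVERSAL_FIXTURE
        p = sd.ModelParams(c0=fx["c0"], h=fx["h"])
        rec = sd.perturbation_experiment(
            p, [fx["R0"], fx["P0"], fx["S0"]], fx["t_pert"], fx["phi"], opts=fast_opts
        )
        assert rec.counterfactual_outcome == "sustainable"
        assert rec.outcome == "collapse"
        assert rec.quasistatic_outcome == "sustainable"
        assert rec.initial_recovery is not None
        assert rec.collapse_onset is not None and rec.collapse_onset > rec.initial_recovery[1]

    def test_reversal_run_is_reproducible(self, fast_opts):
        fx = tr.REVERSAL_FIXTURE
        p = sd.ModelParams(c0=fx["c0"], h=fx["h"])
        runs = [
            sd.perturbation_experiment(
                p, [fx["R0"], fx["P0"], fx["S0"]], fx["t_pert"], fx["phi"], opts=fast_opts
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].post.states, runs[1].post.states)

    def test_unsustainable_start_rejected(self, params, fast_opts):
        p = params.replace(c0=0.0044, h=0.002)  # above the fold
        with pytest.raises(ValueError, match="not sustainable"):
            sd.perturbation_experiment(p, [400.0, 400.0, 600.0], 100.0, 0.5, opts=fast_opts)

    def test_invalid_magnitude_rejected(self, params, fast_opts):
        with pytest.raises(ValueError, match="phi"):
            sd.perturbation_experiment(params, EQ_FREE, 10.0, 1.5, opts=fast_opts)
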