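"""Integration-engine tests: closed forms, control behavior, invariants."""

from dataclasses import replace

import numpy as np
import pytest

import perfusim as pf
from perfusim.simulate import SolverSettings


def _no_inhibition_params(**kw):
    """Growth-only parameter set: inhibition and death switched off."""
    base = dict(kd=0.0, kt=0.0, K_I_phib=1e12)
    base.update(kw)
    return replace(pf.REFERENCE_KINETICS, **base)


class TestFeedFlow:
    def test_constant_vvd(self):
        sched = pf.FeedSchedule(knot_values=(2.0,))
        assert pf.feed_flow(sched, 3.0, V=220.0) == pytest.approx(440.0)

    def test_knot_schedule_piecewise_constant(self):
        sched = pf.FeedSchedule(
            mode="vvd_knots",
            knot_times=(0.0, 4.0, 6.0, 9.0, 13.0, 17.0),
            knot_values=(2.04, 0.81, 1.19, 1.70, 1.89, 1.95),
        )
        assert pf.feed_flow(sched, 5.0, V=200.0) == pytest.approx(
            0.81 * 200.0
        )
        # last value held beyond the final knot
        assert pf.feed_flow(sched, 30.0, V=200.0) == pytest.approx(
            1.95 * 200.0
        )

    def test_zero_exchange_is_batch_mode(self):
        sched = pf.FeedSchedule(knot_values=(0.0,))
        assert pf.feed_flow(sched, 1.0, V=200.0) == 0.0

    def test_bspr_requires_cell_volume(self):
        with pytest.raises(ValueError):
            pf.FeedSchedule(mode="bspr", knot_values=(8.0,))
        sched = pf.FeedSchedule(
            mode="bspr", knot_values=(8.0,),
            cell_volume_signal=lambda t: 2.5e-9,
        )
        # Ff = BSPR * Xv * 1e6 * v_cell * V
        got = pf.feed_flow(sched, 0.0, V=200.0, xv=60.0)
        assert got == pytest.approx(8.0 * 60.0 * 1e6 * 2.5e-9 * 200.0)


class TestClosedForms:
    def test_exponential_growth(self):
        """Without inhibition, death or flows the model is a linear ODE."""
        p = _no_inhibition_params()
        recipe = pf.ProcessRecipe(
            X0=2.5, shift_threshold=1e6, vcd_setpoint=1e7,
            feed=pf.FeedSchedule(knot_values=(0.0,)), t_end=5.0,
        )
        traj = pf.simulate_batch(p, recipe)
        expected = 2.5 * np.exp(0.848 * traj.t)
        np.testing.assert_allclose(traj.Xv, expected, rtol=1e-6)

    def test_washout_decay(self):
        """qp = 0 with an initial titer decays at the dilution rate."""
        recipe = pf.ProcessRecipe(t_end=3.0)
        traj = pf.simulate_batch(pf.REFERENCE_KINETICS, recipe)
        out = pf.integrate_titer(traj, lambda f: np.zeros(f.shape[:-1]),
                                 igg0=1.0)
        np.testing.assert_allclose(
            out["igg"], np.exp(-2.0 * traj.t), rtol=1e-5
        )

    def test_flow_identity(self):
        """Fh = Ff - Fb >= 0 at every output point, bleeding or not."""
        p = _no_inhibition_params(kd=0.00921)
        recipe = pf.ProcessRecipe(t_end=12.0)
        traj = pf.simulate_batch(p, recipe)
        np.testing.assert_allclose(traj.fh, traj.ff - traj.fb, rtol=1e-12)
        assert np.all(traj.fh >= 0)
        assert np.any(traj.fb > 0)  # strong growth: controller must bleed


class TestScaleAndGrid:
    def test_scale_invariance(self):
        """Doubling V at fixed VVD leaves concentrations unchanged."""
        r1 = pf.ProcessRecipe(V=200.0, t_end=15.0)
        r2 = pf.ProcessRecipe(V=400.0, t_end=15.0)
        c1 = pf.BleedController(setpoint=60.0)
        c2 = pf.BleedController(kp=30.0, ki=100.0, setpoint=60.0)
        t1 = pf.simulate_batch(pf.REFERENCE_KINETICS, r1, controller=c1)
        t2 = pf.simulate_batch(pf.REFERENCE_KINETICS, r2, controller=c2)
        np.testing.assert_allclose(t1.states, t2.states, rtol=1e-9,
                                   atol=1e-12)
        np.testing.assert_allclose(t1.ff * 2, t2.ff, rtol=1e-12)

    def test_grid_refinement_convergence(self):
        recipe = pf.ProcessRecipe(t_end=20.0)
        coarse = pf.simulate_batch(
            pf.REFERENCE_KINETICS, recipe,
            settings=SolverSettings(substeps=2),
        )
        fine = pf.simulate_batch(
            pf.REFERENCE_KINETICS, recipe,
            settings=SolverSettings(substeps=4),
        )
        rel = np.abs(fine.states[-1] - coarse.states[-1]) / (
            np.abs(fine.states[-1]) + 1e-9
        )
        assert rel.max() < 1e-4


class TestTemperatureShiftEvent:
    def test_fires_exactly_once_and_trajectory_continuous(self):
        recipe = pf.ProcessRecipe(t_end=15.0)
        traj = pf.simulate_batch(pf.REFERENCE_KINETICS, recipe)
        steps = np.diff(traj.temp)
        assert np.sum(steps != 0) == 1
        assert traj.temp[0] == 37.0 and traj.temp[-1] == 34.0
        # shift at the first crossing of the threshold
        k = int(np.argmax(traj.temp < 37.0))
        assert traj.Xv[k - 1] < recipe.shift_threshold <= traj.Xv[k] * 1.01
        # no state discontinuity across the event
        jumps = np.abs(np.diff(traj.Xv))
        assert jumps.max() < 1.0

    def test_sampled_decision_quantizes_shift_time(self):
        recipe = pf.ProcessRecipe(t_end=15.0, shift_decision_interval_d=1.0)
        traj = pf.simulate_batch(pf.REFERENCE_KINETICS, recipe)
        t_shift = traj.t[int(np.argmax(traj.temp < 37.0))]
        assert t_shift == pytest.approx(round(t_shift))


class TestBleedController:
    def test_no_bleed_below_setpoint(self):
        recipe = pf.ProcessRecipe(t_end=4.0)  # still in growth phase
        traj = pf.simulate_batch(pf.REFERENCE_KINETICS, recipe)
        assert np.all(traj.fb == 0.0)

    def test_step_disturbance_settles_quickly(self):
        """A VCD excursion above setpoint is bled back within ~2 days."""
        p = _no_inhibition_params(kd=0.00921)
        recipe = pf.ProcessRecipe(t_end=12.0)
        traj = pf.simulate_batch(p, recipe)
        t_hit = traj.t[int(np.argmax(traj.Xv >= 60.0))]
        after = traj.t >= t_hit + 2.0
        assert np.all(np.abs(traj.Xv[after] - 60.0) / 60.0 < 0.02)
        assert np.all(traj.fb[after] > 0)

    def test_bleed_never_exceeds_feed(self):
        p = _no_inhibition_params(kd=0.0)
        recipe = pf.ProcessRecipe(
            t_end=10.0, feed=pf.FeedSchedule(knot_values=(0.5,))
        )
        traj = pf.simulate_batch(p, recipe)
        assert np.all(traj.fb <= traj.ff + 1e-9)


class TestSteadyState:
    def test_biomaterial_fixed_point(self):
        ss = pf.steady_state(pf.REFERENCE_KINETICS, D=2.0, fb_over_v=0.1,
                             xv=20.0)
        assert ss.Phib == pytest.approx(10.0)

    def test_decoupled_dead_cell_balance_without_toxicity(self):
        p = replace(pf.REFERENCE_KINETICS, kt=0.0)
        ss = pf.steady_state(p, D=2.0, fb_over_v=0.05, xv=60.0)
        assert ss.Xd == pytest.approx(
            0.00921 * 60.0 / (p.kl + 0.05), rel=1e-12
        )

    def test_divergent_toxicity_raises(self):
        with pytest.raises(ValueError, match="divergent"):
            pf.steady_state(pf.REFERENCE_KINETICS, D=1.0, fb_over_v=0.0,
                            xv=60.0)

    def test_simulation_converges_to_fixed_point(self):
        """Long-horizon closed-loop simulation lands on the analytic
        steady state of the dead/lysed/biomaterial balances."""
        p = _no_inhibition_params(kd=0.00921, kt=0.005)
        recipe = pf.ProcessRecipe(t_end=30.0)
        traj = pf.simulate_batch(p, recipe)
        fb_v = traj.fb[-1] / recipe.V
        ss = pf.steady_state(p, D=2.0, fb_over_v=fb_v, xv=traj.Xv[-1])
        got = traj.states[-1][[1, 2, 3]]
        want = np.array([ss.Xd, ss.Xl, ss.Phib])
        np.testing.assert_allclose(got, want, rtol=2e-3)


class TestConservation:
    def test_cell_number_audit(self):
        """Cells produced = cells accumulated + cells bled + cells lysed."""
        recipe = pf.ProcessRecipe(t_end=15.0)
        p = pf.REFERENCE_KINETICS
        traj = pf.simulate_batch(p, recipe)
        mu_eff, mu_d = traj.rates(p)
        V = recipe.V
        produced = np.trapezoid(mu_eff * traj.Xv * V, traj.t)
        accumulated = (
            (traj.Xv[-1] + traj.Xd[-1]) - (traj.Xv[0] + traj.Xd[0])
        ) * V
        bled = np.trapezoid(traj.fb * (traj.Xv + traj.Xd), traj.t)
        lysed = np.trapezoid(p.kl * traj.Xd * V, traj.t)
        assert produced == pytest.approx(
            accumulated + bled + lysed, rel=2e-3
        )


class TestTrackingMode:
    def test_bleed_updates_only_at_sample_times(self, clean_training_records):
        records, _ = clean_training_records
        rec = records[2]
        p = replace(pf.REFERENCE_KINETICS, mu_max=0.95)  # forces bleeding
        traj = pf.track_record(p, rec)
        changes = np.flatnonzero(np.diff(traj.fb) != 0) + 1
        frac = np.mod(traj.t[changes], 1.0)
        assert np.all((frac < 1e-9) | (frac > 1 - 1e-9))

    def test_inputs_replayed_from_record(self, clean_training_records):
        records, _ = clean_training_records
        rec = records[0]
        traj = pf.track_record(pf.REFERENCE_KINETICS, rec)
        assert set(np.unique(traj.temp)) <= {34.0, 37.0}
        np.testing.assert_allclose(
            traj.at(rec.time_d[:-1], "ff"), rec.feed_ml_d[:-1], rtol=1e-9
        )


class TestIndependentIntegrationOracle:
    def test_matches_adaptive_reference_integrator(self):
        """The fixed-step engine agrees with an adaptive high-accuracy
        integration of the same balance equations (no controller, no
        event, constant flows)."""
        from scipy.integrate import solve_ivp

        from perfusim.kinetics import rhs

        p = pf.REFERENCE_KINETICS
        recipe = pf.ProcessRecipe(
            X0=2.5, shift_threshold=1e6, vcd_setpoint=1e7, t_end=15.0,
            feed=pf.FeedSchedule(knot_values=(1.5,)),
        )
        traj = pf.simulate_batch(p, recipe)

        def f(t, y):
            return rhs(p, y, ff=1.5 * 200.0, fb=0.0, V=200.0,
                       inputs={"temp_c": 37.0, "ph": 7.05})

        y0 = np.zeros(7)
        y0[0] = 2.5
        sol = solve_ivp(f, (0.0, 15.0), y0, rtol=1e-10, atol=1e-12,
                        t_eval=traj.t, method="RK45")
        np.testing.assert_allclose(
            traj.states, sol.y.T, rtol=5e-5, atol=1e-8
        )


class TestTrajectoryExport:
    def test_frames(self):
        traj = pf.simulate_batch(
            pf.REFERENCE_KINETICS, pf.ProcessRecipe(t_end=2.0)
        )
        wide = traj.to_frame()
        assert {"time_d", "xv", "viability", "vvd"} <= set(wide.columns)
        tidy = traj.to_tidy()
        assert set(tidy.columns) == {"time_d", "variable", "value"}
        assert tidy["variable"].nunique() == wide.shape[1] - 1
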