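"""Unit tests of the kinetic rate laws and the ODE right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perfusim as pf
from perfusim.kinetics import IDX, STATE_NAMES, rhs


TEMP = pf.QuadraticEffect("temp_c", target=37.0, theta=0.081)


class TestQuadraticEffect:
    def test_unity_at_target(self):
        assert pf.quadratic_effect(TEMP, 37.0) == pytest.approx(1.0)

    def test_sensitivity_closed_form(self):
        # theta at the upper calibration bound, a 3 degC downshift
        got = pf.quadratic_effect(TEMP, 34.0)
        assert got == pytest.approx(np.exp(-0.5 * (0.081 * 3.0) ** 2))
        assert got == pytest.approx(0.9709, abs=1e-4)

    def test_spread_parameterization(self):
        eff = pf.QuadraticEffect(
            "temp_c", target=37.0, theta=2.0, parameterization="spread"
        )
        assert pf.quadratic_effect(eff, 35.0) == pytest.approx(
            np.exp(-0.5 * 1.0)
        )

    def test_spread_zero_theta_raises(self):
        eff = pf.QuadraticEffect(
            "temp_c", target=37.0, theta=0.0, parameterization="spread"
        )
        with pytest.raises(ZeroDivisionError):
            pf.quadratic_effect(eff, 35.0)

    @given(delta=st.floats(0.001, 50.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_decay(self, delta):
        lo = pf.quadratic_effect(TEMP, 37.0 - delta)
        hi = pf.quadratic_effect(TEMP, 37.0 + delta)
        assert lo == pytest.approx(hi, rel=1e-12)
        assert 0.0 < lo < 1.0
        # strictly decreasing away from the optimum
        assert pf.quadratic_effect(TEMP, 37.0 + 2 * delta) < hi


class TestInhibition:
    def test_limits(self):
        assert pf.inhibition_factor(0.0, 12.7) == 1.0
        assert pf.inhibition_factor(12.7, 12.7) == pytest.approx(0.5)
        assert pf.inhibition_factor(2 * 12.7, 12.7) == pytest.approx(1 / 9)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            pf.inhibition_factor(-1.0, 12.7)
        with pytest.raises(ValueError):
            pf.inhibition_factor(1.0, 0.0)

    @given(
        phi=st.floats(0.0, 1e3),
        step=st.floats(0.01, 100.0),
        ki=st.floats(0.1, 300.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_decreasing(self, phi, step, ki):
        assert pf.inhibition_factor(phi + step, ki) < pf.inhibition_factor(
            phi, ki
        )


class TestRates:
    def test_growth_rate_at_reference_conditions(self, ref_params):
        mu = pf.effective_growth_rate(
            ref_params, 0.0, {"temp_c": 37.0, "ph": 7.05}
        )
        assert mu == pytest.approx(0.848)

    def test_growth_half_max_at_threshold(self, ref_params):
        mu = pf.effective_growth_rate(
            ref_params, ref_params.K_I_phib, {"temp_c": 37.0, "ph": 7.05}
        )
        assert mu == pytest.approx(0.848 / 2)

    def test_growth_is_product_of_factors(self, ref_params):
        rng = np.random.default_rng(42)
        for _ in range(20):
            phib = rng.uniform(0, 50)
            temp = rng.uniform(30, 40)
            ph = rng.uniform(6.6, 7.4)
            expected = (
                ref_params.mu_max
                * pf.inhibition_factor(phib, ref_params.K_I_phib)
                * pf.quadratic_effect(ref_params.quad_effects[0], temp)
                * pf.quadratic_effect(ref_params.quad_effects[1], ph)
            )
            got = pf.effective_growth_rate(
                ref_params, phib, {"temp_c": temp, "ph": ph}
            )
            assert got == pytest.approx(expected, rel=1e-12)

    def test_growth_missing_input_names_the_effect(self, ref_params):
        with pytest.raises(KeyError, match="ph"):
            pf.effective_growth_rate(ref_params, 0.0, {"temp_c": 37.0})

    def test_death_rate(self, ref_params):
        assert pf.effective_death_rate(ref_params, 0.0) == pytest.approx(
            0.00921
        )
        assert pf.effective_death_rate(ref_params, 10.0) == pytest.approx(
            0.00921 + 0.03514 * 10, abs=1e-12
        )
        p0 = pf.KineticParams(kt=0.0, kd=0.00921)
        assert pf.effective_death_rate(p0, 123.0) == pytest.approx(0.00921)


class TestViability:
    def test_values(self):
        assert pf.viability(60.0, 0.0) == 1.0
        assert pf.viability(50.0, 50.0) == 0.5
        # Xd solved from viability = 0.9 at Xv = 60
        assert pf.viability(60.0, 60.0 / 0.9 - 60.0) == pytest.approx(0.9)

    def test_undefined(self):
        with pytest.raises(ZeroDivisionError):
            pf.viability(0.0, 0.0)


def _manual_rhs(p, y, ff, fb, V, temp, ph, qp):
    """Independent term-by-term expansion of the balance equations."""
    xv, xd, xl, phib, xlh, phibh, igg = y
    d = ff / V  # (Fh + Fb)/V at constant volume
    db = fb / V
    mu = (
        p.mu_max
        / (((phib + phibh) / p.K_I_phib) ** 3 + 1.0)
        * np.exp(-0.5 * (p.quad_effects[0].theta * (temp - 37.0)) ** 2)
        * np.exp(-0.5 * (p.quad_effects[1].theta * (ph - 7.05)) ** 2)
    )
    mud = p.kd + p.kt * (xl + xlh)
    return np.array([
        mu * xv - mud * xv - db * xv,
        mud * xv - p.kl * xd - db * xd,
        (1 - p.kls) * p.kl * xd - d * xl,
        (1 - p.kbh) * xv - d * phib,
        p.kls * p.kl * xd - db * xlh,
        p.kbh * xv - db * phibh,
        qp * xv - d * igg,
    ])


class TestRhs:
    def test_batch_mode_limit(self, ref_params):
        # no flows, no death, no product: pure exponential growth term
        from dataclasses import replace

        p = replace(ref_params, kd=0.0, kt=0.0)
        y = np.array([5.0, 0, 0, 0, 0, 0, 0.0])
        dy = rhs(p, y, ff=0.0, fb=0.0, V=200.0,
                 inputs={"temp_c": 37.0, "ph": 7.05})
        assert dy[0] == pytest.approx(0.848 * 5.0)
        assert np.allclose(dy[[1, 2, 4, 5, 6]], 0.0)

    def test_biomaterial_steady_state(self, ref_params):
        # dPhib/dt = 0 at Phib = Xv / D
        y = np.zeros(7)
        y[IDX["Xv"]] = 60.0
        y[IDX["Phib"]] = 30.0
        dy = rhs(ref_params, y, ff=400.0, fb=0.0, V=200.0,
                 inputs={"temp_c": 37.0, "ph": 7.05})
        assert dy[IDX["Phib"]] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_expansion(self):
        from dataclasses import replace

        rng = np.random.default_rng(7)
        p = replace(
            pf.REFERENCE_KINETICS, kls=0.1, kbh=0.05,
        )
        for _ in range(10):
            y = rng.uniform(0.01, 40.0, 7)
            ff, fb = rng.uniform(50, 400), rng.uniform(0, 40)
            temp, ph, qp = rng.uniform(33, 38), rng.uniform(6.8, 7.2), 0.02
            got = rhs(p, y, ff, fb, 200.0,
                      {"temp_c": temp, "ph": ph}, qp=qp)
            want = _manual_rhs(p, y, ff, fb, 200.0, temp, ph, qp)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_sieving_reduces_to_base_model(self, ref_params):
        """With zero retention the extended balances equal the base model
        and the retained pools stay identically empty."""
        rng = np.random.default_rng(11)
        y = np.zeros(7)
        y[:4] = rng.uniform(0.1, 30.0, 4)
        dy = rhs(ref_params, y, 300.0, 20.0, 200.0,
                 {"temp_c": 34.0, "ph": 6.95})
        want = _manual_rhs(ref_params, y, 300.0, 20.0, 200.0, 34.0, 6.95,
                           0.0)
        np.testing.assert_allclose(dy, want, rtol=1e-12)
        assert dy[IDX["Xlh"]] == 0.0 and dy[IDX["Phibh"]] == 0.0

    @given(zero_idx=st.integers(0, 6), data=st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_no_derivative_drives_zero_state_negative(self, zero_idx, data):
        rng_vals = data.draw(
            st.lists(st.floats(0.0, 50.0), min_size=7, max_size=7)
        )
        y = np.asarray(rng_vals)
        y[zero_idx] = 0.0
        ff = data.draw(st.floats(0.0, 500.0))
        fb = data.draw(st.floats(0.0, 100.0))
        dy = rhs(pf.REFERENCE_KINETICS, y, ff, fb, 200.0,
                 {"temp_c": 35.0, "ph": 7.0}, qp=0.01)
        assert dy[zero_idx] >= 0.0


class TestTypes:
    def test_culture_state_invariants(self):
        with pytest.raises(ValueError):
            pf.CultureState(Xv=-1.0)
        with pytest.raises(ValueError):
            pf.CultureState(Xv=1.0, V=0.0)
        s = pf.CultureState(Xv=2.5)
        assert s.as_array()[0] == 2.5

    def test_kinetic_params_invariants(self):
        with pytest.raises(ValueError):
            pf.KineticParams(mu_max=-0.1).validate()
        with pytest.raises(ValueError):
            pf.KineticParams(K_I_phib=0.0).validate()
        with pytest.raises(ValueError):
            pf.KineticParams(kls=1.5).validate()

    def test_flows(self):
        f = pf.Flows(Ff=400.0, Fb=40.0)
        assert f.Fh == pytest.approx(360.0)
        with pytest.raises(ValueError):
            pf.Flows(Ff=100.0, Fb=150.0)
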