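"""Forward-model correctness: drift equations, observation model, and the
fixed-step integrator against independent scipy reference solutions."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from nfdcm.generative_model import (
    DCMParameters,
    HemoParams,
    InputSet,
    UnstableModelWarning,
    bold_coefficients,
    bold_observation,
    hemodynamic_drift,
    integrate_dcm,
    neuronal_drift,
)


def _rest_state(R=4):
    h = np.zeros((R, 4))
    h[:, 1:] = 1.0
    return h


class TestNeuronalDrift:
    def test_zero_state_zero_input_is_fixed_point(self, example_params):
        out = neuronal_drift(np.zeros(4), 0.0, 0.0, example_params)
        assert np.all(out == 0)

    def test_pure_self_decay(self):
        p = DCMParameters(A=-0.5 * np.eye(4), B=np.zeros((4, 4)), C=np.zeros(4))
        out = neuronal_drift(np.ones(4), 0.0, 0.0, p)
        np.testing.assert_allclose(out, -0.5 * np.ones(4))

    def test_modulation_equals_summed_coupling(self, example_params):
        x = np.array([0.3, -0.1, 0.2, 0.05])
        p = example_params
        merged = DCMParameters(
            A=p.A + p.B[0], B=np.zeros((4, 4)), C=p.C.copy(), hemo=p.hemo
        )
        np.testing.assert_allclose(
            neuronal_drift(x, 1.0, 1.0, p), neuronal_drift(x, 1.0, 0.0, merged)
        )

    def test_dimension_mismatch_raises(self, example_params):
        with pytest.raises(ValueError, match="state"):
            neuronal_drift(np.zeros(3), 0.0, 0.0, example_params)


class TestHemodynamicDrift:
    def test_resting_fixed_point(self, example_params):
        out = hemodynamic_drift(_rest_state(), np.zeros(4), example_params)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_inflow_derivative_is_signal(self, example_params):
        h = _rest_state()
        h[:, 0] = 0.1
        out = hemodynamic_drift(h, np.zeros(4), example_params)
        np.testing.assert_allclose(out[:, 1], 0.1)

    def test_nonpositive_state_rejected(self, example_params):
        h = _rest_state()
        h[2, 2] = -0.1
        with pytest.raises(Exception, match="S"):
            hemodynamic_drift(h, np.zeros(4), example_params)

    def test_step_response_matches_stiff_solver(self, example_params):
        """Inflow response to a 1-s neuronal impulse: fixed-step RK4 on the
        drift vs scipy LSODA, integrated phase-wise around the step."""
        p = example_params

        def rhs(z):
            zv = np.full(4, z)

            def f(t, y):
                return hemodynamic_drift(y.reshape(4, 4), zv, p).ravel()

            return f

        y0 = _rest_state().ravel()
        # reference: stiff solver, two phases (z = 1 then z = 0)
        t1 = np.linspace(0, 1, 21)
        s1 = solve_ivp(rhs(1.0), (0, 1), y0, method="LSODA",
                       rtol=1e-11, atol=1e-13, t_eval=t1)
        t2 = np.linspace(1, 20, 96)
        s2 = solve_ivp(rhs(0.0), (1, 20), s1.y[:, -1], method="LSODA",
                       rtol=1e-11, atol=1e-13, t_eval=t2)
        ref_t = np.concatenate([t1, t2[1:]])
        ref_f = np.concatenate([s1.y[1], s2.y[1, 1:]])  # region 0 inflow

        dt = 1e-3
        y = y0.copy()
        out = {0.0: 1.0}
        t = 0.0
        for _ in range(int(20 / dt)):
            z = 1.0 if t < 1.0 - 1e-12 else 0.0
            f = rhs(z)
            k1 = f(t, y)
            k2 = f(t, y + dt / 2 * k1)
            k3 = f(t, y + dt / 2 * k2)
            k4 = f(t, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = round(t + dt, 9)
            out[t] = y[1]
        mine = np.array([out[round(float(tt), 9)] for tt in ref_t])
        assert np.max(np.abs(mine - ref_f)) < 1e-4


class TestBoldObservation:
    def test_rest_calibration(self, example_params):
        np.testing.assert_allclose(bold_observation(_rest_state(), example_params), 0.0)

    def test_volume_normalised_reduction(self, example_params):
        # q = v with v = 1: only the k1 term survives
        h = _rest_state()
        h[:, 3] = 0.9
        k1, _, k2 = bold_coefficients(example_params.hemo)
        expected = 100 * example_params.hemo.V0 * (k1 * 0.1 + 2 * 0.1)
        np.testing.assert_allclose(bold_observation(h, example_params), expected)

    def test_tabulated_pair(self, example_params):
        h = _rest_state()
        h[0, 2], h[0, 3] = 1.05, 0.93  # (v, q)
        hp = example_params.hemo
        k1, k2, k3 = 7 * hp.E0, 2.0, 2 * hp.E0 - 0.2
        expected = 100 * hp.V0 * (
            k1 * (1 - 0.93) + k2 * (1 - 0.93 / 1.05) + k3 * (1 - 1.05)
        )
        assert bold_observation(h, example_params)[0] == pytest.approx(expected, rel=1e-12)


class TestIntegrateDCM:
    def test_zero_drive_zero_output(self, example_params, training_inputs):
        p = DCMParameters(
            A=example_params.A, B=example_params.B, C=np.zeros(4), hemo=example_params.hemo
        )
        ts = integrate_dcm(None, p, training_inputs)
        assert np.all(ts.data == 0)

    def test_matches_independent_ode_solver(self, example_params, training_inputs):
        """Full cascade vs scipy solve_ivp built only from the reference
        drift functions."""
        p = example_params
        ts = integrate_dcm(None, p, training_inputs)
        u_d = training_inputs.u_drive
        u_m = training_inputs.u_mod
        dt = training_inputs.dt

        def rhs(t, y):
            i = min(int(t / dt), u_d.size - 1)
            x = y[:4]
            h = y[4:].reshape(4, 4)
            dx = neuronal_drift(x, u_d[i], u_m[i], p)
            dh = hemodynamic_drift(h, x, p)
            return np.concatenate([dx, dh.ravel()])

        y0 = np.concatenate([np.zeros(4), _rest_state().ravel()])
        t_end = training_inputs.n_volumes * training_inputs.TR
        t_eval = (np.arange(training_inputs.n_volumes) + 1) * training_inputs.TR
        sol = solve_ivp(
            rhs, (0, t_end), y0, method="RK45", rtol=1e-9, atol=1e-11,
            t_eval=t_eval, max_step=dt,
        )
        ref = np.stack(
            [
                bold_observation(sol.y[4:, i].reshape(4, 4), p)
                for i in range(sol.y.shape[1])
            ],
            axis=1,
        )
        assert np.max(np.abs(ts.data - ref)) < 1e-4

    def test_neuronal_subsystem_matches_matrix_exponential(self, example_params):
        """With constant input the neuronal ODE has the closed form
        x(t) = (expm(At) - I) A^-1 c; the drift function must reproduce it."""
        p = example_params
        A = p.A
        c = p.C[:, 0].copy()

        def rhs(t, x):
            return neuronal_drift(x, 1.0, 0.0, p)

        t_eval = np.linspace(0.5, 12, 10)
        sol = solve_ivp(rhs, (0, 12), np.zeros(4), rtol=1e-11, atol=1e-13, t_eval=t_eval)
        for i, t in enumerate(t_eval):
            closed = (expm(A * t) - np.eye(4)) @ np.linalg.solve(A, c)
            np.testing.assert_allclose(sol.y[:, i], closed, atol=1e-6)

    def test_step_size_refinement(self, example_params, training_design):
        from nfdcm.synthetic_cohort import design_events

        ev = design_events(training_design)
        coarse = InputSet.from_events(ev, bins_per_tr=16)
        fine = InputSet.from_events(ev, bins_per_tr=32)
        y16 = integrate_dcm(None, example_params, coarse).data
        y32 = integrate_dcm(None, example_params, fine).data
        assert np.max(np.abs(y16 - y32)) < 1e-4

    def test_bounded_long_run(self, example_params):
        import pandas as pd

        blocks = []
        t = 0.0
        for i in range(41):
            blocks.append((t, 30.0, "baseline" if i % 2 == 0 else "up-regulation"))
            t += 30.0
        ev = pd.DataFrame(blocks, columns=["onset", "duration", "trial_type"])
        inp = InputSet.from_events(ev)
        ts = integrate_dcm(None, example_params, inp)
        assert np.all(np.isfinite(ts.data))
        assert np.max(np.abs(ts.data)) < 50

    def test_linearity_of_neuronal_response_in_drive(self, example_params):
        """The neuronal subsystem is linear: doubling C doubles the peak
        neuronal response (relative error well under 5% for |C| <= 0.1)."""
        p = example_params
        peaks = []
        for gain in (0.05, 0.1):
            C = np.zeros(4)
            C[0] = gain
            q = DCMParameters(A=p.A, B=np.zeros((4, 4)), C=C, hemo=p.hemo)

            def rhs(t, x, q=q):
                return neuronal_drift(x, 1.0, 0.0, q)

            sol = solve_ivp(rhs, (0, 30), np.zeros(4), rtol=1e-10, atol=1e-12)
            peaks.append(np.max(np.abs(sol.y)))
        assert peaks[1] / peaks[0] == pytest.approx(2.0, rel=0.05)

    def test_unstable_coupling_warns_and_flags(self, training_inputs):
        A = 0.2 * np.ones((4, 4))
        np.fill_diagonal(A, -0.1)
        C = np.zeros(4)
        C[0] = 0.01
        p = DCMParameters(A=A, B=np.zeros((4, 4)), C=C)
        with pytest.warns(UnstableModelWarning):
            try:
                ts = integrate_dcm(None, p, training_inputs)
                assert not ts.stable
            except RuntimeError:
                pass  # divergence may also abort the integration


def test_parameter_validation():
    with pytest.raises(ValueError, match="self-inhibition"):
        DCMParameters(A=np.eye(4) * 0.1, B=np.zeros((4, 4)), C=np.zeros(4))
    with pytest.raises(ValueError, match="alpha"):
        HemoParams(alpha=1.5)
    with pytest.raises(ValueError, match="E0"):
        HemoParams(E0=0.0)
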