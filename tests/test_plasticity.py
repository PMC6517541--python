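"""Unit tests of the calcium-threshold plasticity model."""

import numpy as np
import pytest

from rateplast.plasticity import (
    LC_CALCIUM, LC_PLASTICITY, NLC_CALCIUM, NLC_PLASTICITY,
    CalciumParams, PlasticityParams, drift_fixed_point,
    lc_calcium_step, nlc_calcium_step, plasticity_step, xi_coupling,
)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        dict(tau=-1, gamma_p=1, gamma_d=1, theta_p=2, theta_d=1),
        dict(tau=1, gamma_p=0, gamma_d=1, theta_p=2, theta_d=1),
        dict(tau=1, gamma_p=1, gamma_d=1, theta_p=1, theta_d=2),
        dict(tau=1, gamma_p=1, gamma_d=1, theta_p=2, theta_d=0),
        dict(tau=1, gamma_p=1, gamma_d=1, theta_p=2, theta_d=1, sigma=-0.1),
    ])
    def test_invalid_plasticity_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PlasticityParams(**kwargs)

    def test_invalid_calcium_params_rejected(self):
        with pytest.raises(ValueError):
            CalciumParams(tau_ca=0, c_pre=1, c_post=1)
        with pytest.raises(ValueError):
            CalciumParams(tau_ca=10, c_pre=-1, c_post=1)

    def test_nlc_xi_is_derived_exactly(self):
        # xi = 2(C_post + C_pre) - C_post * C_pre
        expected = 2 * (2.30815 + 0.86467) - 2.30815 * 0.86467
        assert NLC_CALCIUM.xi == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.3498, abs=1e-4)
        assert xi_coupling(1.0, 2.0) == 4.0


class TestLinearCalcium:
    def test_pure_decay_step(self):
        out = lc_calcium_step(np.array([1.0]), np.array([False]), False,
                              0.5, LC_CALCIUM)
        assert out[0] == pytest.approx(1.0 * (1 - 0.5 / 22.27212), rel=1e-12)
        assert out[0] == pytest.approx(0.977550, abs=1e-6)

    def test_presynaptic_spike_amplitude(self):
        out = lc_calcium_step(np.array([0.0]), np.array([True]), False,
                              0.5, LC_CALCIUM)
        assert out[0] == pytest.approx(0.84410)

    def test_postsynaptic_spike_amplitude(self):
        out = lc_calcium_step(np.array([0.0]), np.array([False]), True,
                              0.5, LC_CALCIUM)
        assert out[0] == pytest.approx(1.62138)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            lc_calcium_step(np.zeros(1), np.zeros(1, bool), False, -0.5, LC_CALCIUM)
        with pytest.raises(ValueError):
            lc_calcium_step(np.zeros(1), np.zeros(1, bool), False, 30.0, LC_CALCIUM)

    def test_shot_noise_mean_law(self):
        # time-average of c under independent Poisson inputs approaches
        # tau_ca * (C_pre u + C_post v); each synapse gets its own post train
        # so the per-synapse time-averages are independent.
        u, v = 20.0, 20.0
        dt, t_end, n = 0.5, 100.0, 60
        n_steps = int(t_end * 1e3 / dt)
        rng = np.random.default_rng(42)
        p_pre, p_post = u * dt * 1e-3, v * dt * 1e-3
        decay = 1 - dt / LC_CALCIUM.tau_ca
        c = np.zeros(n)
        means = np.zeros(n)
        for _ in range(n_steps):
            c = c * decay
            c += LC_CALCIUM.c_pre * (rng.random(n) < p_pre)
            c += LC_CALCIUM.c_post * (rng.random(n) < p_post)
            means += c
        means /= n_steps
        expected = LC_CALCIUM.tau_ca * 1e-3 * (LC_CALCIUM.c_pre * u
                                               + LC_CALCIUM.c_post * v)
        se = means.std(ddof=1) / np.sqrt(n)
        assert abs(means.mean() - expected) < 3 * se


class TestNonlinearCalcium:
    def test_zero_presynaptic_trace_gives_pure_cpost_increment(self):
        c_pre, c_post = nlc_calcium_step(
            np.array([0.0]), np.array([0.0]), np.array([False]), True,
            0.5, NLC_CALCIUM)
        assert c_post[0] == pytest.approx(NLC_CALCIUM.c_post)

    def test_coupling_reads_pre_decay_trace(self):
        c0 = 1.5
        c_pre, c_post = nlc_calcium_step(
            np.array([c0]), np.array([0.0]), np.array([False]), True,
            0.5, NLC_CALCIUM)
        assert c_post[0] == pytest.approx(
            NLC_CALCIUM.c_post + NLC_CALCIUM.xi * c0)

    def test_no_spikes_decay_monotonically_to_zero(self):
        c_pre = np.array([2.0])
        c_post = np.array([3.0])
        prev = c_pre[0] + c_post[0]
        for _ in range(2000):
            c_pre, c_post = nlc_calcium_step(
                c_pre, c_post, np.array([False]), False, 0.5, NLC_CALCIUM)
            total = c_pre[0] + c_post[0]
            assert total < prev
            prev = total
        assert prev < 1e-10


class TestPlasticityStep:
    DT = 0.5e-3  # seconds

    def test_gates_closed_leaves_weights_unchanged(self):
        rho = np.array([0.1, 0.5, 0.9])
        out = plasticity_step(rho, np.full(3, 0.5), self.DT, LC_PLASTICITY)
        np.testing.assert_array_equal(out, rho)

    def test_fixed_point_with_both_gates_open(self):
        rho_star = drift_fixed_point(LC_PLASTICITY)
        assert rho_star == pytest.approx(0.81254, abs=1e-5)
        rho = np.array([rho_star])
        out = plasticity_step(rho, np.array([10.0]), self.DT, LC_PLASTICITY)
        assert abs(out[0] - rho_star) < 1e-14

    def test_single_depression_step_arithmetic(self):
        # theta_d <= c < theta_p: d rho = -(gamma_d / tau) * rho * dt
        out = plasticity_step(np.array([0.5]), np.array([1.5]), self.DT,
                              LC_PLASTICITY)
        expected = -(137.7586 / 520.76129) * 0.5 * self.DT
        assert out[0] - 0.5 == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(-6.6134e-5, rel=1e-4)

    @pytest.mark.parametrize("c,towards", [(10.0, "up"), (1.5, "down")])
    def test_noise_free_monotonicity(self, c, towards):
        rho = np.array([0.4])
        prev = rho[0]
        for _ in range(500):
            rho = plasticity_step(rho, np.array([c]), self.DT, LC_PLASTICITY)
            if towards == "up":
                assert rho[0] >= prev
                assert rho[0] <= drift_fixed_point(LC_PLASTICITY)
            else:
                assert rho[0] <= prev
                assert rho[0] >= 0.0
            prev = rho[0]

    def test_unstable_step_rejected(self):
        with pytest.raises(ValueError):
            plasticity_step(np.array([0.5]), np.array([10.0]), 2.0,
                            LC_PLASTICITY)

    def test_noise_requires_vector_and_respects_bounds(self):
        params = LC_PLASTICITY.with_sigma(5.0)
        with pytest.raises(ValueError):
            plasticity_step(np.array([0.5]), np.array([10.0]), self.DT, params)
        rng = np.random.default_rng(0)
        rho = np.full(100, 0.99)
        for _ in range(200):
            rho = plasticity_step(rho, np.full(100, 10.0), self.DT, params,
                                  noise=rng.standard_normal(100))
            assert np.all((rho >= 0) & (rho <= 1))

    def test_gated_trajectory_matches_ode_closed_form(self):
        # with the potentiation gate held open the Euler trajectory follows
        # rho(t) = rho* + (rho0 - rho*) exp(-(gp+gd) t / tau)
        p = LC_PLASTICITY
        rho = np.array([0.3])
        n_steps, t = 4000, 2.0
        for _ in range(n_steps):
            rho = plasticity_step(rho, np.array([10.0]), t / n_steps, p)
        rho_star = drift_fixed_point(p)
        lam = (p.gamma_p + p.gamma_d) / p.tau
        expected = rho_star + (0.3 - rho_star) * np.exp(-lam * t)
        assert rho[0] == pytest.approx(expected, rel=1e-3)
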