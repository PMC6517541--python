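"""The compiled trial kernels must reproduce the reference single-step model.

The reference implementations below replay the kernels' documented RNG draw
order with numpy's legacy generator and advance the system with the pure
numpy step functions; trajectories must then agree to floating-point
round-off.
"""

import numpy as np
import pytest

from rateplast import _kernels
from rateplast.neurons import AEIF_PARAMS, MAT_PARAMS, AEIFState, MATState, \
    aeif_step, mat_step
from rateplast.plasticity import (
    LC_CALCIUM, LC_PLASTICITY, NLC_CALCIUM, NLC_PLASTICITY,
    lc_calcium_step, nlc_calcium_step, plasticity_step,
)
from rateplast.setups import aeif_param_array, mat_param_array

DT = 0.5
N_STEPS = 400
N_SYN = 8


def _scales(plast, sigma=0.0):
    dt_s = DT * 1e-3
    return (plast.gamma_p * dt_s / plast.tau,
            plast.gamma_d * dt_s / plast.tau,
            sigma * np.sqrt(dt_s / plast.tau))


def _reference_p1(seed, u, v, rho0, plast, cal, nonlinear, sigma=0.0):
    np.random.seed(seed)
    p_pre, p_post = u * DT * 1e-3, v * DT * 1e-3
    rho = rho0.copy()
    c_pre = np.zeros(N_SYN)
    c_post = np.zeros(N_SYN)
    plast = plast.with_sigma(sigma)
    wbar = [rho.mean()]
    for _ in range(N_STEPS):
        pre = np.random.random(N_SYN) < p_pre
        post = np.random.random() < p_post
        if nonlinear:
            c_pre, c_post = nlc_calcium_step(c_pre, c_post, pre, post, DT, cal)
            c = c_pre + c_post
        else:
            c_pre = lc_calcium_step(c_pre, pre, post, DT, cal)
            c = c_pre
        noise = np.random.normal(size=N_SYN) if sigma > 0 else None
        rho = plasticity_step(rho, c, DT * 1e-3, plast, noise)
        wbar.append(rho.mean())
    return np.array(wbar)


@pytest.mark.parametrize("model,sigma", [
    ("lc", 0.0), ("nlc", 0.0), ("lc", 2.0),
])
def test_p1_direct_kernel_matches_reference(model, sigma):
    plast = LC_PLASTICITY if model == "lc" else NLC_PLASTICITY
    cal = LC_CALCIUM if model == "lc" else NLC_CALCIUM
    rho0 = np.linspace(0.1, 0.9, N_SYN)
    gp, gd, sstep = _scales(plast, sigma)
    got = _kernels.p1_direct_trial(
        123, N_STEPS, DT, 60.0, 40.0, rho0, model == "nlc",
        cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
        plast.theta_p, plast.theta_d, gp, gd, sstep)
    want = _reference_p1(123, 60.0, 40.0, rho0, plast, cal,
                         model == "nlc", sigma)
    np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)


def _reference_p2(seed, u, rho0, plast, cal, nonlinear, neuron, dv_per_rho):
    np.random.seed(seed)
    p_pre = u * DT * 1e-3
    rho = rho0.copy()
    c_pre = np.zeros(N_SYN)
    c_post = np.zeros(N_SYN)
    state = MATState() if neuron == "mat" else AEIFState(v_mem=AEIF_PARAMS.e_l)
    wbar = [rho.mean()]
    posts = []
    for _ in range(N_STEPS):
        pre = np.random.random(N_SYN) < p_pre
        drive = dv_per_rho * np.sum(rho * pre)
        if neuron == "mat":
            state, post = mat_step(state, drive, DT, MAT_PARAMS)
        else:
            state, post = aeif_step(state, drive, DT, AEIF_PARAMS)
        posts.append(post)
        if nonlinear:
            c_pre, c_post = nlc_calcium_step(c_pre, c_post, pre, post, DT, cal)
            c = c_pre + c_post
        else:
            c_pre = lc_calcium_step(c_pre, pre, post, DT, cal)
            c = c_pre
        rho = plasticity_step(rho, c, DT * 1e-3, plast)
        wbar.append(rho.mean())
    return np.array(wbar), np.array(posts, dtype=np.uint8)


@pytest.mark.parametrize("neuron", ["mat", "aeif"])
def test_p2_kernel_matches_reference(neuron):
    plast, cal = LC_PLASTICITY, LC_CALCIUM
    rho0 = np.full(N_SYN, 0.6)
    gp, gd, _ = _scales(plast)
    # large per-spike drive so the tiny test population still spikes
    dv = 5.0 if neuron == "aeif" else 15.0
    ntype = _kernels.NEURON_MAT if neuron == "mat" else _kernels.NEURON_AEIF
    npar = (mat_param_array(MAT_PARAMS) if neuron == "mat"
            else aeif_param_array(AEIF_PARAMS))
    got_w, got_post = _kernels.p2_trial(
        77, N_STEPS, DT, 80.0, rho0, False,
        cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
        plast.theta_p, plast.theta_d, gp, gd, 0.0, ntype, npar, dv)
    want_w, want_post = _reference_p2(77, 80.0, rho0, plast, cal, False,
                                      neuron, dv)
    assert want_post.sum() > 0, "reference run should actually spike"
    np.testing.assert_array_equal(got_post, want_post)
    np.testing.assert_allclose(got_w, want_w, rtol=0, atol=1e-12)


def test_affine_path_equals_direct_path():
    plast, cal = LC_PLASTICITY, LC_CALCIUM
    gp, gd, _ = _scales(plast)
    ma, mb = _kernels.p1_affine_trial(
        5, N_STEPS, N_SYN, DT, 40.0, 40.0, False,
        cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
        plast.theta_p, plast.theta_d, gp, gd)
    for w0 in (0.0, 0.3, 1.0):
        direct = _kernels.p1_direct_trial(
            5, N_STEPS, DT, 40.0, 40.0, np.full(N_SYN, w0), False,
            cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
            plast.theta_p, plast.theta_d, gp, gd, 0.0)
        np.testing.assert_allclose(ma * w0 + mb, direct, atol=1e-12)


def test_nlc_with_zero_coupling_reduces_to_lc():
    # same spike trains, xi forced to 0: total calcium and weights match LC
    plast, cal = LC_PLASTICITY, LC_CALCIUM
    gp, gd, _ = _scales(plast)
    rho0 = np.full(N_SYN, 0.5)
    lc = _kernels.p1_direct_trial(
        9, N_STEPS, DT, 80.0, 60.0, rho0, False,
        cal.tau_ca, cal.c_pre, cal.c_post, 0.0,
        plast.theta_p, plast.theta_d, gp, gd, 0.0)
    nlc = _kernels.p1_direct_trial(
        9, N_STEPS, DT, 80.0, 60.0, rho0, True,
        cal.tau_ca, cal.c_pre, cal.c_post, 0.0,
        plast.theta_p, plast.theta_d, gp, gd, 0.0)
    np.testing.assert_allclose(nlc, lc, atol=1e-12)


def test_p3_kernel_symmetric_populations_are_exchangeable():
    plast, cal = LC_PLASTICITY, LC_CALCIUM
    gp, gd, _ = _scales(plast)
    rho = np.full(N_SYN, 0.5)
    npar = mat_param_array(MAT_PARAMS)
    w1, w2, post = _kernels.p3_trial(
        11, N_STEPS, DT, 50.0, 50.0, rho, rho, False,
        cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
        plast.theta_p, plast.theta_d, gp, gd, 0.0,
        _kernels.NEURON_MAT, npar, 5.0)
    assert w1[0] == w2[0] == 0.5
    # same marginal dynamics: endpoints agree within the spread of either
    assert abs(w1[-1] - w2[-1]) < 0.1


def test_kernel_determinism():
    plast, cal = LC_PLASTICITY, LC_CALCIUM
    gp, gd, _ = _scales(plast)
    args = (321, N_STEPS, N_SYN, DT, 30.0, 30.0, False,
            cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
            plast.theta_p, plast.theta_d, gp, gd)
    a1, b1 = _kernels.p1_affine_trial(*args)
    a2, b2 = _kernels.p1_affine_trial(*args)
    np.testing.assert_array_equal(a1, a2)
    np.testing.assert_array_equal(b1, b2)
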