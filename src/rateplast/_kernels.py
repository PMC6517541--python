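"""Compiled (numba) trial kernels for the spike-level sweeps.

These re-implement the single-step model semantics of
:mod:`rateplast.plasticity` and :mod:`rateplast.neurons` as tight Euler loops
over a whole trial; unit tests verify step-for-step agreement with the pure
numpy reference functions.

Conventions shared by all kernels:

* ``dt_ms`` is the Euler step in ms; plasticity rates are pre-scaled to
  per-step increments ``gp_dt = gamma_p * dt / tau`` (dt in s, tau in s).
* Random numbers come from numpy's legacy MT19937 stream seeded inside the
  kernel; the draw order per step is fixed and documented per kernel so that
  reference implementations can replay the identical stream.
* Within one step the order of events is: presynaptic spikes are drawn, the
  postsynaptic spike is determined (drawn for a Poisson post neuron,
  computed by the neuron model otherwise), calcium decays and receives this
  step's spike increments, the threshold gates are evaluated, and the
  weights are updated.  Spikes at time t therefore act on plasticity at
  time t.

Neuron parameters are passed as packed float64 arrays:

* MAT:  [tau_m, s0, alpha1, alpha2, tau1, tau2, refractory]
* AEIF: [tau_m, e_l, delta_t, v_t, r_mem, tau_z, a, b, v_peak]
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEURON_POISSON = 0
NEURON_MAT = 1
NEURON_AEIF = 2


@njit(cache=True)
def _calcium_update(c_pre, c_post, pre_spikes, post_spike, nonlinear,
                    decay, amp_pre, amp_post, xi):
    """In-place calcium update for one step over all synapses."""
    n = c_pre.shape[0]
    for i in range(n):
        readout = c_pre[i]
        c_pre[i] *= decay
        if nonlinear:
            c_post[i] *= decay
        if pre_spikes[i]:
            c_pre[i] += amp_pre
        if post_spike:
            if nonlinear:
                c_post[i] += amp_post + xi * readout
            else:
                c_pre[i] += amp_post


@njit(cache=True)
def p1_affine_trial(seed, n_steps, n_syn, dt_ms, u, v, nonlinear,
                    tau_ca, amp_pre, amp_post, xi,
                    theta_p, theta_d, gp_dt, gd_dt):
    """P1 trial propagating the affine map w0 -> rho(t) instead of rho itself.

    With sigma = 0 the Euler update is affine in the weight,
    ``rho' = a * rho + b`` with per-synapse, per-step coefficients determined
    only by the calcium gates.  Propagating the products ``A_i`` and offsets
    ``B_i`` yields the population-mean trajectory for every initial weight at
    once: ``wbar(t; w0) = mean_A(t) * w0 + mean_B(t)``.

    RNG draw order per step: ``n_syn`` uniforms (pre spikes), then one
    uniform (post spike).

    Returns ``(mean_a, mean_b)`` arrays of length ``n_steps + 1``.
    """
    np.random.seed(seed)
    p_pre = u * dt_ms * 1e-3
    p_post = v * dt_ms * 1e-3
    decay = 1.0 - dt_ms / tau_ca

    c_pre = np.zeros(n_syn)
    c_post = np.zeros(n_syn)
    a_fac = np.ones(n_syn)
    b_off = np.zeros(n_syn)
    pre_spikes = np.zeros(n_syn, dtype=np.bool_)

    mean_a = np.empty(n_steps + 1)
    mean_b = np.empty(n_steps + 1)
    mean_a[0] = 1.0
    mean_b[0] = 0.0

    for t in range(n_steps):
        for i in range(n_syn):
            pre_spikes[i] = np.random.random() < p_pre
        post_spike = np.random.random() < p_post
        _calcium_update(c_pre, c_post, pre_spikes, post_spike, nonlinear,
                        decay, amp_pre, amp_post, xi)
        sum_a = 0.0
        sum_b = 0.0
        for i in range(n_syn):
            c = c_pre[i] + c_post[i] if nonlinear else c_pre[i]
            hp = 1.0 if c >= theta_p else 0.0
            hd = 1.0 if c >= theta_d else 0.0
            a = 1.0 - gp_dt * hp - gd_dt * hd
            b = gp_dt * hp
            a_fac[i] = a_fac[i] * a
            b_off[i] = b_off[i] * a + b
            sum_a += a_fac[i]
            sum_b += b_off[i]
        mean_a[t + 1] = sum_a / n_syn
        mean_b[t + 1] = sum_b / n_syn
    return mean_a, mean_b


@njit(cache=True)
def p1_direct_trial(seed, n_steps, dt_ms, u, v, rho0, nonlinear,
                    tau_ca, amp_pre, amp_post, xi,
                    theta_p, theta_d, gp_dt, gd_dt, sigma_step):
    """P1 trial with explicit per-synapse weights (supports noise, any init).

    ``sigma_step = sigma * sqrt(dt / tau)`` (dt, tau in s); a value of 0
    disables the noise term.  RNG draw order per step: ``n_syn`` uniforms
    (pre), one uniform (post), then ``n_syn`` normals iff ``sigma_step > 0``.

    Returns the population-mean weight trace of length ``n_steps + 1``.
    """
    np.random.seed(seed)
    n_syn = rho0.shape[0]
    p_pre = u * dt_ms * 1e-3
    p_post = v * dt_ms * 1e-3
    decay = 1.0 - dt_ms / tau_ca

    c_pre = np.zeros(n_syn)
    c_post = np.zeros(n_syn)
    rho = rho0.copy()
    pre_spikes = np.zeros(n_syn, dtype=np.bool_)

    wbar = np.empty(n_steps + 1)
    wbar[0] = rho.mean()

    for t in range(n_steps):
        for i in range(n_syn):
            pre_spikes[i] = np.random.random() < p_pre
        post_spike = np.random.random() < p_post
        _calcium_update(c_pre, c_post, pre_spikes, post_spike, nonlinear,
                        decay, amp_pre, amp_post, xi)
        s = 0.0
        for i in range(n_syn):
            c = c_pre[i] + c_post[i] if nonlinear else c_pre[i]
            hp = 1.0 if c >= theta_p else 0.0
            hd = 1.0 if c >= theta_d else 0.0
            r = rho[i] + gp_dt * hp * (1.0 - rho[i]) - gd_dt * hd * rho[i]
            if sigma_step > 0.0:
                r += sigma_step * np.sqrt(hp + hd) * np.random.normal(0.0, 1.0)
            if r < 0.0:
                r = 0.0
            elif r > 1.0:
                r = 1.0
            rho[i] = r
            s += r
        wbar[t + 1] = s / n_syn
    return wbar


@njit(cache=True)
def _neuron_spike(neuron_type, state, drive, dt_ms, npar):
    """Advance the packed neuron state one step; returns 1.0 on a spike.

    MAT state: [v, h1, h2, age]; AEIF state: [v, z, 0, 0].
    """
    if neuron_type == NEURON_MAT:
        tau_m, s0, a1, a2, tau1, tau2, refr = (
            npar[0], npar[1], npar[2], npar[3], npar[4], npar[5], npar[6])
        v = (state[0] + drive) * (1.0 - dt_ms / tau_m)
        h1 = state[1] * (1.0 - dt_ms / tau1)
        h2 = state[2] * (1.0 - dt_ms / tau2)
        age = state[3] + dt_ms
        spiked = 0.0
        if v >= s0 + h1 + h2 and age >= refr:
            h1 += a1
            h2 += a2
            age = 0.0
            spiked = 1.0
        state[0] = v
        state[1] = h1
        state[2] = h2
        state[3] = age
        return spiked
    else:
        tau_m, e_l, delta_t, v_t, r_mem, tau_z, a, b, v_peak = (
            npar[0], npar[1], npar[2], npar[3], npar[4],
            npar[5], npar[6], npar[7], npar[8])
        v = state[0] + drive
        z = state[1]
        exp_arg = (v - v_t) / delta_t
        if exp_arg > 30.0:
            exp_arg = 30.0
        dv = (-(v - e_l) + delta_t * np.exp(exp_arg) - r_mem * z) * dt_ms / tau_m
        dz = (a * (v - e_l) * 1e-3 - z) * dt_ms / tau_z
        v += dv
        z += dz
        spiked = 0.0
        if v >= v_peak:
            v = e_l
            z += b
            spiked = 1.0
        state[0] = v
        state[1] = z
        return spiked


@njit(cache=True)
def p2_trial(seed, n_steps, dt_ms, u, rho0, nonlinear,
             tau_ca, amp_pre, amp_post, xi,
             theta_p, theta_d, gp_dt, gd_dt, sigma_step,
             neuron_type, npar, dv_per_rho):
    """P2 trial: one presynaptic population driving a model neuron.

    ``dv_per_rho = alpha_n * kappa`` in mV per unit weight per spike.  RNG
    draw order per step: ``n_syn`` uniforms (pre), then ``n_syn`` normals iff
    ``sigma_step > 0``.  Returns ``(wbar, post_spikes)`` with ``post_spikes``
    a per-step 0/1 array.
    """
    np.random.seed(seed)
    n_syn = rho0.shape[0]
    p_pre = u * dt_ms * 1e-3
    decay = 1.0 - dt_ms / tau_ca

    c_pre = np.zeros(n_syn)
    c_post = np.zeros(n_syn)
    rho = rho0.copy()
    pre_spikes = np.zeros(n_syn, dtype=np.bool_)
    nstate = np.zeros(4)
    if neuron_type == NEURON_AEIF:
        nstate[0] = npar[1]  # start at E_L

    wbar = np.empty(n_steps + 1)
    wbar[0] = rho.mean()
    post_spikes = np.zeros(n_steps, dtype=np.uint8)

    for t in range(n_steps):
        drive = 0.0
        for i in range(n_syn):
            spk = np.random.random() < p_pre
            pre_spikes[i] = spk
            if spk:
                drive += rho[i]
        drive *= dv_per_rho
        post_spike = _neuron_spike(neuron_type, nstate, drive, dt_ms, npar) > 0.0
        if post_spike:
            post_spikes[t] = 1
        _calcium_update(c_pre, c_post, pre_spikes, post_spike, nonlinear,
                        decay, amp_pre, amp_post, xi)
        s = 0.0
        for i in range(n_syn):
            c = c_pre[i] + c_post[i] if nonlinear else c_pre[i]
            hp = 1.0 if c >= theta_p else 0.0
            hd = 1.0 if c >= theta_d else 0.0
            r = rho[i] + gp_dt * hp * (1.0 - rho[i]) - gd_dt * hd * rho[i]
            if sigma_step > 0.0:
                r += sigma_step * np.sqrt(hp + hd) * np.random.normal(0.0, 1.0)
            if r < 0.0:
                r = 0.0
            elif r > 1.0:
                r = 1.0
            rho[i] = r
            s += r
        wbar[t + 1] = s / n_syn
    return wbar, post_spikes


@njit(cache=True)
def p3_trial(seed, n_steps, dt_ms, u1, u2, rho0_1, rho0_2, nonlinear,
             tau_ca, amp_pre, amp_post, xi,
             theta_p, theta_d, gp_dt, gd_dt, sigma_step,
             neuron_type, npar, dv_per_rho):
    """P3 trial: two presynaptic populations converging on one model neuron.

    RNG draw order per step: ``n1`` uniforms (population 1), ``n2`` uniforms
    (population 2), then ``n1 + n2`` normals iff ``sigma_step > 0``.
    Returns ``(wbar1, wbar2, post_spikes)``.
    """
    np.random.seed(seed)
    n1 = rho0_1.shape[0]
    n2 = rho0_2.shape[0]
    p1 = u1 * dt_ms * 1e-3
    p2 = u2 * dt_ms * 1e-3
    decay = 1.0 - dt_ms / tau_ca

    c_pre1 = np.zeros(n1)
    c_post1 = np.zeros(n1)
    c_pre2 = np.zeros(n2)
    c_post2 = np.zeros(n2)
    rho1 = rho0_1.copy()
    rho2 = rho0_2.copy()
    spikes1 = np.zeros(n1, dtype=np.bool_)
    spikes2 = np.zeros(n2, dtype=np.bool_)
    nstate = np.zeros(4)
    if neuron_type == NEURON_AEIF:
        nstate[0] = npar[1]

    wbar1 = np.empty(n_steps + 1)
    wbar2 = np.empty(n_steps + 1)
    wbar1[0] = rho1.mean()
    wbar2[0] = rho2.mean()
    post_spikes = np.zeros(n_steps, dtype=np.uint8)

    for t in range(n_steps):
        drive = 0.0
        for i in range(n1):
            spk = np.random.random() < p1
            spikes1[i] = spk
            if spk:
                drive += rho1[i]
        for i in range(n2):
            spk = np.random.random() < p2
            spikes2[i] = spk
            if spk:
                drive += rho2[i]
        drive *= dv_per_rho
        post_spike = _neuron_spike(neuron_type, nstate, drive, dt_ms, npar) > 0.0
        if post_spike:
            post_spikes[t] = 1
        _calcium_update(c_pre1, c_post1, spikes1, post_spike, nonlinear,
                        decay, amp_pre, amp_post, xi)
        _calcium_update(c_pre2, c_post2, spikes2, post_spike, nonlinear,
                        decay, amp_pre, amp_post, xi)
        s1 = 0.0
        for i in range(n1):
            c = c_pre1[i] + c_post1[i] if nonlinear else c_pre1[i]
            hp = 1.0 if c >= theta_p else 0.0
            hd = 1.0 if c >= theta_d else 0.0
            r = rho1[i] + gp_dt * hp * (1.0 - rho1[i]) - gd_dt * hd * rho1[i]
            if sigma_step > 0.0:
                r += sigma_step * np.sqrt(hp + hd) * np.random.normal(0.0, 1.0)
            rho1[i] = min(max(r, 0.0), 1.0)
            s1 += rho1[i]
        s2 = 0.0
        for i in range(n2):
            c = c_pre2[i] + c_post2[i] if nonlinear else c_pre2[i]
            hp = 1.0 if c >= theta_p else 0.0
            hd = 1.0 if c >= theta_d else 0.0
            r = rho2[i] + gp_dt * hp * (1.0 - rho2[i]) - gd_dt * hd * rho2[i]
            if sigma_step > 0.0:
                r += sigma_step * np.sqrt(hp + hd) * np.random.normal(0.0, 1.0)
            rho2[i] = min(max(r, 0.0), 1.0)
            s2 += rho2[i]
        wbar1[t + 1] = s1 / n1
        wbar2[t + 1] = s2 / n2
    return wbar1, wbar2, post_spikes


@njit(cache=True)
def neuron_rate_trial(seed, n_steps, dt_ms, pre_rate, n_syn, rho_value,
                      neuron_type, npar, dv_per_rho):
    """Postsynaptic spike count with plasticity frozen (for rate lookups).

    Simulates ``n_syn`` Poisson inputs at ``pre_rate`` with a fixed common
    weight ``rho_value`` and counts output spikes over the whole run.
    """
    np.random.seed(seed)
    p_pre = pre_rate * dt_ms * 1e-3
    nstate = np.zeros(4)
    if neuron_type == NEURON_AEIF:
        nstate[0] = npar[1]
    count = 0
    for t in range(n_steps):
        n_spk = 0
        for i in range(n_syn):
            if np.random.random() < p_pre:
                n_spk += 1
        drive = dv_per_rho * rho_value * n_spk
        if _neuron_spike(neuron_type, nstate, drive, dt_ms, npar) > 0.0:
            count += 1
    return count
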