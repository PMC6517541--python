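# Default parameter presets. Values mirror the published model parameters;
# grids come in a desk-scale "scaled" preset and the original "full" preset.
plasticity:
  lc:
    tau_ca: 22.27212
    c_pre: 0.84410
    c_post: 1.62138
    theta_d: 1.0
    theta_p: 2.009289
    gamma_d: 137.7586
    gamma_p: 597.08922
    tau: 520.76129
    sigma: 0.0
  nlc:
    tau_ca: 18.93044
    c_pre: 0.86467
    c_post: 2.30815
    theta_d: 1.0
    theta_p: 4.99780
    gamma_d: 111.82515
    gamma_p: 894.23695
    tau: 707.02258
    sigma: 0.0

neuron:
  mat:
    tau_m: 5.0
    r_mem: 50.0
    s0: 20.0
    alpha1: 30.0
    alpha2: 2.0
    tau1: 10.0
    tau2: 200.0
    refractory: 2.0
    alpha_n: {p2: 400.0, p3: 200.0}
  aeif:
    tau_m: 9.367
    e_l: -70.6
    delta_t: 2.0
    v_t: -50.4
    r_mem: 33.33
    tau_z: 144.0
    a: 4.0
    b: 0.0805
    v_peak: 0.0
    alpha_n: {p2: 170.0, p3: 80.5}

drive:
  kappa_ms: 0.5   # membrane deflection per spike = kappa * alpha_n * rho

grids:
  scaled:
    rate_step: 5.0
    w_step: 0.1
    n_synapses: 200
    n_inits: {P1: 20, P2: 10, P3: 5}
    p3_rate_step: 25.0
    p3_w_step: 0.25
  full:
    rate_step: 1.0
    w_step: 0.05
    n_synapses: 1000
    n_inits: {P1: 100, P2: 100, P3: 38}
    p3_rate_step: 1.0
    p3_w_step: 0.05

simulation:
  t_end: 2.0      # s
  dt: 0.5         # ms
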