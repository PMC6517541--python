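"""Spike generation: Poisson trains, MAT and AEIF postsynaptic neurons.

Two point-neuron models can stand in for the postsynaptic cell:

* MAT (multi-timescale adaptive threshold): a leaky integrator whose spike
  threshold jumps by ``alpha1``/``alpha2`` after each output spike and decays
  back on two timescales.  The membrane is never reset; only spike emission
  is blocked during the refractory period.
* AEIF (adaptive exponential integrate-and-fire): exponential spike
  initiation around ``v_t`` plus a slow adaptation current ``z``; on a spike
  the membrane resets to ``e_l`` and ``z`` jumps by ``b``.

Presynaptic input enters through a weight-dependent drive: each presynaptic
spike from synapse i deflects the membrane by ``kappa * alpha_n * rho_i``
where ``alpha_n`` (mV/s) is the published population-size-dependent scale and
``kappa`` a fixed unit-bridging time constant.  ``kappa`` defaults to the
integration step (0.5 ms), i.e. a spike acts as a one-step current pulse;
this calibration makes the standard two-population benchmark reproduce net
depression at 30 Hz input and net potentiation at 60 Hz (see docs/methods.md)
and is frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KAPPA_MS",
    "MATParams",
    "MATState",
    "AEIFParams",
    "AEIFState",
    "MAT_PARAMS",
    "AEIF_PARAMS",
    "ALPHA_N",
    "poisson_spikes",
    "postsyn_drive",
    "mat_step",
    "aeif_step",
]

#: Unit bridge for the spike drive, in ms: one presynaptic spike adds
#: ``alpha_n [mV/s] * KAPPA_MS * 1e-3 [s] * rho_i`` mV to the membrane.
KAPPA_MS = 0.5

#: Population size the published alpha(N) values refer to.  alpha(N) is a
#: population-size-dependent scale: simulating a smaller population at the
#: same total drive requires alpha_n * (ALPHA_REF_N / N).
ALPHA_REF_N = 1000

#: Published drive scales alpha(N) in mV/s, keyed by (neuron, motif).
ALPHA_N = {
    ("mat", "P2"): 400.0,
    ("mat", "P3"): 200.0,
    ("aeif", "P2"): 170.0,
    ("aeif", "P3"): 80.5,
}


@dataclass(frozen=True)
class MATParams:
    """Multi-timescale adaptive threshold neuron (times in ms, voltages mV)."""

    tau_m: float = 5.0
    r_mem: float = 50.0
    s0: float = 20.0
    alpha1: float = 30.0
    alpha2: float = 2.0
    tau1: float = 10.0
    tau2: float = 200.0
    refractory: float = 2.0
    alpha_n: float = 400.0

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau1, self.tau2) <= 0:
            raise ValueError("time constants must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")


@dataclass
class MATState:
    """Membrane and threshold state; ``last_spike_age`` in ms."""

    v_mem: float = 0.0
    h1: float = 0.0
    h2: float = 0.0
    last_spike_age: float = np.inf

    @property
    def threshold(self) -> float:
        return self.h1 + self.h2

    def threshold_total(self, params: MATParams) -> float:
        return params.s0 + self.h1 + self.h2


@dataclass(frozen=True)
class AEIFParams:
    """Adaptive exponential integrate-and-fire neuron.

    ``v_peak`` is the numerical spike-detection cutoff (the published model
    names none; 0 mV is the conventional choice).  ``a`` is in nS, ``b`` in
    nA, ``r_mem`` in MOhm, so ``r_mem * z`` is in mV and the subthreshold
    adaptation target ``a * (V - e_l)`` is converted from pA to nA.
    """

    tau_m: float = 9.367
    e_l: float = -70.6
    delta_t: float = 2.0
    v_t: float = -50.4
    r_mem: float = 33.33
    tau_z: float = 144.0
    a: float = 4.0
    b: float = 0.0805
    v_peak: float = 0.0
    alpha_n: float = 170.0

    def __post_init__(self) -> None:
        if self.delta_t <= 0 or self.tau_z <= 0 or self.tau_m <= 0:
            raise ValueError("delta_t, tau_z, tau_m must be positive")


@dataclass
class AEIFState:
    v_mem: float = -70.6
    z: float = 0.0


MAT_PARAMS = MATParams()
AEIF_PARAMS = AEIFParams()


def poisson_spikes(
    rate: float,
    n_neurons: int,
    n_steps: int,
    dt: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Bernoulli-thinned Poisson spike trains, shape (n_steps, n_neurons).

    ``rate`` in Hz, ``dt`` in ms.  Requires ``rate * dt <= 0.1`` so that the
    per-step Bernoulli approximation (at most one spike per step) is valid.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    p = rate * dt * 1e-3
    if p > 0.1:
        raise ValueError("rate * dt too large for Bernoulli thinning")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.random((n_steps, n_neurons)) < p


def postsyn_drive(
    rho: np.ndarray,
    pre_spikes_this_step: np.ndarray,
    alpha_n: float,
    kappa_ms: float = KAPPA_MS,
) -> float:
    """Membrane increment (mV) from this step's presynaptic spikes.

    Linear in the weights: ``kappa * alpha_n * sum_i rho_i [spike_i]``.
    """
    rho = np.asarray(rho, dtype=float)
    spikes = np.asarray(pre_spikes_this_step)
    if rho.shape != spikes.shape:
        raise ValueError("rho and spike vectors must have equal length")
    return float(alpha_n * kappa_ms * 1e-3 * np.sum(rho * spikes))


def mat_step(
    state: MATState,
    drive: float,
    dt: float,
    params: MATParams,
) -> tuple[MATState, bool]:
    """One Euler step of the MAT neuron (dt in ms).

    The drive is applied as an instantaneous increment before the leak.  A
    spike is emitted when V reaches the adaptive threshold and the neuron is
    out of its refractory period; there is no voltage reset.
    """
    if dt >= params.tau_m:
        raise ValueError("dt must be smaller than tau_m")
    v = state.v_mem + drive
    v = v * (1.0 - dt / params.tau_m)
    h1 = state.h1 * (1.0 - dt / params.tau1)
    h2 = state.h2 * (1.0 - dt / params.tau2)
    age = state.last_spike_age + dt
    threshold = params.s0 + h1 + h2
    spiked = (v >= threshold) and (age >= params.refractory)
    if spiked:
        h1 += params.alpha1
        h2 += params.alpha2
        age = 0.0
    return MATState(v_mem=v, h1=h1, h2=h2, last_spike_age=age), spiked


def aeif_step(
    state: AEIFState,
    drive: float,
    dt: float,
    params: AEIFParams,
) -> tuple[AEIFState, bool]:
    """One Euler step of the AEIF neuron (dt in ms).

    The exponential argument is capped to keep a runaway membrane finite; the
    spike itself is detected at ``v_peak``, after which V resets to ``e_l``
    and the adaptation current jumps by ``b``.
    """
    if dt >= params.tau_m:
        raise ValueError("dt must be smaller than tau_m")
    v = state.v_mem + drive
    exp_arg = min((v - params.v_t) / params.delta_t, 30.0)
    dv = (-(v - params.e_l) + params.delta_t * np.exp(exp_arg)
          - params.r_mem * state.z) * dt / params.tau_m
    # a*(V-E_L) is in pA (nS * mV); z and b are in nA.
    dz = (params.a * (v - params.e_l) * 1e-3 - state.z) * dt / params.tau_z
    v = v + dv
    z = state.z + dz
    spiked = v >= params.v_peak
    if spiked:
        v = params.e_l
        z += params.b
    return AEIFState(v_mem=v, z=z), spiked
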