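"""Calcium-based synaptic plasticity: the detailed spike-level model.

The synapse model is a calcium-threshold rule: each synapse i carries a
dimensionless strength ``rho_i`` in [0, 1] and a postsynaptic calcium trace
``c_i``.  Whenever calcium exceeds the potentiation threshold ``theta_p`` the
strength relaxes toward 1 at rate ``gamma_p``; whenever it exceeds the
depression threshold ``theta_d`` it relaxes toward 0 at rate ``gamma_d``; both
gates may be open at once.  An optional activity-gated white-noise term models
weight fluctuations unrelated to the deterministic drift:

    tau * drho/dt = gamma_p (1 - rho) H(c - theta_p) - gamma_d rho H(c - theta_d)
                    + sigma sqrt(tau) sqrt(H(c - theta_p) + H(c - theta_d)) eta(t)

Calcium is driven by pre- and postsynaptic spikes and decays with time
constant ``tau_ca``.  Two variants are supported: a linear model (LC) where a
single trace receives fixed-amplitude increments ``c_pre`` / ``c_post``, and a
nonlinear model (NLC) with separate pre- and postsynaptically evoked traces in
which a postsynaptic spike additionally reads out the instantaneous
presynaptic trace through the coupling factor ``xi``.

All functions here are plain-numpy single-Euler-step updates.  They define
the model semantics and serve as the reference against which the compiled
sweep kernels in :mod:`rateplast._kernels` are verified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PlasticityParams",
    "CalciumParams",
    "SynapseState",
    "LC_PLASTICITY",
    "NLC_PLASTICITY",
    "LC_CALCIUM",
    "NLC_CALCIUM",
    "xi_coupling",
    "lc_calcium_step",
    "nlc_calcium_step",
    "plasticity_step",
    "drift_fixed_point",
]


def xi_coupling(c_pre: float, c_post: float) -> float:
    """Nonlinearity factor coupling pre- and postsynaptic calcium (NLC)."""
    return 2.0 * (c_post + c_pre) - c_post * c_pre


@dataclass(frozen=True)
class PlasticityParams:
    """Weight-update parameters of the calcium-threshold plasticity rule.

    ``tau`` is in seconds; ``gamma_p``/``gamma_d`` are dimensionless rates,
    ``theta_p``/``theta_d`` calcium thresholds, ``sigma`` the noise amplitude.
    The noise amplitude is not part of the published parameter set; the
    default is 0 so that all stochasticity comes from the spike trains.
    """

    tau: float
    gamma_p: float
    gamma_d: float
    theta_p: float
    theta_d: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.gamma_p <= 0 or self.gamma_d <= 0:
            raise ValueError("gamma_p and gamma_d must be positive")
        if not (self.theta_p >= self.theta_d > 0):
            raise ValueError("thresholds must satisfy theta_p >= theta_d > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def with_sigma(self, sigma: float) -> "PlasticityParams":
        return replace(self, sigma=sigma)


@dataclass(frozen=True)
class CalciumParams:
    """Calcium-trace parameters.  ``tau_ca`` in ms; amplitudes dimensionless.

    ``xi`` is only used by the nonlinear model and is derived from the spike
    amplitudes; for the linear model it is irrelevant and kept at 0.
    """

    tau_ca: float
    c_pre: float
    c_post: float
    xi: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be positive")
        if self.c_pre <= 0 or self.c_post <= 0:
            raise ValueError("c_pre and c_post must be positive")

    @classmethod
    def nonlinear(cls, tau_ca: float, c_pre: float, c_post: float) -> "CalciumParams":
        """Build NLC parameters with the coupling factor derived exactly."""
        return cls(tau_ca=tau_ca, c_pre=c_pre, c_post=c_post,
                   xi=xi_coupling(c_pre, c_post))


# Published parameter sets for the linear (LC) and nonlinear (NLC) variants.
LC_PLASTICITY = PlasticityParams(
    tau=520.76129, gamma_p=597.08922, gamma_d=137.7586,
    theta_p=2.009289, theta_d=1.0,
)
NLC_PLASTICITY = PlasticityParams(
    tau=707.02258, gamma_p=894.23695, gamma_d=111.82515,
    theta_p=4.99780, theta_d=1.0,
)
LC_CALCIUM = CalciumParams(tau_ca=22.27212, c_pre=0.84410, c_post=1.62138)
NLC_CALCIUM = CalciumParams.nonlinear(tau_ca=18.93044, c_pre=0.86467, c_post=2.30815)


@dataclass
class SynapseState:
    """Per-synapse strengths and calcium traces for one population.

    For the LC model ``c_post_trace`` stays None and ``c_pre_trace`` holds the
    single calcium variable.  For NLC both traces are present and the total
    calcium seen by the plasticity rule is their sum.
    """

    rho: np.ndarray
    c_pre_trace: np.ndarray
    c_post_trace: np.ndarray | None = None

    @property
    def calcium(self) -> np.ndarray:
        if self.c_post_trace is None:
            return self.c_pre_trace
        return self.c_pre_trace + self.c_post_trace

    @classmethod
    def uniform(cls, n: int, w0: float, nonlinear: bool = False) -> "SynapseState":
        rho = np.full(n, float(w0))
        if nonlinear:
            return cls(rho, np.zeros(n), np.zeros(n))
        return cls(rho, np.zeros(n))


def _check_dt(dt: float, tau_ca: float) -> None:
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= tau_ca:
        raise ValueError(f"dt={dt} must be smaller than tau_ca={tau_ca}")


def lc_calcium_step(
    c: np.ndarray,
    pre_spike: np.ndarray,
    post_spike: bool | np.ndarray,
    dt: float,
    params: CalciumParams,
) -> np.ndarray:
    """One explicit-Euler step of the linear calcium trace (dt, tau_ca in ms).

    The decay sub-step is applied first, then the spike increments, so spikes
    at time t act on plasticity at time t with their full amplitude.
    """
    _check_dt(dt, params.tau_ca)
    out = c * (1.0 - dt / params.tau_ca)
    out = out + params.c_pre * np.asarray(pre_spike, dtype=float)
    out = out + params.c_post * (np.asarray(post_spike, dtype=float))
    return out


def nlc_calcium_step(
    c_pre: np.ndarray,
    c_post: np.ndarray,
    pre_spike: np.ndarray,
    post_spike: bool | np.ndarray,
    dt: float,
    params: CalciumParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of the nonlinear (two-trace) calcium dynamics.

    Postsynaptic spikes deposit ``c_post + xi * c_pre`` where the presynaptic
    trace is read out at its value from before this step's decay, matching a
    delta-function reading of the continuous-time equations.
    """
    _check_dt(dt, params.tau_ca)
    c_pre_readout = c_pre  # value before the decay sub-step
    decay = 1.0 - dt / params.tau_ca
    post = np.asarray(post_spike, dtype=float)
    new_pre = c_pre * decay + params.c_pre * np.asarray(pre_spike, dtype=float)
    new_post = c_post * decay + (params.c_post + params.xi * c_pre_readout) * post
    return new_pre, new_post


def plasticity_step(
    rho: np.ndarray,
    c: np.ndarray,
    dt: float,
    params: PlasticityParams,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """One Euler(-Maruyama) step of the weight update (dt in seconds).

    ``noise`` is a standard-normal vector (one draw per synapse); it is only
    consulted when ``params.sigma > 0``.  The gate convention is H(0) = 1.
    The result is clipped to [0, 1]; with sigma = 0 and a stable step size
    the clip is never active.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt * params.gamma_p / params.tau >= 1 or dt * params.gamma_d / params.tau >= 1:
        raise ValueError("unstable step: dt * gamma / tau must be < 1")
    h_p = (c >= params.theta_p).astype(float)
    h_d = (c >= params.theta_d).astype(float)
    drift = (params.gamma_p * (1.0 - rho) * h_p - params.gamma_d * rho * h_d)
    new = rho + drift * (dt / params.tau)
    if params.sigma > 0:
        if noise is None:
            raise ValueError("sigma > 0 requires a noise vector")
        amp = params.sigma * np.sqrt(dt / params.tau) * np.sqrt(h_p + h_d)
        new = new + amp * noise
    return np.clip(new, 0.0, 1.0)


def drift_fixed_point(params: PlasticityParams) -> float:
    """Weight at which the drift vanishes when both gates are open."""
    return params.gamma_p / (params.gamma_p + params.gamma_d)
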