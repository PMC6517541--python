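"""Neuronal motifs and grid sweeps of spike-level trials.

Three motifs are supported, each a presynaptic population of ``N`` Poisson
neurons converging on one postsynaptic unit:

* ``P1`` — the postsynaptic train is itself an independent Poisson process
  at a preset rate ``v``; grid over (u, v, w0).
* ``P2`` — the postsynaptic unit is a model neuron (MAT or AEIF) driven by
  the weighted presynaptic spikes; grid over (u, w0), with ``v`` measured.
* ``P3`` — two presynaptic populations with independent rates and initial
  weights drive the same model neuron; grid over (u1, u2, w1, w2).

A sweep runs ``Z`` independently seeded trials per grid point and yields one
:class:`TrialTrace` per (point, initialization): the population-mean weight
trajectory over the trial horizon plus, for P2/P3, the measured postsynaptic
rate.  Seeds are derived deterministically from the master seed, the motif,
the models, the grid point and the initialization index, so sweeps are
reproducible and individual trials can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from . import _kernels
from .neurons import (ALPHA_N, ALPHA_REF_N, KAPPA_MS, AEIF_PARAMS,
    MAT_PARAMS, AEIFParams, MATParams)
from .plasticity import (
    LC_CALCIUM, LC_PLASTICITY, NLC_CALCIUM, NLC_PLASTICITY,
    CalciumParams, PlasticityParams,
)

__all__ = [
    "SetupConfig",
    "TrialTrace",
    "derive_seed",
    "mean_weight",
    "measure_post_rate",
    "run_trial",
    "sweep_grid",
    "mat_param_array",
    "aeif_param_array",
]

_MOTIFS = ("P1", "P2", "P3")
_PLASTICITY = {"lc": (LC_PLASTICITY, LC_CALCIUM), "nlc": (NLC_PLASTICITY, NLC_CALCIUM)}
_NEURON_IDS = {"poisson": _kernels.NEURON_POISSON, "mat": _kernels.NEURON_MAT,
               "aeif": _kernels.NEURON_AEIF}


def mat_param_array(p: MATParams) -> np.ndarray:
    return np.array([p.tau_m, p.s0, p.alpha1, p.alpha2, p.tau1, p.tau2,
                     p.refractory], dtype=float)


def aeif_param_array(p: AEIFParams) -> np.ndarray:
    return np.array([p.tau_m, p.e_l, p.delta_t, p.v_t, p.r_mem, p.tau_z,
                     p.a, p.b, p.v_peak], dtype=float)


@dataclass(frozen=True)
class SetupConfig:
    """Configuration of one motif sweep.

    Grids default to a desk-scale reduction of the full parameter space
    (full: u, v in 0..100 Hz step 1, w step 0.05, N = 1000, Z = 100): rate
    step 5 Hz, weight step 0.1, N = 200 synapses and Z = 20 (P1) / 10 (P2) /
    5 (P3) initializations.  ``t_end`` is in seconds, ``dt`` in ms.
    """

    motif: str = "P1"
    plasticity_model: str = "lc"
    neuron_model: str = "poisson"
    n_synapses: int = 200
    u_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 101, 5))
    v_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 101, 5))
    w_grid: tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 10))
    u2_grid: tuple[float, ...] | None = None    # P3; defaults to u_grid
    w2_grid: tuple[float, ...] | None = None    # P3; defaults to w_grid
    n_inits: int = 20
    t_end: float = 2.0
    dt: float = 0.5
    sigma: float = 0.0
    kappa_ms: float = KAPPA_MS
    alpha_n: float | None = None                # defaults per neuron/motif
    master_seed: int = 0
    rate_window_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.motif not in _MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.plasticity_model not in _PLASTICITY:
            raise ValueError(f"unknown plasticity model {self.plasticity_model!r}")
        if self.neuron_model not in _NEURON_IDS:
            raise ValueError(f"unknown neuron model {self.neuron_model!r}")
        if self.motif == "P1" and self.neuron_model != "poisson":
            raise ValueError("P1 uses an independent Poisson postsynaptic train")
        if self.motif in ("P2", "P3") and self.neuron_model == "poisson":
            raise ValueError(f"{self.motif} requires a model neuron (mat or aeif)")
        max_rate = max(list(self.u_grid) + list(self.v_grid)
                       + list(self.u2_grid or ()))
        if max_rate * self.dt * 1e-3 > 0.1:
            raise ValueError("rate * dt too large for Bernoulli spike thinning")
        plast, _ = _PLASTICITY[self.plasticity_model]
        dt_s = self.dt * 1e-3
        if dt_s * plast.gamma_p / plast.tau >= 1 or dt_s * plast.gamma_d / plast.tau >= 1:
            raise ValueError("unstable plasticity step size")

    # -- derived quantities -------------------------------------------------

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / (self.dt * 1e-3)))

    @property
    def plasticity(self) -> PlasticityParams:
        return _PLASTICITY[self.plasticity_model][0].with_sigma(self.sigma)

    @property
    def calcium(self) -> CalciumParams:
        return _PLASTICITY[self.plasticity_model][1]

    @property
    def nonlinear(self) -> bool:
        return self.plasticity_model == "nlc"

    @property
    def neuron_id(self) -> int:
        return _NEURON_IDS[self.neuron_model]

    def neuron_param_array(self) -> np.ndarray:
        if self.neuron_model == "mat":
            return mat_param_array(MAT_PARAMS)
        if self.neuron_model == "aeif":
            return aeif_param_array(AEIF_PARAMS)
        return np.zeros(1)

    def drive_scale(self) -> float:
        """mV membrane deflection per presynaptic spike per unit weight.

        The published alpha(N) values refer to a population of 1000
        presynaptic neurons; a scaled-down population keeps the same total
        drive by rescaling alpha with ALPHA_REF_N / N.
        """
        alpha = self.alpha_n
        if alpha is None:
            alpha = ALPHA_N.get((self.neuron_model, self.motif), 0.0)
        return alpha * (ALPHA_REF_N / self.n_synapses) * self.kappa_ms * 1e-3

    def grid_points(self) -> list[tuple[float, ...]]:
        """All grid coordinates for this motif, in deterministic order."""
        if self.motif == "P1":
            return [(u, v, w) for u in self.u_grid for v in self.v_grid
                    for w in self.w_grid]
        if self.motif == "P2":
            return [(u, w) for u in self.u_grid for w in self.w_grid]
        u2 = self.u2_grid or self.u_grid
        w2 = self.w2_grid or self.w_grid
        return [(u1, uu2, w1, ww2) for u1 in self.u_grid for uu2 in u2
                for w1 in self.w_grid for ww2 in w2]


@dataclass
class TrialTrace:
    """Population-mean weight trajectory of one trial at one grid point."""

    motif: str
    point: tuple[float, ...]
    init: int
    dt: float                       # ms
    w_bar: np.ndarray               # length n_steps + 1
    w_bar2: np.ndarray | None = None   # P3 population 2
    v_measured: float | None = None    # Hz; preset v for P1
    seed: int = 0

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.w_bar.size) * self.dt * 1e-3


def derive_seed(master_seed: int, motif: str, plasticity_model: str,
                neuron_model: str, point: Sequence[float], init: int) -> int:
    """Deterministic per-trial seed (uint32) from the sweep coordinates."""
    entropy = [int(master_seed) & 0xFFFFFFFF,
               _MOTIFS.index(motif),
               list(_PLASTICITY).index(plasticity_model),
               _NEURON_IDS[neuron_model],
               int(init)]
    entropy += [int(round(float(c) * 1_000_000)) for c in point]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0])


def mean_weight(rho: np.ndarray) -> float:
    """Population-mean synaptic strength."""
    rho = np.asarray(rho, dtype=float)
    if rho.size == 0:
        raise ValueError("empty synapse population")
    return float(rho.mean())


def measure_post_rate(post_spikes: np.ndarray, window: float, dt: float) -> float:
    """Postsynaptic rate (Hz) as spike count over the first ``window`` ms."""
    if window <= 0:
        raise ValueError("window must be positive")
    n = int(round(window / dt))
    spikes = np.asarray(post_spikes)
    if n > spikes.size:
        raise ValueError("window longer than the spike train")
    return float(spikes[:n].sum() / (window * 1e-3))


def _plasticity_step_scales(config: SetupConfig) -> tuple[float, float, float]:
    p = config.plasticity
    dt_s = config.dt * 1e-3
    gp_dt = p.gamma_p * dt_s / p.tau
    gd_dt = p.gamma_d * dt_s / p.tau
    sigma_step = p.sigma * np.sqrt(dt_s / p.tau)
    return gp_dt, gd_dt, sigma_step


def run_trial(config: SetupConfig, point: tuple[float, ...], init_index: int,
              rho0: np.ndarray | None = None) -> TrialTrace:
    """Run one spike-level trial at one grid point.

    By default every synapse starts at the grid point's initial weight
    (degenerate initial distribution); ``rho0`` overrides this with an
    explicit per-synapse initialization (used e.g. to probe insensitivity to
    the initial weight distribution).
    """
    if point not in config.grid_points():
        raise ValueError(f"point {point} is not on the configured grid")
    cal, plast = config.calcium, config.plasticity
    gp_dt, gd_dt, sigma_step = _plasticity_step_scales(config)
    seed = derive_seed(config.master_seed, config.motif, config.plasticity_model,
                       config.neuron_model, point, init_index)
    npar = config.neuron_param_array()

    if config.motif == "P1":
        u, v, w0 = point
        if rho0 is None:
            rho0 = np.full(config.n_synapses, float(w0))
        wbar = _kernels.p1_direct_trial(
            seed, config.n_steps, config.dt, u, v, rho0, config.nonlinear,
            cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
            plast.theta_p, plast.theta_d, gp_dt, gd_dt, sigma_step)
        return TrialTrace(config.motif, point, init_index, config.dt, wbar,
                          v_measured=v, seed=seed)

    if config.motif == "P2":
        u, w0 = point
        if rho0 is None:
            rho0 = np.full(config.n_synapses, float(w0))
        wbar, post = _kernels.p2_trial(
            seed, config.n_steps, config.dt, u, rho0, config.nonlinear,
            cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
            plast.theta_p, plast.theta_d, gp_dt, gd_dt, sigma_step,
            config.neuron_id, npar, config.drive_scale())
        window = min(config.rate_window_ms, config.t_end * 1e3)
        v_meas = measure_post_rate(post, window, config.dt)
        return TrialTrace(config.motif, point, init_index, config.dt, wbar,
                          v_measured=v_meas, seed=seed)

    u1, u2, w1, w2 = point
    rho0_1 = np.full(config.n_synapses, float(w1)) if rho0 is None else rho0
    rho0_2 = np.full(config.n_synapses, float(w2))
    wbar1, wbar2, post = _kernels.p3_trial(
        seed, config.n_steps, config.dt, u1, u2, rho0_1, rho0_2,
        config.nonlinear, cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
        plast.theta_p, plast.theta_d, gp_dt, gd_dt, sigma_step,
        config.neuron_id, npar, config.drive_scale())
    window = min(config.rate_window_ms, config.t_end * 1e3)
    v_meas = measure_post_rate(post, window, config.dt)
    return TrialTrace(config.motif, point, init_index, config.dt, wbar1,
                      w_bar2=wbar2, v_measured=v_meas, seed=seed)


def sweep_grid(config: SetupConfig) -> Iterator[TrialTrace]:
    """Yield one TrialTrace per grid point and initialization.

    For P1 with sigma = 0 the sweep exploits that the noise-free weight
    update is affine in the initial weight: one calcium/spike simulation per
    (u, v, initialization) yields the mean-weight trajectory for every
    initial weight on the grid simultaneously (common random numbers across
    initial weights).  Traces are yielded lazily; a full scaled-down P1
    sweep does not fit in memory at once.
    """
    cal, plast = config.calcium, config.plasticity
    gp_dt, gd_dt, sigma_step = _plasticity_step_scales(config)

    if config.motif == "P1" and config.sigma == 0.0:
        for u in config.u_grid:
            for v in config.v_grid:
                for z in range(config.n_inits):
                    # seed keyed to the (u, v) column, shared across w0
                    seed = derive_seed(config.master_seed, "P1",
                                       config.plasticity_model,
                                       config.neuron_model, (u, v), z)
                    mean_a, mean_b = _kernels.p1_affine_trial(
                        seed, config.n_steps, config.n_synapses, config.dt,
                        u, v, config.nonlinear,
                        cal.tau_ca, cal.c_pre, cal.c_post, cal.xi,
                        plast.theta_p, plast.theta_d, gp_dt, gd_dt)
                    for w0 in config.w_grid:
                        yield TrialTrace("P1", (u, v, w0), z, config.dt,
                                         mean_a * w0 + mean_b,
                                         v_measured=v, seed=seed)
        return

    for point in config.grid_points():
        for z in range(config.n_inits):
            yield run_trial(config, point, z)
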