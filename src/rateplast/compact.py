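"""Forward integration of compact rate laws and comparison to spiking runs.

A fitted rule dw/dt = f(u, v, w) is integrated by explicit Euler from an
initial weight.  For the P1 motif the postsynaptic rate is preset; for
P2/P3 it is supplied by a response model v(u, w) tabulated once from short
neuron-only simulations (plasticity frozen) and interpolated — the compact
model then needs no spike-level machinery at run time.  The resulting
weight trajectory can be compared against an ensemble of spike-level trials
at the same condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator, interp1d

from . import _kernels
from .neurons import ALPHA_N, ALPHA_REF_N, KAPPA_MS
from .model_reduction import Estimator
from .setups import TrialTrace, aeif_param_array, mat_param_array
from .neurons import MAT_PARAMS, AEIF_PARAMS

__all__ = [
    "RateTrajectory",
    "DivergenceReport",
    "VLookup",
    "build_v_lookup",
    "build_p3_v_model",
    "integrate_rate_model",
    "compare_to_spiking",
]


def _neuron_setup(neuron_model: str, motif: str, alpha_n: float | None,
                  kappa_ms: float, n_synapses: int):
    if neuron_model == "mat":
        ntype, npar = _kernels.NEURON_MAT, mat_param_array(MAT_PARAMS)
    elif neuron_model == "aeif":
        ntype, npar = _kernels.NEURON_AEIF, aeif_param_array(AEIF_PARAMS)
    else:
        raise ValueError(f"no response model for neuron {neuron_model!r}")
    if alpha_n is None:
        alpha_n = ALPHA_N[(neuron_model, motif)]
    # published alpha(N) refers to 1000 inputs; keep total drive fixed
    dv = alpha_n * (ALPHA_REF_N / n_synapses) * kappa_ms * 1e-3
    return ntype, npar, dv


@dataclass
class VLookup:
    """Bilinear (u, w) -> postsynaptic rate table for one neuron model."""

    u_grid: np.ndarray
    w_grid: np.ndarray
    table: np.ndarray           # Hz, shape (len(u_grid), len(w_grid))

    def __post_init__(self) -> None:
        self._interp = RegularGridInterpolator(
            (self.u_grid, self.w_grid), self.table,
            bounds_error=False, fill_value=None)

    def __call__(self, u, w):
        pts = np.stack(np.broadcast_arrays(np.asarray(u, float),
                                           np.asarray(w, float)), axis=-1)
        out = np.squeeze(self._interp(pts))
        return float(out) if out.ndim == 0 else out


def build_v_lookup(
    neuron_model: str = "mat",
    motif: str = "P2",
    u_grid=None,
    w_grid=None,
    n_synapses: int = 1000,
    t_sim: float = 1.0,
    dt: float = 0.5,
    seed: int = 0,
    alpha_n: float | None = None,
    kappa_ms: float = KAPPA_MS,
) -> VLookup:
    """Tabulate the neuron's firing rate over the (u, w) grid.

    Each table entry is a short frozen-weight simulation: ``n_synapses``
    Poisson inputs at rate u with common weight w.  The tabulation is the
    postsynaptic response used when integrating compact models for P2.
    """
    u_grid = np.arange(0.0, 101.0, 10.0) if u_grid is None else np.asarray(u_grid, float)
    w_grid = np.round(np.arange(0.0, 1.01, 0.1), 10) if w_grid is None else np.asarray(w_grid, float)
    ntype, npar, dv = _neuron_setup(neuron_model, motif, alpha_n, kappa_ms,
                                    n_synapses)
    n_steps = int(round(t_sim / (dt * 1e-3)))
    table = np.empty((u_grid.size, w_grid.size))
    ss = np.random.SeedSequence([seed, 0x7E5B])
    seeds = ss.generate_state(u_grid.size * w_grid.size)
    k = 0
    for i, u in enumerate(u_grid):
        for j, w in enumerate(w_grid):
            count = _kernels.neuron_rate_trial(
                int(seeds[k]), n_steps, dt, u, n_synapses, w, ntype, npar, dv)
            table[i, j] = count / t_sim
            k += 1
    return VLookup(u_grid, w_grid, table)


def build_p3_v_model(
    neuron_model: str = "mat",
    n_synapses: int = 1000,
    t_sim: float = 1.0,
    dt: float = 0.5,
    seed: int = 0,
    alpha_n: float | None = None,
    kappa_ms: float = KAPPA_MS,
    s_grid=None,
):
    """Response model v(u1, u2, w1, w2) for the two-population motif.

    The postsynaptic drive depends on the populations only through the
    summed weighted input rate s = u1 w1 + u2 w2 (per presynaptic neuron),
    so a one-dimensional table over s suffices; spike-size granularity
    differences at equal s are negligible at population size 1000.  Returns
    a callable ``v_of(u1, u2, w1, w2)``.
    """
    s_grid = np.arange(0.0, 201.0, 10.0) if s_grid is None else np.asarray(s_grid, float)
    ntype, npar, dv = _neuron_setup(neuron_model, "P3", alpha_n, kappa_ms,
                                    n_synapses)
    n_steps = int(round(t_sim / (dt * 1e-3)))
    seeds = np.random.SeedSequence([seed, 0x93A1]).generate_state(s_grid.size)
    rates = np.empty(s_grid.size)
    for k, s in enumerate(s_grid):
        count = _kernels.neuron_rate_trial(
            int(seeds[k]), n_steps, dt, s, n_synapses, 1.0, ntype, npar, dv)
        rates[k] = count / t_sim
    table = interp1d(s_grid, rates, bounds_error=False,
                     fill_value=(rates[0], rates[-1]))

    def v_of(u1, u2, w1, w2):
        return float(table(u1 * w1 + u2 * w2))

    return v_of


@dataclass
class RateTrajectory:
    """Euler-integrated weight trajectory of a compact rule."""

    times: np.ndarray               # s
    w: np.ndarray
    w2: np.ndarray | None = None    # P3 second population
    v: np.ndarray | None = None     # postsynaptic rate used at each step
    estimator: str = ""
    v_source: str = "preset"


def integrate_rate_model(
    estimator: Estimator,
    u: float | tuple[float, float],
    v_source,
    w0: float | tuple[float, float],
    t_end: float = 200.0,
    dt: float = 0.01,
) -> RateTrajectory:
    """Integrate dw/dt = f(u, v, w) by explicit Euler, clipping w to [0, 1].

    ``v_source`` is a preset rate (number, P1 style), a ``VLookup`` /
    callable ``v(u, w)`` for P2, or a callable ``v(u1, u2, w1, w2)`` for P3
    (select P3 by passing tuples for ``u`` and ``w0``).
    """
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    law = estimator.predict
    p3 = isinstance(u, (tuple, list))

    if p3:
        u1, u2 = float(u[0]), float(u[1])
        if not callable(v_source):
            raise ValueError("P3 integration needs a v(u1, u2, w1, w2) model")
        w1 = np.empty(n_steps + 1)
        w2 = np.empty(n_steps + 1)
        vs = np.empty(n_steps + 1)
        w1[0], w2[0] = float(w0[0]), float(w0[1])
        for t in range(n_steps):
            v = float(v_source(u1, u2, w1[t], w2[t]))
            vs[t] = v
            w1[t + 1] = np.clip(w1[t] + dt * float(law(u1, v, w1[t])), 0.0, 1.0)
            w2[t + 1] = np.clip(w2[t] + dt * float(law(u2, v, w2[t])), 0.0, 1.0)
        vs[-1] = vs[-2] if n_steps else np.nan
        return RateTrajectory(times, w1, w2=w2, v=vs,
                              estimator=str([str(f) for f in estimator.features]),
                              v_source="lookup")

    u = float(u)
    w = np.empty(n_steps + 1)
    vs = np.empty(n_steps + 1)
    w[0] = float(w0)
    preset = not callable(v_source)
    if preset and v_source is None:
        raise ValueError("v_source is required")
    for t in range(n_steps):
        v = float(v_source) if preset else float(np.asarray(v_source(u, w[t])))
        vs[t] = v
        w[t + 1] = np.clip(w[t] + dt * float(law(u, v, w[t])), 0.0, 1.0)
    vs[-1] = vs[-2] if n_steps else np.nan
    return RateTrajectory(times, w, v=vs,
                          estimator=str([str(f) for f in estimator.features]),
                          v_source="preset" if preset else "lookup")


@dataclass
class DivergenceReport:
    """Gap statistics between a rate trajectory and a spiking ensemble."""

    final_gap: float
    max_gap: float
    within_band: bool       # endpoint inside ensemble mean +/- 2 sd
    ensemble_mean_final: float
    ensemble_sd_final: float


def compare_to_spiking(
    rate_traj: RateTrajectory,
    spiking_traces: list[TrialTrace],
    population: int = 1,
) -> DivergenceReport:
    """Compare a compact-model trajectory with matched spike-level trials.

    All spiking traces must share one grid point; the rate trajectory is
    linearly interpolated onto the spiking time base over the overlapping
    horizon.
    """
    if not spiking_traces:
        raise ValueError("no spiking traces given")
    points = {t.point for t in spiking_traces}
    if len(points) != 1:
        raise ValueError(f"spiking traces mix conditions: {sorted(points)}")
    traces = np.stack([
        (t.w_bar2 if population == 2 else t.w_bar) for t in spiking_traces])
    t_spike = spiking_traces[0].times
    horizon = min(t_spike[-1], rate_traj.times[-1])
    sel = t_spike <= horizon + 1e-12
    t_common = t_spike[sel]
    ens = traces[:, sel]
    w_rate = np.interp(t_common,
                       rate_traj.times,
                       rate_traj.w2 if population == 2 else rate_traj.w)
    mean = ens.mean(axis=0)
    sd = ens.std(axis=0, ddof=1) if ens.shape[0] > 1 else np.zeros_like(mean)
    gaps = np.abs(w_rate - mean)
    return DivergenceReport(
        final_gap=float(gaps[-1]),
        max_gap=float(gaps.max()),
        within_band=bool(gaps[-1] <= 2.0 * sd[-1] + 1e-9),
        ensemble_mean_final=float(mean[-1]),
        ensemble_sd_final=float(sd[-1]),
    )
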