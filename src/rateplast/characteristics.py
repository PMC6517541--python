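"""Qualitative characteristics of a rate-based plasticity rule.

A compact rule dw/dt = f(u, v, w) is judged against nine qualitative
properties of calcium-based plasticity observed in the spike-level
simulations: dominance of potentiation at low weights (LTP Area), growing
depression between the LTP region and the equilibrium weight (LTD
Increase), dominance of depression above the equilibrium (LTD Area),
negligible change at low rates (Invariability), a convex-to-concave switch
with increasing activity (Curvilinearity), rate-independence at high
activity (Saturation), the characteristic weight dependence per motif
(w-Behavior), and — for the two-population motif only — Competition and
Steadiness.

The source characteristics are verbal; the numeric operationalizations here
(grid coverage fractions, relative-magnitude thresholds) are calibrated
reconstructions, exposed through :class:`CharacteristicThresholds` and
recorded in every report.  Verdicts are booleans; Competition and
Steadiness are ``None`` (undefined) outside P3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CharacteristicThresholds",
    "CharacteristicReport",
    "EquilibriumInfo",
    "CHARACTERISTIC_NAMES",
    "equilibrium_weight",
    "evaluate_characteristics",
]

CHARACTERISTIC_NAMES = (
    "ltp_area", "ltd_increase", "ltd_area", "invariability",
    "saturation", "curvilinearity", "w_behavior", "competition", "steadiness",
)


@dataclass(frozen=True)
class CharacteristicThresholds:
    """Numeric thresholds behind the boolean verdicts (all configurable)."""

    ltp_w_max: float = 0.3          # weights counted as "low"
    ltp_fraction: float = 0.95      # fraction of active grid that must be LTP
    low_rate: float = 10.0          # Hz; boundary of the low-activity region
    invariability_fraction: float = 0.05
    saturation_band: tuple[float, float] = (80.0, 100.0)
    saturation_fraction: float = 0.10
    linear_r2: float = 0.95         # P1 w-linearity per slice
    majority: float = 0.5
    competition_u1: float = 5.0
    competition_w1: float = 0.9
    competition_w2: float = 0.6
    competition_u2_range: tuple[float, float] = (60.0, 100.0)
    steadiness_fraction: float = 0.10


@dataclass(frozen=True)
class EquilibriumInfo:
    """Root of dw/dt in w at fixed rates; ``w_star`` is None if no root."""

    u: float
    v: float
    w_star: float | None


@dataclass
class CharacteristicReport:
    """Boolean verdicts for one rule on one motif and evaluation grid."""

    motif: str
    verdicts: dict[str, bool | None]
    thresholds: CharacteristicThresholds
    grid: dict[str, list[float]] = field(default_factory=dict)
    note: str = "thresholds are calibrated reconstructions of verbal criteria"

    def __getitem__(self, name: str) -> bool | None:
        return self.verdicts[name]

    def to_json(self, path) -> None:
        payload = {
            "motif": self.motif,
            "verdicts": self.verdicts,
            "thresholds": asdict(self.thresholds),
            "note": self.note,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def as_table(self) -> str:
        mark = {True: "yes", False: "no", None: "-"}
        lines = [f"characteristic      {self.motif}", "-" * 24]
        for name in CHARACTERISTIC_NAMES:
            lines.append(f"{name:<19s} {mark[self.verdicts.get(name)]}")
        return "\n".join(lines)


def _evaluate_grid(rate_law, u_grid, v_grid, w_grid) -> np.ndarray:
    uu, vv, ww = np.meshgrid(u_grid, v_grid, w_grid, indexing="ij")
    vals = np.asarray(rate_law(uu, vv, ww), dtype=float)
    if vals.shape != uu.shape:
        vals = np.broadcast_to(vals, uu.shape).copy()
    if not np.all(np.isfinite(vals)):
        raise ValueError("rate law produced non-finite values on the grid")
    return vals


def equilibrium_weight(
    rate_law: Callable,
    u: float,
    v: float,
    tol: float = 1e-10,
    n_scan: int = 201,
) -> EquilibriumInfo:
    """Equilibrium weight w* with f(u, v, w*) = 0, by bracketed root find.

    Scans w in [0, 1] for the first downward (+ to -) sign crossing and
    refines it with Brent's method.  ``w* = 0`` is reported when the rule
    vanishes at w = 0 and is negative beyond; no crossing yields
    ``w_star=None`` (not an error).
    """
    w = np.linspace(0.0, 1.0, n_scan)
    f = np.asarray(rate_law(np.full_like(w, u), np.full_like(w, v), w), float)
    for k in range(n_scan - 1):
        if f[k] >= 0 > f[k + 1]:
            if f[k] == 0.0:
                return EquilibriumInfo(u, v, float(w[k]))
            root = brentq(lambda x: float(rate_law(u, v, x)),
                          w[k], w[k + 1], xtol=tol)
            return EquilibriumInfo(u, v, float(root))
    return EquilibriumInfo(u, v, None)


def _grid_equilibrium_index(f_w: np.ndarray) -> int | None:
    """Index k of the grid interval containing the first + to - crossing."""
    for k in range(f_w.size - 1):
        if f_w[k] >= 0 > f_w[k + 1]:
            return k
    return None


def _interp_root(w_grid: np.ndarray, f_w: np.ndarray, k: int) -> float:
    if f_w[k] == 0.0:
        return float(w_grid[k])
    frac = f_w[k] / (f_w[k] - f_w[k + 1])
    return float(w_grid[k] + frac * (w_grid[k + 1] - w_grid[k]))


def evaluate_characteristics(
    rate_law: Callable,
    motif: str,
    u_grid: np.ndarray | None = None,
    v_grid: np.ndarray | None = None,
    w_grid: np.ndarray | None = None,
    thresholds: CharacteristicThresholds | None = None,
    v_of: Callable | None = None,
) -> CharacteristicReport:
    """Apply the nine qualitative tests to a rate law on a dense grid.

    ``rate_law(u, v, w)`` must broadcast over arrays.  For P3 the
    Competition and Steadiness checks additionally need the postsynaptic
    response model ``v_of(u1, u2, w1, w2)`` (e.g. a neuron rate lookup);
    without it those verdicts cannot be computed.
    """
    th = thresholds or CharacteristicThresholds()
    u_grid = np.arange(0.0, 101.0) if u_grid is None else np.asarray(u_grid, float)
    v_grid = np.arange(0.0, 101.0) if v_grid is None else np.asarray(v_grid, float)
    w_grid = (np.round(np.arange(0.0, 1.0001, 0.05), 10) if w_grid is None
              else np.asarray(w_grid, float))
    f = _evaluate_grid(rate_law, u_grid, v_grid, w_grid)
    scale = np.abs(f).max()
    eps = 1e-12 * max(scale, 1.0)

    active_u = u_grid >= th.low_rate
    active_v = v_grid >= th.low_rate
    low_u = u_grid < th.low_rate
    low_v = v_grid < th.low_rate
    verdicts: dict[str, bool | None] = {}

    # 1. LTP Area: potentiation dominates at low weights for active rates.
    low_w = w_grid <= th.ltp_w_max
    block = f[np.ix_(active_u, active_v, low_w)]
    verdicts["ltp_area"] = bool(
        ((block > 0).mean(axis=(0, 1)) >= th.ltp_fraction).all())

    # Equilibria per active (u, v) pair, from the grid sign structure.
    eq_idx: dict[tuple[int, int], float] = {}
    for iu in range(u_grid.size):
        for iv in range(v_grid.size):
            k = _grid_equilibrium_index(f[iu, iv])
            if k is not None:
                eq_idx[(iu, iv)] = _interp_root(w_grid, f[iu, iv], k)

    # 2. LTD Increase: between the LTP region and w*, dw/dt falls with w.
    ok = True
    for (iu, iv), w_star in eq_idx.items():
        if not (active_u[iu] and active_v[iv]):
            continue
        inside = (w_grid > th.ltp_w_max) & (w_grid < w_star)
        vals = f[iu, iv, inside]
        if vals.size >= 2 and not np.all(np.diff(vals) < 0):
            ok = False
            break
    verdicts["ltd_increase"] = ok

    # 3. LTD Area: depression dominates above the equilibrium weight.
    ok = True
    for (iu, iv), w_star in eq_idx.items():
        beyond = w_grid > w_star
        if np.any(f[iu, iv, beyond] >= 0):
            ok = False
            break
    verdicts["ltd_area"] = ok

    # 4. Invariability: negligible change when both rates are low.
    low_block = np.abs(f[np.ix_(low_u, low_v)])
    low_max = low_block.max() if low_block.size else 0.0
    verdicts["invariability"] = bool(low_max <= th.invariability_fraction * scale)

    # 5. Saturation: rate-independence at high activity, along u and v.
    def _saturates(axis: int, grid: np.ndarray) -> bool:
        d = np.abs(np.diff(f, axis=axis))
        mid = 0.5 * (grid[:-1] + grid[1:])
        band = (mid >= th.saturation_band[0]) & (mid <= th.saturation_band[1])
        d_band = np.compress(band, d, axis=axis)
        if d.max() == 0:
            return True
        return d_band.max() <= th.saturation_fraction * d.max()

    verdicts["saturation"] = bool(_saturates(0, u_grid) and _saturates(1, v_grid))

    # 6. Curvilinearity: convex-to-concave switch along u above low_rate.
    d2 = np.diff(f, n=2, axis=0)
    mid_u = u_grid[1:-1]
    sel = mid_u > th.low_rate
    d2 = d2[sel]
    n_switch = 0
    n_slices = d2.shape[1] * d2.shape[2]
    for iv in range(d2.shape[1]):
        for iw in range(d2.shape[2]):
            s = d2[:, iv, iw]
            seen_pos = False
            for val in s:
                if val > eps:
                    seen_pos = True
                elif val < -eps and seen_pos:
                    n_switch += 1
                    break
    verdicts["curvilinearity"] = bool(n_switch > th.majority * n_slices)

    # 7. w-Behavior: near-linear in w for P1; single-peaked in w for P2/P3.
    n_slices = u_grid.size * v_grid.size
    n_pass = 0
    if motif == "P1":
        wc = w_grid - w_grid.mean()
        denom = np.sum(wc ** 2)
        for iu in range(u_grid.size):
            for iv in range(v_grid.size):
                y = f[iu, iv]
                yc = y - y.mean()
                ss_tot = np.sum(yc ** 2)
                if ss_tot <= eps ** 2:
                    n_pass += 1    # constant slice is trivially linear
                    continue
                slope = np.sum(wc * yc) / denom
                ss_res = np.sum((yc - slope * wc) ** 2)
                if 1.0 - ss_res / ss_tot >= th.linear_r2:
                    n_pass += 1
    else:
        for iu in range(u_grid.size):
            for iv in range(v_grid.size):
                d = np.diff(f[iu, iv])
                gone_down = False
                unimodal = True
                for val in d:
                    if val < -eps:
                        gone_down = True
                    elif val > eps and gone_down:
                        unimodal = False
                        break
                if unimodal:
                    n_pass += 1
    verdicts["w_behavior"] = bool(n_pass > th.majority * n_slices)

    # 8./9. Competition and Steadiness: P3 only, need the response model.
    if motif != "P3":
        verdicts["competition"] = None
        verdicts["steadiness"] = None
    else:
        if v_of is None:
            raise ValueError("P3 characteristics require a v_of(u1,u2,w1,w2) model")
        u2_lo, u2_hi = th.competition_u2_range
        u2_vals = np.arange(u2_lo, u2_hi + 1e-9, 5.0)
        u1c, w1c, w2c = th.competition_u1, th.competition_w1, th.competition_w2
        vals = np.array([
            float(rate_law(u1c, v_of(u1c, u2, w1c, w2c), w1c))
            for u2 in u2_vals
        ])
        verdicts["competition"] = bool(
            vals[0] >= 0 and vals[-1] < 0 and np.all(np.diff(vals) < 0))

        # |d(dw/dt)/du1| at saturated far-population activity vs none.
        du1 = np.diff(u_grid).mean()

        def _du1_max(u2: float) -> float:
            best = 0.0
            for w1 in w_grid:
                g = np.array([
                    float(rate_law(u1, v_of(u1, u2, w1, w2c), w1))
                    for u1 in u_grid
                ])
                best = max(best, np.abs(np.diff(g)).max() / du1)
            return best

        hi = _du1_max(u2_hi)
        lo = _du1_max(0.0)
        verdicts["steadiness"] = bool(lo > 0 and hi <= th.steadiness_fraction * lo)

    return CharacteristicReport(
        motif=motif,
        verdicts=verdicts,
        thresholds=th,
        grid={"u": u_grid.tolist(), "v": v_grid.tolist(), "w": w_grid.tolist()},
    )
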