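"""Transform weight trajectories into rate-based derivative observations.

Each spike-level trial produces a noisy population-mean weight trajectory
``wbar(t)`` over the trial horizon.  The rate-based observation for a grid
point is the initial time derivative of that trajectory: a smoothing spline
regularizes the trace and its derivative is read off at t = 0, eliminating
the explicit time dependence while the weight dependence is scanned through
the grid of initial weights.  Derivatives from the Z independent
initializations of the same grid point are averaged, and their sample
variance provides the weight for the subsequent regression.

The smoothing spline is scipy's ``UnivariateSpline`` with degree ``k`` and
smoothing factor ``s`` (the bound on the summed squared residuals; knots are
inserted until the bound holds).  The defaults k = 1, s = 0.1 mean that a
trace whose fluctuation around a straight line is small keeps a single
linear segment, while strongly curved (saturating) traces receive interior
knots so that the t = 0 slope remains local.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .setups import TrialTrace

__all__ = [
    "RateSample",
    "RateDataset",
    "smooth_and_differentiate",
    "aggregate_inits",
    "build_dataset",
]

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHING = 0.1
DEFAULT_DEGREE = 1


@dataclass(frozen=True)
class RateSample:
    """One rate-based observation: (u, v, w0) -> mean derivative at t = 0.

    ``w_dot`` is in 1/s; ``var_w_dot`` is the unbiased sample variance of
    the per-initialization derivatives (before any flooring).
    """

    u: float
    v: float
    w0: float
    w_dot: float
    var_w_dot: float
    n_inits: int
    motif: str = "P1"
    population: int = 1


@dataclass
class RateDataset:
    """All rate samples of one motif (and population, for P3)."""

    samples: list[RateSample]
    motif: str = "P1"
    population: int = 1

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": [s.motif for s in self.samples],
                "population": [s.population for s in self.samples],
                "u": [s.u for s in self.samples],
                "v": [s.v for s in self.samples],
                "w0": [s.w0 for s in self.samples],
                "w_dot": [s.w_dot for s in self.samples],
                "var": [s.var_w_dot for s in self.samples],
                "n_inits": [s.n_inits for s in self.samples],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RateDataset":
        samples = [
            RateSample(u=row.u, v=row.v, w0=row.w0, w_dot=row.w_dot,
                       var_w_dot=row.var, n_inits=int(row.n_inits),
                       motif=row.motif, population=int(row.population))
            for row in frame.itertuples()
        ]
        motif = frame["motif"].iloc[0] if len(frame) else "P1"
        pop = int(frame["population"].iloc[0]) if len(frame) else 1
        return cls(samples, motif=motif, population=pop)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateDataset":
        return cls.from_frame(pd.read_csv(path))

    # array views used by the regression
    @property
    def uvw(self) -> np.ndarray:
        return np.array([(s.u, s.v, s.w0) for s in self.samples])

    @property
    def w_dot(self) -> np.ndarray:
        return np.array([s.w_dot for s in self.samples])

    def weights(self, variance_floor: float | None = None) -> np.ndarray:
        """Regression weights 1/var with degenerate variances floored.

        Samples whose variance is non-positive (or based on fewer than two
        initializations) cannot carry an infinite weight; they are assigned
        the dataset's median positive variance (or ``variance_floor``).
        """
        var = np.array([s.var_w_dot for s in self.samples], dtype=float)
        n = np.array([s.n_inits for s in self.samples])
        bad = (var <= 0) | (n < 2)
        scale = np.median(var[~bad]) if (~bad).any() else 1.0
        # variances indistinguishable from floating-point noise (e.g. the
        # silent u = v = 0 grid point) would otherwise dominate the fit
        bad |= var < 1e-9 * scale
        if bad.any():
            if variance_floor is None:
                positive = var[~bad]
                variance_floor = float(np.median(positive)) if positive.size else 1.0
            var = np.where(bad, variance_floor, var)
        return 1.0 / var


def smooth_and_differentiate(
    w_bar: np.ndarray,
    dt: float,
    smoothing: float = DEFAULT_SMOOTHING,
    degree: int = DEFAULT_DEGREE,
) -> float:
    """Initial derivative (1/s) of a weight trace via a smoothing spline.

    ``dt`` is the sample spacing in seconds.  The spline degree defaults to
    1 (the published fitting procedure); degree 3 gives conventional cubic
    smoothing splines and is available through ``degree``.
    """
    w_bar = np.asarray(w_bar, dtype=float)
    if w_bar.size < 3:
        raise ValueError("trace must contain at least 3 samples")
    if not np.all(np.isfinite(w_bar)):
        raise ValueError("trace contains non-finite values")
    t = np.arange(w_bar.size) * dt
    spline = UnivariateSpline(t, w_bar, k=degree, s=smoothing)
    return float(spline.derivative()(0.0))


def aggregate_inits(derivatives: Iterable[float]) -> tuple[float, float]:
    """Mean and unbiased sample variance over initializations."""
    arr = np.asarray(list(derivatives), dtype=float)
    if arr.size == 0:
        raise ValueError("no derivatives to aggregate")
    mean = float(arr.mean())
    var = float(arr.var(ddof=1)) if arr.size > 1 else 0.0
    return mean, var


class _PointAccumulator:
    """Streaming Welford accumulator for one grid point."""

    __slots__ = ("n", "mean", "m2", "v_sum")

    def __init__(self) -> None:
        self.n = 0
        self.mean = 0.0
        self.m2 = 0.0
        self.v_sum = 0.0

    def add(self, deriv: float, v: float) -> None:
        self.n += 1
        delta = deriv - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (deriv - self.mean)
        self.v_sum += v

    @property
    def variance(self) -> float:
        return self.m2 / (self.n - 1) if self.n > 1 else 0.0

    @property
    def v_mean(self) -> float:
        return self.v_sum / self.n


def build_dataset(
    traces: Iterable[TrialTrace],
    motif: str,
    population: int = 1,
    smoothing: float = DEFAULT_SMOOTHING,
    degree: int = DEFAULT_DEGREE,
    expected_inits: int | None = None,
) -> RateDataset:
    """Consume a sweep (lazily) and build one rate sample per grid point.

    For P1 the postsynaptic rate is the preset grid value; for P2/P3 it is
    the across-initialization mean of the measured rates.  For P3 the
    population-1 trace is used by default (``population=2`` selects the
    second population, keyed by u2/w2).
    """
    acc: dict[tuple[float, ...], _PointAccumulator] = {}
    for trace in traces:
        if trace.motif != motif:
            raise ValueError(f"trace motif {trace.motif} != dataset motif {motif}")
        if motif == "P3" and population == 2:
            if trace.w_bar2 is None:
                raise ValueError("P3 trace lacks a population-2 trajectory")
            wbar = trace.w_bar2
        else:
            wbar = trace.w_bar
        # each grid point stays a distinct sample (P3: full 4-tuple, so that
        # different far-population conditions keep their own measured v)
        key = tuple(trace.point)
        deriv = smooth_and_differentiate(wbar, trace.dt * 1e-3,
                                         smoothing=smoothing, degree=degree)
        acc.setdefault(key, _PointAccumulator()).add(deriv, trace.v_measured)

    samples = []
    for key, a in acc.items():
        if expected_inits is not None and a.n < expected_inits:
            logger.warning("grid point %s has %d/%d initializations",
                           key, a.n, expected_inits)
        if motif == "P1":
            u, v, w0 = key
        elif motif == "P2":
            u, w0 = key
            v = a.v_mean
        else:
            u1, u2, w1, w2 = key
            u, w0 = (u2, w2) if population == 2 else (u1, w1)
            v = a.v_mean
        samples.append(RateSample(u=u, v=v, w0=w0, w_dot=a.mean,
                                  var_w_dot=a.variance, n_inits=a.n,
                                  motif=motif, population=population))
    return RateDataset(samples, motif=motif, population=population)
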