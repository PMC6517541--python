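"""Sparse polynomial regression of the rate-based plasticity data.

The learning rule is modelled as a truncated Taylor expansion in the
presynaptic rate u, postsynaptic rate v and weight w,

    dw/dt = sum_{a,b,g in {0,1,2}} c_abg * u^a v^b w^g,

restricted to the 27 monomial features with per-variable order at most two
(the order reached by the classical Hebb, Oja and BCM rate rules).  Fitting
is variance-weighted linear least squares; model accuracy is the pooled
weighted coefficient of determination from seeded 5-fold cross-validation,
adjusted for the number of features.  Subset search finds the best small
feature combination (exhaustive up to four features, forward selection
beyond), and a unified fit pools several motifs' datasets under a combined
accuracy score RU^2 = mean(per-setup R^2) - std(per-setup R^2).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.linalg import qr
from sklearn.model_selection import KFold

from .rate_transform import RateDataset

__all__ = [
    "Feature",
    "Estimator",
    "SearchResult",
    "all_features",
    "design_matrix",
    "wls_fit",
    "weighted_r2",
    "cv_adjusted_r2",
    "subset_search",
    "unified_fit_and_score",
    "ru2_score",
    "feature_occurrence_table",
    "feature_exclusion_experiment",
]


@dataclass(frozen=True, order=True)
class Feature:
    """Monomial feature u^alpha v^beta w^gamma with exponents in {0, 1, 2}."""

    alpha: int
    beta: int
    gamma: int

    def __post_init__(self) -> None:
        for e in (self.alpha, self.beta, self.gamma):
            if e not in (0, 1, 2):
                raise ValueError("feature exponents must be 0, 1 or 2")

    def __str__(self) -> str:
        parts = []
        for sym, e in (("u", self.alpha), ("v", self.beta), ("w", self.gamma)):
            if e == 1:
                parts.append(sym)
            elif e == 2:
                parts.append(f"{sym}^2")
        return " ".join(parts) if parts else "1"

    def evaluate(self, u, v, w) -> np.ndarray:
        u, v, w = np.asarray(u, float), np.asarray(v, float), np.asarray(w, float)
        return u ** self.alpha * v ** self.beta * w ** self.gamma


def all_features() -> list[Feature]:
    """The 27 features, ordered by total degree then u-major precedence."""
    feats = [Feature(a, b, g) for a, b, g in itertools.product((0, 1, 2), repeat=3)]
    feats.sort(key=lambda f: (f.alpha + f.beta + f.gamma,
                              -f.alpha, -f.beta, -f.gamma))
    return feats


@dataclass
class Estimator:
    """A fitted rate law: features, coefficients and accuracy."""

    features: list[Feature]
    coef: np.ndarray
    se: np.ndarray | None = None
    r2: float | None = None
    fitted_on: tuple[str, ...] = ()
    strategy: str = "direct"

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.size != len(self.features):
            raise ValueError("coefficient count must equal feature count")

    def predict(self, u, v, w) -> np.ndarray:
        cols = [f.evaluate(u, v, w) for f in self.features]
        return sum(c * col for c, col in zip(self.coef, cols))

    def rate_law(self):
        """The fitted dw/dt as a plain callable f(u, v, w)."""
        return self.predict

    def to_dict(self) -> dict:
        return {
            "features": [[f.alpha, f.beta, f.gamma] for f in self.features],
            "feature_names": [str(f) for f in self.features],
            "coef": self.coef.tolist(),
            "se": None if self.se is None else np.asarray(self.se).tolist(),
            "r2": self.r2,
            "fitted_on": list(self.fitted_on),
            "strategy": self.strategy,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "Estimator":
        return cls(
            features=[Feature(*t) for t in d["features"]],
            coef=np.array(d["coef"], dtype=float),
            se=None if d.get("se") is None else np.array(d["se"], dtype=float),
            r2=d.get("r2"),
            fitted_on=tuple(d.get("fitted_on", ())),
            strategy=d.get("strategy", "direct"),
        )


def design_matrix(
    dataset: RateDataset,
    features: list[Feature],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observation matrix, response and regression weights for one dataset."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    uvw = dataset.uvw
    u, v, w = uvw[:, 0], uvw[:, 1], uvw[:, 2]
    x = np.column_stack([f.evaluate(u, v, w) for f in features])
    return x, dataset.w_dot, dataset.weights()


def wls_fit(
    matrix: np.ndarray,
    response: np.ndarray,
    weights: np.ndarray,
    features: list[Feature] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares; returns coefficients and standard errors.

    There is no implicit intercept: a constant enters only through the
    explicit all-zero-exponent feature.  Raises on rank deficiency, naming
    the dependent columns when feature metadata is available.
    """
    matrix = np.asarray(matrix, float)
    xw = matrix * np.sqrt(np.asarray(weights, float))[:, None]
    rank = np.linalg.matrix_rank(xw)
    if rank < matrix.shape[1]:
        _, _, piv = qr(xw, pivoting=True)
        bad = sorted(piv[rank:])
        names = ([str(features[i]) for i in bad] if features is not None
                 else [str(i) for i in bad])
        raise np.linalg.LinAlgError(
            f"collinear features in design matrix: {', '.join(names)}")
    fit = sm.WLS(response, matrix, weights=weights).fit()
    return np.asarray(fit.params), np.asarray(fit.bse)


def weighted_r2(y: np.ndarray, y_hat: np.ndarray, weights: np.ndarray) -> float:
    """Weighted coefficient of determination around the weighted mean."""
    y, y_hat, w = (np.asarray(a, float) for a in (y, y_hat, weights))
    ybar = np.average(y, weights=w)
    ss_res = np.sum(w * (y - y_hat) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _adjust_r2(r2: float, n: int, n_features: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_features - 1)


def _cv_predictions(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, k_folds: int, seed: int,
) -> np.ndarray:
    """Held-out predictions from seeded k-fold CV with per-fold WLS fits."""
    n = y.size
    y_hat = np.empty(n)
    sw = np.sqrt(w)
    splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in splitter.split(x):
        coef, *_ = np.linalg.lstsq(x[train] * sw[train, None],
                                   y[train] * sw[train], rcond=None)
        y_hat[test] = x[test] @ coef
    return y_hat


def cv_adjusted_r2(
    dataset: RateDataset,
    features: list[Feature],
    k_folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated, feature-count-adjusted weighted R^2 of one basis."""
    x, y, w = design_matrix(dataset, features)
    n = y.size
    if n <= len(features) + k_folds:
        raise ValueError("dataset too small for this basis and fold count")
    y_hat = _cv_predictions(x, y, w, k_folds, seed)
    return _adjust_r2(weighted_r2(y, y_hat, w), n, len(features))


@dataclass
class SearchResult:
    """Best estimator per feature count plus the accuracy curve."""

    best: dict[int, Estimator]

    @property
    def accuracy_curve(self) -> dict[int, float]:
        return {f: est.r2 for f, est in self.best.items()}


def _fit_estimator(dataset: RateDataset, features: list[Feature],
                   r2: float, strategy: str) -> Estimator:
    x, y, w = design_matrix(dataset, features)
    coef, se = wls_fit(x, y, w, features)
    return Estimator(features=list(features), coef=coef, se=se, r2=r2,
                     fitted_on=(dataset.motif,), strategy=strategy)


def subset_search(
    dataset: RateDataset,
    n_features: int,
    k_folds: int = 5,
    seed: int = 0,
    candidate_features: list[Feature] | None = None,
    exhaustive_limit: int = 4,
) -> Estimator:
    """Best feature subset of a given size by cross-validated accuracy.

    Exhaustive over all combinations up to ``exhaustive_limit`` features;
    beyond that, forward selection starting from the best exhaustive subset
    (a documented approximation — the search space is otherwise
    combinatorial).  The returned estimator is refit on the full dataset.
    """
    pool = candidate_features if candidate_features is not None else all_features()
    if not 1 <= n_features <= len(pool):
        raise ValueError("n_features out of range for the candidate pool")
    x_full, y, w = design_matrix(dataset, pool)
    n = y.size
    if n <= n_features + k_folds:
        raise ValueError("dataset too small for this subset size")

    def score(cols: tuple[int, ...]) -> float:
        y_hat = _cv_predictions(x_full[:, cols], y, w, k_folds, seed)
        return _adjust_r2(weighted_r2(y, y_hat, w), n, len(cols))

    if n_features <= exhaustive_limit:
        best_cols, best_r2 = None, -np.inf
        for cols in itertools.combinations(range(len(pool)), n_features):
            r2 = score(cols)
            if r2 > best_r2:
                best_cols, best_r2 = cols, r2
        strategy = "exhaustive"
    else:
        cols_list = list(range(len(pool)))
        best_cols, best_r2 = None, -np.inf
        for cols in itertools.combinations(cols_list, exhaustive_limit):
            r2 = score(cols)
            if r2 > best_r2:
                best_cols, best_r2 = cols, r2
        current = list(best_cols)
        while len(current) < n_features:
            cand_best, cand_r2 = None, -np.inf
            for j in cols_list:
                if j in current:
                    continue
                r2 = score(tuple(current + [j]))
                if r2 > cand_r2:
                    cand_best, cand_r2 = j, r2
            current.append(cand_best)
            best_r2 = cand_r2
        best_cols = tuple(current)
        strategy = f"forward-from-best-{exhaustive_limit}"

    feats = [pool[i] for i in best_cols]
    return _fit_estimator(dataset, feats, best_r2, strategy)


def ru2_score(per_setup_r2) -> float:
    """Unified accuracy: mean of per-setup R^2 minus their population std."""
    vals = np.asarray(list(per_setup_r2), dtype=float)
    return float(vals.mean() - vals.std(ddof=0))


def unified_fit_and_score(
    datasets: dict[str, RateDataset],
    features: list[Feature],
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[Estimator, float, dict[str, float]]:
    """One coefficient vector across several motifs, scored by RU^2.

    Each dataset's weights are normalized to unit total so that no motif
    dominates by sample count or variance scale; cross-validation folds are
    drawn over the pooled samples.  Per-setup R^2 values are computed from
    each setup's own held-out predictions with its own weights and combined
    as mean minus population standard deviation.
    """
    if len(datasets) < 2:
        raise ValueError("unified fit needs at least two datasets")
    xs, ys, ws, owners = [], [], [], []
    for name, ds in datasets.items():
        x, y, w = design_matrix(ds, features)
        xs.append(x)
        ys.append(y)
        ws.append(w / w.sum())
        owners.extend([name] * y.size)
    x = np.vstack(xs)
    y = np.concatenate(ys)
    w = np.concatenate(ws)
    owners = np.array(owners)

    y_hat = _cv_predictions(x, y, w, k_folds, seed)
    per_setup = {}
    for name in datasets:
        mask = owners == name
        r2 = weighted_r2(y[mask], y_hat[mask], w[mask])
        per_setup[name] = _adjust_r2(r2, int(mask.sum()), len(features))
    ru2 = ru2_score(per_setup.values())

    coef, se = wls_fit(x, y, w, features)
    est = Estimator(features=list(features), coef=coef, se=se, r2=ru2,
                    fitted_on=tuple(datasets), strategy="unified")
    return est, ru2, per_setup


def feature_occurrence_table(
    search_results: dict[str, SearchResult],
) -> dict[str, dict[str, int]]:
    """Occurrence count of each feature in the best estimators per condition.

    For each condition (motif/model combination) the best estimators for
    feature counts 3..10 are inspected; each feature's count is the number
    of those estimators (0-8) containing it.
    """
    table: dict[str, dict[str, int]] = {}
    names = [str(f) for f in all_features()]
    for condition, result in search_results.items():
        counts = dict.fromkeys(names, 0)
        for est in result.best.values():
            for f in est.features:
                counts[str(f)] += 1
        table[condition] = counts
    return table


def feature_exclusion_experiment(
    dataset: RateDataset,
    exclusion,
    f_values=range(3, 11),
    k_folds: int = 5,
    seed: int = 0,
    exhaustive_limit: int = 4,
):
    """Accuracy-vs-feature-count curves with and without excluded features.

    ``exclusion`` is a predicate on :class:`Feature`; features for which it
    returns True are removed from the candidate pool (e.g.
    ``lambda f: f.alpha == 2`` removes every u^2 term).  Returns a mapping
    ``F -> (r2_full, r2_excluded)``.
    """
    full_pool = all_features()
    reduced_pool = [f for f in full_pool if not exclusion(f)]
    curves = {}
    for n_feat in f_values:
        if n_feat > len(reduced_pool):
            raise ValueError("exclusion leaves too few features")
        full = subset_search(dataset, n_feat, k_folds, seed,
                             candidate_features=full_pool,
                             exhaustive_limit=exhaustive_limit)
        reduced = subset_search(dataset, n_feat, k_folds, seed,
                                candidate_features=reduced_pool,
                                exhaustive_limit=exhaustive_limit)
        curves[n_feat] = (full.r2, reduced.r2)
    return curves
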