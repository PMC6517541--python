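"""End-to-end orchestration: simulate -> transform -> fit -> characterize.

Every stage writes plain-text artifacts (CSV for tabular data, JSON for
estimators and reports) into an output directory together with a manifest
recording the configuration hash and master seed, so a rerun with the same
configuration is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .characteristics import evaluate_characteristics
from .config import config_hash, setup_from_preset
from .model_reduction import Estimator, Feature, all_features, subset_search
from .rate_transform import RateDataset, build_dataset
from .setups import SetupConfig, TrialTrace, sweep_grid

__all__ = ["run_pipeline", "traces_to_frame", "frame_to_traces",
           "fit_dataset", "parse_feature_spec"]

logger = logging.getLogger(__name__)


def traces_to_frame(traces) -> pd.DataFrame:
    """Flatten TrialTraces into long-format records (one row per time step)."""
    rows = []
    for tr in traces:
        t = tr.times
        for k in range(t.size):
            row = {"motif": tr.motif, "init": tr.init, "t": t[k],
                   "w_bar": tr.w_bar[k], "v_measured": tr.v_measured}
            for name, val in zip(_point_names(tr.motif), tr.point):
                row[name] = val
            if tr.w_bar2 is not None:
                row["w_bar2"] = tr.w_bar2[k]
            rows.append(row)
    return pd.DataFrame(rows)


def _point_names(motif: str) -> tuple[str, ...]:
    return {"P1": ("u", "v", "w0"), "P2": ("u", "w0"),
            "P3": ("u1", "u2", "w01", "w02")}[motif]


def frame_to_traces(frame: pd.DataFrame) -> list[TrialTrace]:
    motif = frame["motif"].iloc[0]
    names = list(_point_names(motif))
    traces = []
    for key, grp in frame.groupby(names + ["init"], sort=True):
        grp = grp.sort_values("t")
        t = grp["t"].to_numpy()
        dt_ms = float(np.diff(t).mean() * 1e3) if t.size > 1 else 0.5
        traces.append(TrialTrace(
            motif=motif,
            point=tuple(float(k) for k in key[:-1]),
            init=int(key[-1]),
            dt=dt_ms,
            w_bar=grp["w_bar"].to_numpy(),
            w_bar2=grp["w_bar2"].to_numpy() if "w_bar2" in grp else None,
            v_measured=float(grp["v_measured"].iloc[0]),
        ))
    return traces


def parse_feature_spec(spec: str) -> list[Feature]:
    """Parse features like ``"v,vw,uww"`` or ``"010,011,102"`` into Features.

    Each item is either a three-digit exponent triple or a monomial written
    with repeated symbols (``uww`` = u w^2, ``uuv`` = u^2 v).
    """
    feats = []
    for item in spec.split(","):
        item = item.strip()
        if item.isdigit() and len(item) == 3:
            feats.append(Feature(int(item[0]), int(item[1]), int(item[2])))
        else:
            counts = {"u": 0, "v": 0, "w": 0}
            for ch in item:
                if ch == "1" and len(item) == 1:
                    break
                if ch not in counts:
                    raise ValueError(f"cannot parse feature {item!r}")
                counts[ch] += 1
            feats.append(Feature(counts["u"], counts["v"], counts["w"]))
    return feats


def fit_dataset(
    dataset: RateDataset,
    n_features: int | None = None,
    features: list[Feature] | None = None,
    exclude: str = "none",
    k_folds: int = 5,
    seed: int = 0,
) -> Estimator:
    """Fit a rate law: fixed basis if ``features`` given, else subset search."""
    from .model_reduction import cv_adjusted_r2, design_matrix, wls_fit

    if features is not None:
        x, y, w = design_matrix(dataset, features)
        coef, se = wls_fit(x, y, w, features)
        r2 = cv_adjusted_r2(dataset, features, k_folds=k_folds, seed=seed)
        return Estimator(features=features, coef=coef, se=se, r2=r2,
                         fitted_on=(dataset.motif,), strategy="fixed-basis")
    pool = all_features()
    if exclude == "u2":
        pool = [f for f in pool if f.alpha < 2]
    elif exclude == "u":
        pool = [f for f in pool if f.alpha != 1]
    elif exclude != "none":
        raise ValueError(f"unknown exclusion {exclude!r}")
    return subset_search(dataset, n_features or 3, k_folds=k_folds, seed=seed,
                         candidate_features=pool)


def run_pipeline(
    outdir: str | Path,
    motif: str = "P1",
    plasticity_model: str = "lc",
    neuron_model: str | None = None,
    preset: str = "scaled",
    master_seed: int = 0,
    stages: tuple[str, ...] = ("transform", "fit", "characterize"),
    n_features: int | None = None,
    features: list[Feature] | None = None,
    exclude: str = "none",
    write_traces: bool = False,
    setup: SetupConfig | None = None,
) -> dict:
    """Run the staged pipeline, writing artifacts into ``outdir``.

    ``transform`` runs the spike-level sweep and streams it into the
    rate-transform (writing the full trace table only on request — it is
    large); ``fit`` regresses the resulting dataset; ``characterize``
    evaluates the fitted rule's qualitative characteristics.  If a dataset
    CSV already exists in ``outdir`` the transform stage is skipped
    implicitly when not requested.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if setup is None:
        setup = setup_from_preset(motif, plasticity_model, neuron_model,
                                  preset=preset, master_seed=master_seed)
    manifest = {
        "config": dataclasses.asdict(setup),
        "config_hash": config_hash(dataclasses.asdict(setup)),
        "master_seed": master_seed,
        "stages": list(stages),
    }
    dataset_path = outdir / f"dataset_{setup.motif}.csv"
    estimator_path = outdir / "estimator.json"
    artifacts = {"manifest": str(outdir / "manifest.json")}

    if "transform" in stages or "simulate" in stages:
        traces = sweep_grid(setup)
        if write_traces or "simulate" in stages:
            traces = list(traces)
            traces_to_frame(traces).to_csv(outdir / "traces.csv", index=False)
            artifacts["traces"] = str(outdir / "traces.csv")
        if "transform" in stages:
            dataset = build_dataset(traces, setup.motif,
                                    expected_inits=setup.n_inits)
            dataset.to_csv(dataset_path)
            artifacts["dataset"] = str(dataset_path)

    if "fit" in stages:
        if not dataset_path.exists():
            raise FileNotFoundError(f"no dataset at {dataset_path}; "
                                    "run the transform stage first")
        dataset = RateDataset.from_csv(dataset_path)
        est = fit_dataset(dataset, n_features=n_features, features=features,
                          exclude=exclude, seed=master_seed)
        est.to_json(estimator_path)
        artifacts["estimator"] = str(estimator_path)

    if "characterize" in stages:
        if not estimator_path.exists():
            raise FileNotFoundError("no estimator.json; run the fit stage first")
        with open(estimator_path) as fh:
            est = Estimator.from_dict(json.load(fh))
        v_of = None
        if setup.motif == "P3":
            from .compact import build_p3_v_model
            v_of = build_p3_v_model(neuron_model=setup.neuron_model,
                                    seed=master_seed)
        report = evaluate_characteristics(est.predict, setup.motif, v_of=v_of)
        report.to_json(outdir / "characteristics.json")
        artifacts["characteristics"] = str(outdir / "characteristics.json")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump({**manifest, "artifacts": artifacts}, fh, indent=2, default=str)
    return artifacts
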