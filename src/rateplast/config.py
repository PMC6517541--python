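"""Configuration loading: presets file -> parameter objects and setups."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .neurons import AEIFParams, MATParams
from .plasticity import CalciumParams, PlasticityParams
from .setups import SetupConfig

__all__ = [
    "load_presets",
    "plasticity_from_config",
    "calcium_from_config",
    "neuron_from_config",
    "setup_from_preset",
    "config_hash",
]


def load_presets(path: str | Path | None = None) -> dict:
    """Load the packaged presets, or a user-provided YAML override."""
    if path is None:
        text = resources.files("rateplast").joinpath("presets.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    required = ("plasticity", "neuron", "grids", "simulation")
    missing = [k for k in required if k not in cfg]
    if missing:
        raise ValueError(f"config missing keys: {', '.join(missing)}")
    return cfg


def plasticity_from_config(cfg: dict, model: str) -> PlasticityParams:
    d = cfg["plasticity"][model]
    return PlasticityParams(tau=d["tau"], gamma_p=d["gamma_p"],
                            gamma_d=d["gamma_d"], theta_p=d["theta_p"],
                            theta_d=d["theta_d"], sigma=d.get("sigma", 0.0))


def calcium_from_config(cfg: dict, model: str) -> CalciumParams:
    d = cfg["plasticity"][model]
    if model == "nlc":
        return CalciumParams.nonlinear(d["tau_ca"], d["c_pre"], d["c_post"])
    return CalciumParams(d["tau_ca"], d["c_pre"], d["c_post"])


def neuron_from_config(cfg: dict, model: str, motif: str = "P2"):
    d = dict(cfg["neuron"][model])
    alpha = d.pop("alpha_n")[motif.lower()]
    if model == "mat":
        return MATParams(alpha_n=alpha, **d)
    return AEIFParams(alpha_n=alpha, **d)


def _rate_grid(step: float) -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 100.0 + step / 2, step), 10))


def _w_grid(step: float) -> tuple[float, ...]:
    return tuple(np.round(np.arange(0.0, 1.0 + step / 2, step), 10))


def setup_from_preset(
    motif: str,
    plasticity_model: str = "lc",
    neuron_model: str | None = None,
    preset: str = "scaled",
    master_seed: int = 0,
    cfg: dict | None = None,
    **overrides,
) -> SetupConfig:
    """Build a SetupConfig from the packaged grid presets."""
    cfg = cfg or load_presets()
    g = cfg["grids"][preset]
    sim = cfg["simulation"]
    if neuron_model is None:
        neuron_model = "poisson" if motif == "P1" else "mat"
    rate_step = g["p3_rate_step"] if motif == "P3" else g["rate_step"]
    w_step = g["p3_w_step"] if motif == "P3" else g["w_step"]
    kwargs = dict(
        motif=motif,
        plasticity_model=plasticity_model,
        neuron_model=neuron_model,
        n_synapses=g["n_synapses"],
        u_grid=_rate_grid(rate_step),
        v_grid=_rate_grid(rate_step),
        w_grid=_w_grid(w_step),
        n_inits=g["n_inits"][motif],
        t_end=sim["t_end"],
        dt=sim["dt"],
        kappa_ms=cfg.get("drive", {}).get("kappa_ms", 0.5),
        master_seed=master_seed,
    )
    kwargs.update(overrides)
    return SetupConfig(**kwargs)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
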