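import numpy as np
import pytest

from rateplast.model_reduction import Feature
from rateplast.rate_transform import RateDataset, RateSample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(coef_map, noise_sd=0.0, rng=None, motif="P1",
                 u_vals=None, v_vals=None, w_vals=None, var=1.0):
    """Planted-law dataset: w_dot = sum coef * u^a v^b w^g (+ noise)."""
    u_vals = np.arange(0, 101, 20.0) if u_vals is None else np.asarray(u_vals, float)
    v_vals = np.arange(0, 101, 20.0) if v_vals is None else np.asarray(v_vals, float)
    w_vals = np.linspace(0, 1, 5) if w_vals is None else np.asarray(w_vals, float)
    samples = []
    for u in u_vals:
        for v in v_vals:
            for w in w_vals:
                y = sum(c * u ** f.alpha * v ** f.beta * w ** f.gamma
                        for f, c in coef_map.items())
                if noise_sd > 0:
                    y += rng.normal(0.0, noise_sd)
                samples.append(RateSample(u=u, v=v, w0=w, w_dot=float(y),
                                          var_w_dot=var, n_inits=10, motif=motif))
    return RateDataset(samples, motif=motif)


@pytest.fixture
def planted_dataset_factory():
    return make_dataset


@pytest.fixture
def feature_uvw():
    """Commonly used features keyed by short name."""
    return {
        "1": Feature(0, 0, 0), "u": Feature(1, 0, 0), "v": Feature(0, 1, 0),
        "w": Feature(0, 0, 1), "uv": Feature(1, 1, 0), "vw": Feature(0, 1, 1),
        "uw2": Feature(1, 0, 2), "u2": Feature(2, 0, 0), "u2w2": Feature(2, 0, 2),
        "u2w": Feature(2, 0, 1), "uvw": Feature(1, 1, 1),
    }
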