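# rateplast

Compact, firing-rate-dependent synaptic plasticity rules derived from a
detailed calcium-based model of spike-timing-dependent plasticity (STDP).

Detailed plasticity models track individual spikes and postsynaptic calcium
transients; they match slice experiments but are too unwieldy for
network-level analysis.  Classical rate rules (Hebb, Oja, BCM) are
analytically convenient but only loosely tied to biophysics.  `rateplast`
bridges the two: it simulates the calcium-threshold STDP model

  τ ρ̇ᵢ = γ_p (1 − ρᵢ) H(cᵢ − θ_p) − γ_d ρᵢ H(cᵢ − θ_d),

where a synapse potentiates while its calcium trace cᵢ exceeds θ_p and
depresses while it exceeds θ_d, in three neuronal motifs (a Poisson
population onto an independent Poisson postsynaptic train; onto an
adaptive-threshold MAT or adaptive-exponential AEIF model neuron; and two
populations competing for one neuron).  Population-mean weight trajectories
are converted into derivative observations ẇ(u, v, w) by smoothing-spline
differentiation at t = 0, and a sparse polynomial rate law

  ẇ = Σ c_abg · uᵃ vᵇ wᵍ,   a, b, g ∈ {0, 1, 2}

is selected by variance-weighted least squares with cross-validated,
feature-count-adjusted R².  The headline finding this machinery supports is
that the fitted rules lean on the *square* of the presynaptic rate (u²,
u²w), not only on the Hebbian product uv.  Fitted rules can be integrated
forward as ordinary differential equations and compared against the spiking
ground truth, and are scored against nine qualitative characteristics of
calcium-based plasticity (LTP/LTD regimes, low-rate invariability,
saturation, weight dependence, competition, ...).

## Worked example

Fit the three-feature rate law of the first motif on a coarse grid (six
rates × six weights, 100 synapses, 5 initializations — a ~1-minute run):

```python
import numpy as np
from rateplast import SetupConfig, sweep_grid, build_dataset, fit_dataset
from rateplast.pipeline import parse_feature_spec
from rateplast.characteristics import evaluate_characteristics

setup = SetupConfig(
    motif="P1", plasticity_model="lc", n_synapses=100,
    u_grid=tuple(np.arange(0.0, 101, 20)), v_grid=tuple(np.arange(0.0, 101, 20)),
    w_grid=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0), n_inits=5, master_seed=42,
)
dataset = build_dataset(sweep_grid(setup), "P1", expected_inits=5)
est = fit_dataset(dataset, features=parse_feature_spec("v,vw,uww"), seed=42)
for f, c, s in zip(est.features, est.coef, est.se):
    print(f"c[{f}] = {c:+.6f} +/- {s:.6f}")
print(f"5-fold adjusted R^2 = {est.r2:.3f}")
report = evaluate_characteristics(est.predict, "P1")
print({k: v for k, v in report.verdicts.items() if v is not None})
```

prints

```
c[v] = +0.006646 +/- 0.000379
c[v w] = -0.007296 +/- 0.000453
c[u w^2] = -0.001338 +/- 0.000048
5-fold adjusted R^2 = 0.803
{'ltp_area': True, 'ltd_increase': True, 'ltd_area': True,
 'invariability': False, 'saturation': False, 'curvilinearity': False,
 'w_behavior': True}
```

Reading: potentiation grows with the postsynaptic rate (c[v] > 0), is
damped at strong weights (c[vw] < 0), and a weight-dependent depression
term c[uw²] < 0 stabilizes the synapse — the rule potentiates low weights
for almost all co-active rate pairs (LTP area ✓), depresses above its
equilibrium weight (LTD area ✓), and depends near-linearly on w
(w-behavior ✓), but as a polynomial it neither saturates at high rates nor
switches curvature.  `rateplast.rules` ships the published benchmark
coefficient sets for all three motifs and the unified cross-motif rules for
comparison.

A `rateplast` command line wraps the same pipeline
(`rateplast all --motif P1 --preset scaled --seed 1 --out runs/p1`), with
stages `simulate`, `transform`, `fit`, `characterize` and `compare`.

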