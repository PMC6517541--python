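# Methods

`rateplast` derives compact, firing-rate-dependent plasticity rules
dw/dt = f(u, v, w) from a detailed calcium-based model of spike-timing
dependent plasticity, in three stages: spike-level simulation of neuronal
motifs (Step I), transformation of weight trajectories into rate-based
derivative observations (Step II), and sparse polynomial regression with
cross-validated model selection (Step III).

## The detailed synapse model

Each synapse i carries a strength ρ_i ∈ [0, 1] and a calcium trace c_i.
The weight obeys a calcium-threshold rule

    τ dρ_i/dt = γ_p (1 − ρ_i) H(c_i − θ_p) − γ_d ρ_i H(c_i − θ_d) + noise,

with H the Heaviside gate (H(0) = 1 here; equality is measure-zero with
floating-point calcium).  With both gates open the drift has a stable fixed
point ρ* = γ_p/(γ_p + γ_d) ≈ 0.8125 (linear-calcium parameters).  The
optional noise term is activity-gated white noise with amplitude σ; its
Euler–Maruyama increment is σ √(Δt/τ) √(H_p + H_d) η.  **σ defaults to 0**:
the published parameter set does not include a value, so all stochasticity
comes from the spike trains, and every reported result uses σ = 0.  Weights
are hard-clipped to [0, 1] after each step; at σ = 0 the clip is never
active.

Calcium comes in two variants with published parameter columns:

* **LC** (linear): one trace decaying with τ_Ca, incremented by C_pre per
  presynaptic and C_post per postsynaptic spike.
* **NLC** (nonlinear): separate pre- and postsynaptically evoked traces;
  a postsynaptic spike deposits C_post + ξ·c_pre with
  ξ = 2(C_post + C_pre) − C_post·C_pre, reading the presynaptic trace at
  its value before the current step's decay.  Total calcium is the sum.

Within one Euler step (Δt = 0.5 ms) the order of events is: draw
presynaptic spikes → determine the postsynaptic spike → decay calcium and
add this step's spike increments → evaluate the gates → update ρ.  Spikes
at time t therefore influence plasticity at time t.

## Neuronal motifs

* **P1**: N presynaptic Poisson neurons at rate u onto a postsynaptic train
  that is itself an independent Poisson process at preset rate v.
* **P2**: the postsynaptic cell is a model neuron — MAT (leaky integrator,
  adaptive two-timescale threshold, no voltage reset, 2 ms refractoriness)
  or AEIF (exponential spike initiation plus adaptation current, reset to
  E_L) — driven by the weighted presynaptic spikes.
* **P3**: two presynaptic populations with independent rates u₁, u₂ and
  initial weights w₁, w₂ converge on one model neuron.

The synaptic drive adds κ·α(N)·ρ_i mV to the membrane per presynaptic
spike.  α(N) is the published population-size-dependent scale (e.g.
400 mV/s for MAT in P2, for N = 1000 inputs); simulating a smaller
population keeps the total drive fixed by rescaling α with 1000/N.  The
unit bridge κ is not recoverable from the published unit convention; it was
calibrated once against the qualitative benchmark that a P2 (LC + MAT)
population at w(t₀) = 0.6 shows net depression at u = 30 Hz and net
potentiation at u = 60 Hz, and frozen at κ = Δt = 0.5 ms (a spike acts as a
one-step current pulse; at N = 1000 this yields 0.6 → 0.558 at 30 Hz and
0.6 → 0.758 at 60 Hz).  κ = 1 ms fails the same benchmark (potentiation at
both rates).

## Step I — simulation

The full study grid (u, v ∈ {0..100} Hz step 1, w ∈ {0..1} step 0.05,
N = 1000 synapses, Z = 100 initializations, T = 2 s) is far beyond a
single-workstation budget; the shipped `scaled` preset uses rate step 5 Hz,
weight step 0.1, N = 200, Z = 20 (P1) / 10 (P2) / 5 (P3), chosen so a full
P1 sweep completes in roughly ten minutes on one core.  The `full` preset
retains the original grids.  Calcium starts at zero; all synapses start at
the grid point's weight (a degenerate initial distribution — the derivative
estimates are insensitive to spreading the initial weights, which is itself
a regression test).  Per-trial seeds derive deterministically from the
master seed, motif, models, grid point and initialization index.

With σ = 0 the weight update is affine in ρ given the gate sequence, so the
P1 sweep propagates the affine map (A_i, B_i) per synapse instead of ρ:
one calcium simulation per (u, v, z) yields the population-mean trajectory
for *every* initial weight at once.  This is exact (verified against the
direct per-weight kernel to 1e-14) and applies common random numbers across
initial weights — a variance-reduction for the estimated weight dependence.
Trial kernels are numba-compiled and verified step-for-step against pure
numpy reference implementations of the model equations.

For P2/P3 the postsynaptic rate v is measured as the spike count over the
first 500 ms, the same epoch as the t = 0 derivative below.

## Step II — rate transform

The population-mean trajectory w̄(t) of each trial is smoothed by a
`scipy.interpolate.UnivariateSpline` of degree k = 1 with smoothing factor
s = 0.1 (the bound on the summed squared residuals; knots are inserted
until it holds), and the rate observation is the spline derivative at
t = 0.  Degree 1 with s = 0.1 is the published fitting configuration; the
degree is configurable (k = 3 gives conventional cubic smoothing splines).
Derivatives of the Z initializations are averaged; their unbiased sample
variance becomes the regression weight 1/var.  Samples whose variance is
zero, indistinguishable from floating-point noise (below 1e-9 of the median
positive variance — e.g. the silent u = v = 0 point), or based on fewer
than two initializations are floored at the dataset's median positive
variance so no sample carries effectively infinite weight.

Known limitation: on strongly saturating traces (e.g. u = v = 100 Hz from
w₀ = 0.5, where the weight relaxes toward ρ* within ~0.7 s) the first knot
interval of the k = 1, s = 0.1 spline spans several hundred ms, so the
t = 0 slope is systematically attenuated relative to the instantaneous
drift [γ_p(1 − w₀) − γ_d w₀]/τ — by roughly 40% even on noise-free traces.
This attenuation is part of the published estimand (the same smoothing
produced the published coefficients), so it is kept; the simulation core
itself is validated against the gated-ODE closed form at trajectory level
instead.

## Step III — regression and selection

Candidate features are the 27 monomials u^a v^b w^g with a, b, g ∈ {0,1,2}
(the order reached by the Hebb, Oja and BCM rate rules).  Fitting is
weighted least squares without an implicit intercept; accuracy is the
pooled weighted R² of held-out predictions from seeded 5-fold
cross-validation, adjusted as 1 − (1 − R²)(n − 1)/(n − F − 1).  Subset
search is exhaustive up to four features and forward selection from the
best four-feature subset beyond (the published work does not state its
search algorithm; this choice is recorded in the estimator metadata).
Unified fits pool several motifs' datasets with per-dataset weight
normalization; the unified score is RU² = mean(per-setup R²) − population
standard deviation — the population (divide-by-n) convention reproduces the
published summary values 0.620 and 0.967 from the printed per-setup scores.

## Qualitative characteristics

Nine verbal properties of the simulated plasticity surfaces are
operationalized as boolean predicates on a rule f(u, v, w), evaluated on a
dense grid (u, v step 1 Hz, w step 0.05); all thresholds are exposed in
`CharacteristicThresholds` and recorded in each report as calibrated
reconstructions:

1. **LTP Area** — f > 0 at ≥ 95% of (u, v) ∈ [10, 100]² for every w ≤ 0.3.
2. **LTD Increase** — f strictly decreasing in w on (0.3, w*) wherever an
   equilibrium w* exists (u, v ≥ 10 Hz).
3. **LTD Area** — f < 0 for all w > w* wherever w* exists.
4. **Invariability** — max |f| over u, v < 10 Hz ≤ 5% of the grid-wide max.
5. **Saturation** — max |∂f/∂u| over u ∈ [80, 100] ≤ 10% of its grid-wide
   max, and the same along v.  Polynomial rules necessarily fail.
6. **Curvilinearity** — the second difference along u switches from
   positive to negative above 10 Hz in a majority of (v, w) slices.
   Degree-2 polynomials have constant curvature along u and fail.
7. **w-Behavior** — P1: a linear fit of f(w) reaches R² ≥ 0.95 in a
   majority of slices; P2/P3: f(w) is unimodal (a single maximum, boundary
   permitted) in a majority of slices.  A strict "interior maximum" reading
   would misclassify the published P2/P3 rules, which are monotone in w
   with their maximum at w = 0 yet are assessed as passing.
8. **Competition** (P3) — with u₁ = 5 Hz, w₁ = 0.9, the population-1
   derivative starts non-negative at u₂ = 60 Hz, decreases monotonically,
   and is negative by u₂ = 100 Hz.
9. **Steadiness** (P3) — |∂f₁/∂u₁| at u₂ = 100 Hz is ≤ 10% of its value at
   u₂ = 0.

P3 checks need a postsynaptic response model v(u₁, u₂, w₁, w₂); the
package tabulates one from short frozen-weight neuron simulations.  Because
the drive depends on the populations only through the summed weighted input
rate s = u₁w₁ + u₂w₂, a one-dimensional table over s suffices (spike-size
granularity at equal s is negligible at N = 1000).  For P2 a bilinear
(u, w) table is used.

## Compact-model integration

Fitted rules are integrated by explicit Euler (default dt = 10 ms, horizon
200 s for equilibrium comparisons; endpoints are stable to < 1e-3 under dt
halving), with v preset for P1 and read from the response tables for
P2/P3.  Trajectories are compared against matched spike-level ensembles by
endpoint gap, maximal pointwise gap, and whether the endpoint lies within
the ensemble mean ± 2 sd.

## What the scaled-down reproduction does and does not show

The scaled conditions reproduce the published cross-validated accuracies
closely (three-feature P1 R² ≈ 0.82 vs 0.810; 27-feature ≈ 0.98 vs 0.981)
and the qualitative characteristic patterns exactly.  Individual
coefficients of the three-feature rules are reproduced only approximately
(roughly 15–30% for P1), for reasons that appear intrinsic rather than
numerical:

* Inverse-variance weights span six orders of magnitude; over 90% of the
  total weight sits on near-deterministic low-activity grid points (v = 0,
  u ≤ 10 Hz), so the fitted coefficients are hypersensitive to the exact
  variance profile, which changes with N, Z and σ.  A nonzero σ in the
  original study — its value is not recoverable — would lift the variance
  floor of exactly these points and decompress the weights.
* At the P2 scale (231 grid points, Z = 10) the inverse-variance weights
  are so concentrated that a single near-deterministic point can carry
  ~95% of the total weight, making the weighted cross-validated R² a
  fragile, seed-sensitive statistic (observed range roughly 0.4–0.95).
  Variance shrinkage — weights 1/(var + λ·median var) — stabilizes it
  completely at negligible λ, but changes the estimand away from the
  published plain inverse-variance convention (and moves the statistic to
  ≈0.95–0.99); the package therefore keeps plain 1/var as the default and
  leaves shrinkage to the caller via `RateDataset.weights(variance_floor=…)`.
* In P2 the features u² and uv are nearly collinear because v is itself a
  function of (u, w); the division of explanatory weight between them
  shifts with the response calibration (κ).  The published u² coefficient
  (1.9e-4) moreover implies dw/dt ≈ 1.9/s at u = 100 Hz near w = 0 — above
  the model's intrinsic drift bound γ_p/τ ≈ 1.15/s — so it cannot be the
  pointwise behavior of any faithful re-simulation there and must reflect
  a differently weighted compromise.  The accuracy scores, which are the
  selection criterion, are insensitive to this split.
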