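"""Benchmark compact plasticity rules.

These are the published three-feature rate laws for this calcium-based
plasticity model family (linear calcium + MAT neuron data): one per motif,
plus the three best unified (cross-motif) rules.  They serve as reference
points for the qualitative characteristic analysis, for validating the
regression pipeline, and as ready-made rate laws for forward integration.

Coefficients c_abg multiply the feature u^a v^b w^g with u, v in Hz and the
resulting dw/dt in 1/s.
"""

from __future__ import annotations

from .model_reduction import Estimator, Feature

__all__ = [
    "P1_THREE_FEATURE",
    "P2_THREE_FEATURE",
    "P3_THREE_FEATURE",
    "UNIFIED_U2W",
    "UNIFIED_U2W2",
    "UNIFIED_HEBBIAN",
    "BENCHMARK_RULES",
]

#: Best three-feature rule for P1 (Poisson postsynaptic neuron):
#: dw/dt = c010 v + c011 v w + c102 u w^2
P1_THREE_FEATURE = Estimator(
    features=[Feature(0, 1, 0), Feature(0, 1, 1), Feature(1, 0, 2)],
    coef=[0.007832, -0.009186, -0.000989],
    r2=0.810,
    fitted_on=("P1",),
    strategy="published",
)

#: Best three-feature rule for P2 (MAT postsynaptic neuron):
#: dw/dt = c200 u^2 + c110 u v + c202 u^2 w^2
P2_THREE_FEATURE = Estimator(
    features=[Feature(2, 0, 0), Feature(1, 1, 0), Feature(2, 0, 2)],
    coef=[0.0001900, 0.0000527, -0.0001197],
    r2=0.822,
    fitted_on=("P2",),
    strategy="published",
)

#: Best three-feature rule for P3 (two populations, MAT neuron):
#: dw/dt = c200 u^2 + c210 u^2 v + c202 u^2 w^2
P3_THREE_FEATURE = Estimator(
    features=[Feature(2, 0, 0), Feature(2, 1, 0), Feature(2, 0, 2)],
    coef=[0.0000227, 0.0000004, -0.0000789],
    r2=0.652,
    fitted_on=("P3",),
    strategy="published",
)

#: Most accurate unified rule: u^2-driven growth with linear-in-w stabilization.
UNIFIED_U2W = Estimator(
    features=[Feature(2, 0, 0), Feature(2, 1, 0), Feature(2, 0, 1)],
    coef=[0.0000228, 0.0000004, -0.0000789],
    r2=0.620,
    fitted_on=("P1", "P2", "P3"),
    strategy="published-unified",
)

#: Second unified rule: as above with quadratic-in-w stabilization.
UNIFIED_U2W2 = Estimator(
    features=[Feature(2, 0, 0), Feature(2, 1, 0), Feature(2, 0, 2)],
    coef=[0.0000360, 0.0000004, -0.0000786],
    r2=0.610,
    fitted_on=("P1", "P2", "P3"),
    strategy="published-unified",
)

#: Third unified rule: Hebbian correlation terms with a u w^2 stabilizer.
#: dw/dt = c110 u v + c111 u v w + c102 u w^2
UNIFIED_HEBBIAN = Estimator(
    features=[Feature(1, 1, 0), Feature(1, 1, 1), Feature(1, 0, 2)],
    coef=[0.0001272, -0.0001444, -0.0011699],
    r2=0.599,
    fitted_on=("P1", "P2", "P3"),
    strategy="published-unified",
)

BENCHMARK_RULES = {
    "p1_three_feature": P1_THREE_FEATURE,
    "p2_three_feature": P2_THREE_FEATURE,
    "p3_three_feature": P3_THREE_FEATURE,
    "unified_u2w": UNIFIED_U2W,
    "unified_u2w2": UNIFIED_U2W2,
    "unified_hebbian": UNIFIED_HEBBIAN,
}
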