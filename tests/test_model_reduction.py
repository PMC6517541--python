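"""Regression machinery: design matrices, WLS, CV scoring, subset search."""

import numpy as np
import pytest

from rateplast.model_reduction import (
    Estimator, Feature, all_features, cv_adjusted_r2, design_matrix,
    feature_exclusion_experiment, feature_occurrence_table, ru2_score,
    subset_search, unified_fit_and_score, weighted_r2, wls_fit, SearchResult,
)
from conftest import make_dataset


class TestFeatures:
    def test_basis_has_27_distinct_bounded_monomials(self):
        feats = all_features()
        assert len(feats) == len(set(feats)) == 27
        assert all(e in (0, 1, 2)
                   for f in feats for e in (f.alpha, f.beta, f.gamma))

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            Feature(3, 0, 0)

    def test_names(self):
        assert str(Feature(0, 0, 0)) == "1"
        assert str(Feature(2, 1, 0)) == "u^2 v"
        assert str(Feature(1, 0, 2)) == "u w^2"


class TestDesignMatrix:
    def test_monomial_entries(self):
        ds = make_dataset({Feature(0, 0, 0): 0.0},
                          u_vals=[2.0, 10.0], v_vals=[3.0], w_vals=[0.5])
        x, _, _ = design_matrix(ds, [Feature(2, 1, 1), Feature(0, 0, 0),
                                     Feature(2, 0, 2)])
        # u^2 v w at (2, 3, 0.5) = 6; constant column; u^2 w^2 at (10,.,0.5)=25
        assert x[0, 0] == pytest.approx(6.0)
        np.testing.assert_array_equal(x[:, 1], 1.0)
        assert x[1, 2] == pytest.approx(25.0)


class TestWLS:
    def test_noiseless_planted_law_recovered_exactly(self, feature_uvw):
        law = {feature_uvw["uv"]: 0.01, feature_uvw["vw"]: -0.02}
        ds = make_dataset(law, u_vals=np.linspace(1, 100, 5),
                          v_vals=np.linspace(1, 100, 5),
                          w_vals=np.linspace(0, 1, 5))
        feats = list(law)
        x, y, w = design_matrix(ds, feats)
        coef, se = wls_fit(x, y, w, feats)
        np.testing.assert_allclose(coef, [0.01, -0.02], rtol=1e-10)

    def test_zero_response_gives_zero_coefficients(self, feature_uvw):
        ds = make_dataset({feature_uvw["1"]: 0.0})
        feats = [feature_uvw["u"], feature_uvw["vw"]]
        x, y, w = design_matrix(ds, feats)
        coef, _ = wls_fit(x, y, w, feats)
        np.testing.assert_allclose(coef, 0.0, atol=1e-12)

    def test_collinear_features_raise_named_error(self, feature_uvw):
        ds = make_dataset({feature_uvw["u"]: 1.0})
        feats = [feature_uvw["u"], feature_uvw["u"]]
        x, y, w = design_matrix(ds, feats)
        with pytest.raises(np.linalg.LinAlgError, match="u"):
            wls_fit(x, y, w, feats)

    def test_inverse_variance_weighting_beats_unweighted(self, feature_uvw):
        # Gauss-Markov: with strongly heteroscedastic noise, 1/var weights
        # give lower coefficient RMSE than uniform weights
        rng = np.random.default_rng(12)
        feats = [feature_uvw["u"], feature_uvw["v"]]
        truth = np.array([0.01, -0.02])
        u = np.linspace(1, 100, 40)
        v = np.linspace(100, 1, 40)
        x = np.column_stack([u, v])
        sd = np.where(np.arange(40) % 2 == 0, 5.0, 0.05)
        err_w, err_u = [], []
        for _ in range(200):
            y = x @ truth + rng.normal(0, sd)
            cw, *_ = np.linalg.lstsq(x / sd[:, None], y / sd, rcond=None)
            cu, *_ = np.linalg.lstsq(x, y, rcond=None)
            err_w.append(np.sum((cw - truth) ** 2))
            err_u.append(np.sum((cu - truth) ** 2))
        assert np.sqrt(np.mean(err_w)) < np.sqrt(np.mean(err_u))

    def test_scale_consistency(self, feature_uvw):
        # rescaling rates by factor s rescales c_abg by s^-(alpha+beta)
        law = {feature_uvw["uv"]: 0.01, feature_uvw["u2"]: -0.001}
        feats = list(law)
        ds1 = make_dataset(law, u_vals=[1, 2, 4], v_vals=[1, 3, 5],
                           w_vals=[0.2, 0.8])
        s = 10.0
        ds2 = make_dataset(law, u_vals=[1, 2, 4], v_vals=[1, 3, 5],
                           w_vals=[0.2, 0.8])
        for smp in ds2.samples:
            object.__setattr__(smp, "u", smp.u * s)
            object.__setattr__(smp, "v", smp.v * s)
        c1, _ = wls_fit(*design_matrix(ds1, feats)[:3], feats)
        c2, _ = wls_fit(*design_matrix(ds2, feats)[:3], feats)
        np.testing.assert_allclose(c2, c1 * [s ** -2.0, s ** -2.0], rtol=1e-8)


class TestCrossValidation:
    def test_perfect_fit_scores_one(self, feature_uvw):
        law = {feature_uvw["uv"]: 0.01}
        ds = make_dataset(law)
        assert cv_adjusted_r2(ds, list(law), seed=0) == pytest.approx(1.0)

    def test_uninformative_features_score_at_most_zeroish(self, feature_uvw):
        rng = np.random.default_rng(5)
        scores = []
        for seed in range(5):
            ds = make_dataset({feature_uvw["1"]: 0.0}, noise_sd=1.0, rng=rng)
            scores.append(cv_adjusted_r2(ds, [feature_uvw["u"],
                                              feature_uvw["vw"]], seed=seed))
        assert np.mean(scores) < 0.05

    def test_adjustment_penalizes_feature_count(self, feature_uvw):
        rng = np.random.default_rng(8)
        ds = make_dataset({feature_uvw["uv"]: 0.01}, noise_sd=5.0, rng=rng)
        from rateplast.model_reduction import _adjust_r2
        assert _adjust_r2(0.9, 100, 10) < 0.9
        assert _adjust_r2(1.0, 100, 10) == 1.0

    def test_small_dataset_rejected(self, feature_uvw):
        ds = make_dataset({feature_uvw["u"]: 1.0}, u_vals=[1, 2],
                          v_vals=[1], w_vals=[0.5])
        with pytest.raises(ValueError):
            cv_adjusted_r2(ds, [feature_uvw["u"]], seed=0)


class TestSubsetSearch:
    def test_planted_three_feature_law_is_selected(self, rng, feature_uvw):
        law = {feature_uvw["v"]: 0.008, feature_uvw["vw"]: -0.009,
               feature_uvw["uw2"]: -0.001}
        ds = make_dataset(law, noise_sd=0.01, rng=rng,
                          u_vals=np.linspace(0, 100, 6),
                          v_vals=np.linspace(0, 100, 6),
                          w_vals=np.linspace(0, 1, 5), var=1e-4)
        est = subset_search(ds, 3, seed=2)
        assert set(est.features) == set(law)
        np.testing.assert_allclose(
            est.coef, [law[f] for f in est.features], rtol=0.05)

    def test_forward_selection_extends_exhaustive_base(self, rng, feature_uvw):
        law = {feature_uvw["u"]: 0.01, feature_uvw["v"]: 0.02,
               feature_uvw["w"]: -0.5, feature_uvw["uv"]: 1e-4}
        pool = [feature_uvw[k] for k in ("u", "v", "w", "uv", "vw", "u2")]
        ds = make_dataset(law, noise_sd=0.01, rng=rng, var=1e-4)
        est = subset_search(ds, 4, seed=0, candidate_features=pool,
                            exhaustive_limit=2)
        assert est.strategy == "forward-from-best-2"
        assert len(est.features) == 4
        # greedy forward selection is an approximation; it must still land
        # close to a full explanation of the planted law
        assert est.r2 > 0.95

    def test_training_accuracy_non_decreasing_in_features(self, rng, feature_uvw):
        law = {feature_uvw["uv"]: 0.01, feature_uvw["w"]: -0.3}
        ds = make_dataset(law, noise_sd=0.5, rng=rng, var=0.25)
        feats27 = all_features()
        x, y, w = design_matrix(ds, feats27)
        def train_r2(cols):
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(x[:, cols] * sw[:, None], y * sw,
                                       rcond=None)
            return weighted_r2(y, x[:, cols] @ coef, w)
        r2_small = train_r2([5])                 # uv alone
        r2_mid = train_r2([5, 3])                # uv + w
        r2_full = train_r2(list(range(27)))
        assert r2_small <= r2_mid + 1e-12 <= r2_full + 1e-12


class TestUnifiedScoring:
    def test_ru2_printed_value_reproduction(self):
        # mean - population std of the printed per-setup scores, to the
        # precision the source tables carry
        assert ru2_score([0.629, 0.677, 0.626]) == pytest.approx(0.620, abs=1e-3)
        assert ru2_score([0.981, 0.986, 0.963]) == pytest.approx(0.967, abs=1e-3)

    def test_ru2_equals_value_for_identical_scores(self):
        assert ru2_score([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_ru2_never_exceeds_mean(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 1, 3)
            assert ru2_score(vals) <= vals.mean() + 1e-12

    def test_unified_fit_recovers_shared_law(self, rng, feature_uvw):
        law = {feature_uvw["uv"]: 0.01, feature_uvw["w"]: -0.2}
        ds1 = make_dataset(law, noise_sd=0.02, rng=rng, motif="P1", var=4e-4)
        ds2 = make_dataset(law, noise_sd=0.02, rng=rng, motif="P2", var=4e-4)
        est, ru2, per_setup = unified_fit_and_score(
            {"P1": ds1, "P2": ds2}, list(law), seed=1)
        np.testing.assert_allclose(est.coef, [law[f] for f in est.features],
                                   rtol=0.05)
        assert set(per_setup) == {"P1", "P2"}
        assert ru2 <= np.mean(list(per_setup.values())) + 1e-12

    def test_single_dataset_rejected(self, rng, feature_uvw):
        ds = make_dataset({feature_uvw["u"]: 1.0})
        with pytest.raises(ValueError):
            unified_fit_and_score({"P1": ds}, [feature_uvw["u"]])


class TestOccurrenceAndExclusion:
    def test_occurrence_counts_and_sum_identity(self, feature_uvw):
        ests = {}
        for n in range(3, 11):
            feats = all_features()[:n]
            ests[n] = Estimator(features=feats, coef=np.zeros(n))
        table = feature_occurrence_table({"P1 LC": SearchResult(best=ests)})
        counts = table["P1 LC"]
        assert sum(counts.values()) == sum(range(3, 11))   # 52
        assert counts[str(all_features()[0])] == 8          # in every estimator
        assert counts[str(all_features()[-1])] == 0         # in none

    def test_excluding_u2_terms_hurts_u2_dependent_law(self, rng, feature_uvw):
        law = {feature_uvw["u2w"]: 1e-3, feature_uvw["v"]: 0.01}
        ds = make_dataset(law, noise_sd=0.05, rng=rng, var=2.5e-3)
        curves = feature_exclusion_experiment(
            ds, lambda f: f.alpha == 2, f_values=[2], exhaustive_limit=2)
        r2_full, r2_excl = curves[2]
        assert r2_excl < r2_full

    def test_empty_exclusion_reproduces_full_curve(self, rng, feature_uvw):
        law = {feature_uvw["uv"]: 0.01}
        ds = make_dataset(law, noise_sd=0.05, rng=rng, var=2.5e-3)
        curves = feature_exclusion_experiment(
            ds, lambda f: False, f_values=[2], exhaustive_limit=2)
        r2_full, r2_excl = curves[2]
        assert r2_full == pytest.approx(r2_excl)
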