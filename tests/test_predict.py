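import json

import numpy as np
import pytest

from pathrisk.io import ExpressionMatrix, SurvivalData, ValidationError
from pathrisk.predict import (
    Predictor,
    fit_predictor,
    predict_risk,
    weighted_first_pc,
)
from pathrisk.evaluate import harrell_c
from pathrisk.summarize import build_feature_matrix
from pathrisk.synthetic import SimConfig, generate


@pytest.fixture
def fitted(rng):
    """A hybrid predictor on a small synthetic cohort."""
    data = generate(SimConfig(n_genes=300, n_sets=15, n_informative_sets=3,
                              n_train=60, n_test=40, seed=5))
    fm = build_feature_matrix(data.expr_train, data.collection)
    from pathrisk.scoring import score_all
    from pathrisk.selection import select_features

    scores = score_all(fm, data.surv_train)
    selected = select_features(scores, float(scores.abs().quantile(0.9)))
    pred = fit_predictor(fm.subset(selected), data.surv_train)
    return data, fm, pred


class TestWeightedPc:
    def test_matches_brute_force_svd_on_weighted_toy_matrix(self):
        # 2 features, weights (3,1), 4 samples; oracle = full SVD of the
        # explicitly weighted matrix
        X = np.array([[1.0, 2.0, 0.0, -1.0], [0.5, -0.5, 1.5, 0.5]])
        weights = np.array([3.0, 1.0])
        A = (X - X.mean(axis=1, keepdims=True)) * weights[:, None]
        w, scores = weighted_first_pc(A)
        U, S, Vt = np.linalg.svd(A)
        sign = np.sign(np.dot(w, U[:, 0]))
        np.testing.assert_allclose(w, sign * U[:, 0], atol=1e-10)
        np.testing.assert_allclose(scores, sign * S[0] * Vt[0], atol=1e-10)

    def test_tall_and_wide_branches_agree(self, rng):
        A = rng.normal(size=(30, 10))
        w1, s1 = weighted_first_pc(A)
        w2, s2 = weighted_first_pc(A.copy())
        U, S, Vt = np.linalg.svd(A)
        for w, s in ((w1, s1), (w2, s2)):
            sign = np.sign(np.dot(w, U[:, 0]))
            np.testing.assert_allclose(np.abs(np.dot(w, U[:, 0])), 1.0, atol=1e-10)
            np.testing.assert_allclose(s, sign * S[0] * Vt[0], atol=1e-8)

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(ValidationError):
            weighted_first_pc(np.zeros((3, 5)))


class TestFitPredictor:
    def test_unit_member_counts_reduce_to_conventional_pca(self, rng):
        # the degenerate case: all N_i = 1 must equal plain first-PC scores
        from sklearn.decomposition import PCA

        n, p = 40, 25
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(p)], [f"s{j}" for j in range(n)],
            rng.normal(size=(p, n)),
        )
        surv = SurvivalData(list(expr.sample_ids), rng.exponential(5, n), np.ones(n, dtype=int))
        fm = build_feature_matrix(expr, None, include_single_genes=True)
        pred = fit_predictor(fm, surv)
        risks = predict_risk(pred, expr)
        pc1 = PCA(n_components=1).fit_transform(fm.values.T)[:, 0]
        err = min(np.abs(risks - pc1).max(), np.abs(risks + pc1).max())
        assert err < 1e-10

    def test_rank_one_case_is_affine_in_the_single_feature(self, fitted):
        data, fm, _ = fitted
        one = fm.subset([fm.feature_ids[0]])
        pred = fit_predictor(one, data.surv_train)
        risks = predict_risk(pred, data.expr_train)
        feature = one.values[0]
        rho = abs(np.corrcoef(risks, feature)[0, 1])
        assert rho == pytest.approx(1.0, abs=1e-10)
        c_feat = harrell_c(feature, data.surv_train)
        c_pred = harrell_c(risks, data.surv_train)
        assert c_pred == pytest.approx(max(c_feat, 1 - c_feat), abs=1e-12)

    def test_orientation_gives_nonnegative_training_cox_coefficient(self, fitted):
        _, _, pred = fitted
        assert pred.train_cox_coef >= 0

    def test_loading_vector_is_unit_norm(self, fitted):
        _, _, pred = fitted
        assert np.linalg.norm(pred.loading) == pytest.approx(1.0)


class TestPredictRisk:
    def test_training_self_consistency(self, fitted):
        data, fm, pred = fitted
        risks = predict_risk(pred, data.expr_train)
        # rebuild by hand from the stored pieces
        from pathrisk.predict import rebuild_features, feature_weights

        X = rebuild_features(pred, data.expr_train)
        A = (X - pred.centers[:, None]) * feature_weights(pred.member_counts)[:, None]
        np.testing.assert_allclose(risks, pred.sign * (pred.loading @ A), atol=1e-12)
        # and the training scores equal the oriented PC scores
        fidx = fm.feature_index()
        rows = [fidx[f] for f in pred.feature_ids]
        Xtr = fm.values[rows, :]
        np.testing.assert_allclose(X, Xtr, atol=1e-10)

    def test_duplicated_sample_gets_identical_risk(self, fitted):
        data, _, pred = fitted
        expr = data.expr_test
        dup = ExpressionMatrix(
            list(expr.gene_ids),
            list(expr.sample_ids) + ["DUP"],
            np.c_[expr.values, expr.values[:, [0]]],
        )
        risks = predict_risk(pred, dup)
        assert risks[-1] == pytest.approx(risks[0], abs=1e-12)

    def test_missing_required_gene_is_named(self, fitted):
        data, _, pred = fitted
        needed = pred.standardization.gene_ids[0]
        keep = [g for g in data.expr_test.gene_ids if g != needed]
        expr = ExpressionMatrix(
            keep, data.expr_test.sample_ids,
            data.expr_test.values[[data.expr_test.gene_index()[g] for g in keep], :],
        )
        with pytest.raises(ValidationError, match=needed):
            predict_risk(pred, expr)

    def test_common_weight_rescaling_preserves_risk_ranking(self, fitted):
        data, fm, pred = fitted
        scaled = Predictor.from_dict(pred.to_dict())
        sub = fm.subset(pred.feature_ids)
        sub.member_counts = sub.member_counts * 7
        pred7 = fit_predictor(sub, data.surv_train)
        r1 = predict_risk(pred, data.expr_test)
        r7 = predict_risk(pred7, data.expr_test)
        np.testing.assert_array_equal(np.argsort(r1), np.argsort(r7))
        rho = np.corrcoef(r1, r7)[0, 1]
        assert rho == pytest.approx(1.0, abs=1e-10)

    def test_predicts_risk_direction_on_new_cohorts(self):
        # planted hazard on the latent factors: predicted risk must be
        # concordant (C > 0.5) on held-out samples, on average
        cs = []
        for seed in range(8):
            data = generate(SimConfig(n_genes=400, n_sets=20, n_informative_sets=4,
                                      n_train=80, n_test=80, seed=seed))
            fm = build_feature_matrix(data.expr_train, data.collection)
            from pathrisk.scoring import score_all
            from pathrisk.selection import select_features

            scores = score_all(fm, data.surv_train)
            selected = select_features(scores, float(scores.abs().quantile(0.95)))
            pred = fit_predictor(fm.subset(selected), data.surv_train)
            cs.append(harrell_c(predict_risk(pred, data.expr_test), data.surv_test))
        assert np.mean(cs) > 0.55


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, fitted, tmp_path):
        data, _, pred = fitted
        path = tmp_path / "pred.json"
        pred.save(path)
        back = Predictor.load(path)
        np.testing.assert_allclose(
            predict_risk(back, data.expr_test), predict_risk(pred, data.expr_test),
            atol=0,
        )

    def test_document_is_plain_json(self, fitted, tmp_path):
        _, _, pred = fitted
        path = tmp_path / "pred.json"
        pred.save(path)
        doc = json.loads(path.read_text())
        assert set(doc) >= {"feature_ids", "member_counts", "loading", "sign",
                            "centers", "standardization"}
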