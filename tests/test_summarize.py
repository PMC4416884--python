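import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathrisk.io import ExpressionMatrix, GeneSetCollection, ValidationError
from pathrisk.summarize import (
    apply_standardization,
    build_feature_matrix,
    fit_standardization,
    maxmean,
    rescale_geneset,
)


class TestStandardization:
    def test_closed_form_mean_and_sample_sd(self):
        expr = ExpressionMatrix(["g"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        model = fit_standardization(expr)
        assert model.mu[0] == pytest.approx(2.0)
        assert model.sigma[0] == pytest.approx(1.0)  # n-1 denominator

    def test_constant_gene_excluded(self):
        expr = ExpressionMatrix(
            ["g1", "g2"], ["a", "b", "c"], np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]])
        )
        model = fit_standardization(expr)
        assert model.gene_ids == ["g2"]
        assert model.dropped_genes == ["g1"]

    def test_all_constant_is_an_error(self):
        expr = ExpressionMatrix(["g1"], ["a", "b"], np.array([[7.0, 7.0]]))
        with pytest.raises(ValidationError, match="constant"):
            fit_standardization(expr)

    def test_training_rows_standardize_to_zero_one(self, rng):
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(50)],
            [f"s{j}" for j in range(20)],
            rng.normal(3, 2, (50, 20)),
        )
        model = fit_standardization(expr)
        z = apply_standardization(expr, model)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_test_data_uses_training_parameters_without_refit(self, rng):
        train = ExpressionMatrix(
            ["g1"], [f"s{j}" for j in range(10)], rng.normal(0, 1, (1, 10))
        )
        model = fit_standardization(train)
        shifted = ExpressionMatrix(["g1"], ["t1", "t2"], np.array([[4.0, 4.0]]))
        z = apply_standardization(shifted, model)
        expected = (4.0 - model.mu[0]) / model.sigma[0]
        np.testing.assert_allclose(z, expected)
        assert abs(z.mean()) > 0.1  # not re-centered

    def test_missing_model_gene_is_an_error(self, small_expr):
        model = fit_standardization(small_expr)
        reduced = ExpressionMatrix(
            small_expr.gene_ids[:5], small_expr.sample_ids, small_expr.values[:5]
        )
        with pytest.raises(ValidationError, match="missing"):
            apply_standardization(reduced, model)


class TestMaxmean:
    def test_all_zero_members_give_zero(self):
        assert maxmean(np.zeros((4, 6))).tolist() == [0.0] * 6

    def test_hand_evaluated_positive_case(self):
        # members (1.0, -0.5, 0.25): positive mean 1.25/3, negative mean -0.5/3
        u = maxmean(np.array([[1.0], [-0.5], [0.25]]))
        assert u[0] == pytest.approx(1.25 / 3)

    def test_hand_evaluated_negative_case(self):
        # members (-1.0, -1.0, 0.5): positive mean 0.5/3, negative mean -2/3
        u = maxmean(np.array([[-1.0], [-1.0], [0.5]]))
        assert u[0] == pytest.approx(-2.0 / 3)

    def test_empty_member_list_is_an_error(self):
        with pytest.raises(ValidationError):
            maxmean(np.empty((0, 3)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8), st.integers(0, 10**6))
    def test_sign_coherence_and_permutation_invariance(self, members, perm_seed):
        col = np.array(members)[:, None]
        u = maxmean(col)[0]
        if all(m >= 0 for m in members):
            assert u >= 0
        if all(m <= 0 for m in members):
            assert u <= 0
        shuffled = np.random.default_rng(perm_seed).permutation(members)[:, None]
        assert maxmean(shuffled)[0] == pytest.approx(u)


class TestRescale:
    def test_shared_member_moments_are_reproduced(self, rng):
        u = rng.normal(size=40)
        x, _, _ = rescale_geneset(u, member_mu=np.full(6, 3.0), member_sigma=np.full(6, 2.0))
        assert x.mean() == pytest.approx(3.0, abs=1e-10)
        assert x.std(ddof=1) == pytest.approx(2.0, abs=1e-10)

    def test_zero_variance_summary_is_an_error(self):
        with pytest.raises(ValidationError, match="zero-variance"):
            rescale_geneset(np.ones(10), np.array([1.0]), np.array([1.0]))

    def test_random_set_conserves_average_member_moments(self, rng):
        # direct recomputation of both sides of the conservation contract
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(30)],
            [f"s{j}" for j in range(100)],
            rng.normal(4, 3, (30, 100)),
        )
        members = list(rng.choice(expr.gene_ids, size=5, replace=False))
        coll = GeneSetCollection("one", {"S": frozenset(members)})
        model = fit_standardization(expr)
        fm = build_feature_matrix(expr, coll, include_single_genes=False, model=model)
        gidx = {g: i for i, g in enumerate(model.gene_ids)}
        rows = [gidx[g] for g in members]
        assert fm.values[0].mean() == pytest.approx(model.mu[rows].mean(), abs=1e-8)
        assert fm.values[0].var(ddof=1) == pytest.approx(
            np.mean(model.sigma[rows] ** 2), abs=1e-8
        )


class TestFeatureMatrix:
    def test_hybrid_feature_count(self, small_expr, small_collection):
        fm = build_feature_matrix(small_expr, small_collection, include_single_genes=True)
        assert fm.n_features == 13  # 3 sets + 10 genes

    def test_geneset_only_feature_count_and_kind(self, small_expr, small_collection):
        fm = build_feature_matrix(small_expr, small_collection, include_single_genes=False)
        assert fm.n_features == 3
        assert set(fm.kinds) == {"gene_set"}

    def test_absent_genes_intersected_out_of_member_count(self, small_expr, small_collection):
        fm = build_feature_matrix(small_expr, small_collection, include_single_genes=False)
        counts = dict(zip(fm.feature_ids, fm.member_counts))
        assert counts["GS:SET_C"] == 3  # MISSING_GENE dropped

    def test_single_gene_rows_carry_raw_expression(self, small_expr, small_collection):
        fm = build_feature_matrix(small_expr, small_collection, include_single_genes=True)
        fidx = fm.feature_index()
        gidx = small_expr.gene_index()
        np.testing.assert_array_equal(
            fm.values[fidx["SG:G4"]], small_expr.values[gidx["G4"]]
        )

    def test_singleton_set_reproduces_raw_gene_exactly(self, small_expr):
        coll = GeneSetCollection("singles", {f"ONE_{g}": {g} for g in small_expr.gene_ids})
        fm = build_feature_matrix(small_expr, coll, include_single_genes=False)
        gidx = small_expr.gene_index()
        for fid, row in zip(fm.feature_ids, fm.values):
            gene = fid[len("GS:ONE_"):]
            np.testing.assert_allclose(row, small_expr.values[gidx[gene]], atol=1e-12)

    def test_test_rebuild_matches_from_scratch_recomputation(self, rng):
        # train/test split of a synthetic cohort: rebuilding test features
        # from the stored model must equal a literal feature-by-feature
        # recomputation with the stored training parameters
        from pathrisk.synthetic import SimConfig, generate
        from pathrisk.summarize import maxmean as mm

        data = generate(SimConfig(n_genes=300, n_sets=15, n_informative_sets=3,
                                  n_train=40, n_test=30, seed=9))
        fm_tr = build_feature_matrix(data.expr_train, data.collection)
        fm_te = build_feature_matrix(
            data.expr_test, data.collection,
            model=fm_tr.standardization, transform=fm_tr.transform,
        )
        model, tf = fm_tr.standardization, fm_tr.transform
        z = apply_standardization(data.expr_test, model)
        gidx = {g: i for i, g in enumerate(model.gene_ids)}
        fidx = fm_te.feature_index()
        for k, set_name in enumerate(tf.set_names):
            rows = [gidx[g] for g in tf.members[set_name]]
            u = mm(z[rows, :], len(rows))
            x = (u - tf.u_mean[k]) / tf.u_sd[k] * tf.target_sd[k] + tf.target_mean[k]
            np.testing.assert_allclose(fm_te.values[fidx[f"GS:{set_name}"]], x, atol=1e-12)

    def test_no_features_requested_is_an_error(self, small_expr):
        with pytest.raises(ValidationError):
            build_feature_matrix(small_expr, None, include_single_genes=False)
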