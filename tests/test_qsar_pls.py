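"""Descriptor assembly, NIPALS PLS, LOO validation and QSAR statistics."""

import numpy as np
import pytest

from fieldqsar.fields import FieldGrid
from fieldqsar.qsar_pls import (
    assemble_descriptors,
    block_scale,
    endpoint_correlation,
    f_statistic,
    field_fractions,
    loo_validate,
    model_summary,
    nipals_pls,
    q2_statistic,
    r2_pred,
    split_train_test,
    transform_like,
)
from tests._datasets import DUAL_ENDPOINT_PIC50
from tests.conftest import dm_from_matrix


def _grids(field, rows):
    return [FieldGrid(f"row_{i}", field, r) for i, r in enumerate(np.asarray(rows, float))]


class TestAssemble:
    def test_low_sigma_columns_masked(self):
        # col0 constant, col1 std ~0.4-0.5 (below 1), col2 wide
        rows = [[5.0, 0.0, 0.0], [5.0, 0.5, 4.0], [5.0, 1.0, 9.0]]
        dm = assemble_descriptors(_grids("comfa_steric", rows), sigma_min=1.0)
        assert list(dm.retained_mask) == [False, False, True]

    def test_extra_columns_exempt_from_filtering(self):
        rows = [[0.0, 3.0], [1.0, 9.0], [2.0, 5.0]]
        extras = {"ClogP": {"row_0": 2.0, "row_1": 2.0, "row_2": 2.0}}
        dm = assemble_descriptors(_grids("comfa_steric", rows), extras, sigma_min=1.0)
        assert dm.column_meta[-1] == ("extra", "ClogP")
        assert dm.retained_mask[-1]  # constant but retained

    def test_missing_extra_errors(self):
        rows = [[0.0], [1.0], [2.0]]
        with pytest.raises(ValueError, match="missing"):
            assemble_descriptors(_grids("comfa_steric", rows), {"ClogP": {"row_0": 1.0}})

    def test_inconsistent_lattice_errors(self):
        grids = _grids("comfa_steric", [[0.0, 1.0]]) + [
            FieldGrid("row_1", "comfa_steric", np.array([0.0, 1.0, 2.0]))
        ]
        with pytest.raises(ValueError, match="lattice"):
            assemble_descriptors(grids)

    def test_clash_mean_fill_before_filtering(self):
        vals = np.array([[10.0], [2.0], [4.0], [6.0]])
        clash = np.array([[True], [False], [False], [False]])
        grids = [
            FieldGrid(f"row_{i}", "comfa_elec", vals[i], clash[i]) for i in range(4)
        ]
        dm = assemble_descriptors(grids, sigma_min=0.0)
        assert abs(dm.values[0, 0] - 4.0) < 1e-12  # mean of the non-clash rows


class TestBlockScale:
    def test_single_block_total_variance_equals_column_count(self):
        rng = np.random.default_rng(0)
        dm = assemble_descriptors(_grids("comfa_steric", rng.normal(0, 5, (10, 6))), sigma_min=0.0)
        scaled = block_scale(dm, "comfa_std")
        total_var = scaled.retained().var(axis=0).sum()
        assert abs(total_var - 6) < 1e-9

    def test_two_blocks_equalized(self):
        rng = np.random.default_rng(1)
        g = _grids("comfa_steric", rng.normal(0, 10, (8, 4))) + _grids(
            "comfa_elec", rng.normal(0, 0.5, (8, 4))
        )
        dm = block_scale(assemble_descriptors(g, sigma_min=0.0), "comfa_std")
        blocks = dm.column_blocks()[dm.retained_mask]
        Xr = dm.retained()
        v1 = Xr[:, blocks == "comfa_steric"].var(axis=0).sum()
        v2 = Xr[:, blocks == "comfa_elec"].var(axis=0).sum()
        assert abs(v1 - v2) < 1e-9

    def test_scheme_none_unchanged(self):
        rng = np.random.default_rng(2)
        dm = assemble_descriptors(_grids("comfa_steric", rng.normal(size=(5, 3))), sigma_min=0.0)
        assert np.allclose(block_scale(dm, "none").values, dm.values)

    def test_zero_variance_block_errors(self):
        dm = assemble_descriptors(_grids("comfa_steric", np.ones((4, 3))), sigma_min=0.0)
        with pytest.raises(ValueError, match="zero-variance"):
            block_scale(dm, "comfa_std")


class TestNipals:
    def test_exact_univariate_relationship(self):
        # orthonormal columns: the first latent variable is exactly the
        # signal-carrying column, so one component fits perfectly
        rng = np.random.default_rng(3)
        A = rng.normal(size=(12, 5))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))  # zero-mean orthonormal columns
        y = 2.5 * Q[:, 2] + 1.0
        model = nipals_pls(Q, y, 1)
        assert np.allclose(model.predict(Q), y, atol=1e-10)

    def test_first_weight_proportional_to_xty(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = nipals_pls(X, y, 1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w_ref = Xc.T @ yc
        w_ref /= np.linalg.norm(w_ref)
        assert np.allclose(np.abs(model.weights[:, 0]), np.abs(w_ref), atol=1e-10)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 10))
        y = X @ rng.normal(size=10) + 0.1 * rng.normal(size=20)
        model = nipals_pls(X, y, 5)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    @pytest.mark.parametrize("c", [1, 2, 3])
    def test_matches_sklearn_pls(self, c):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        model = nipals_pls(X, y, c)
        ref = PLSRegression(n_components=c, scale=False).fit(X, y)
        assert np.allclose(model.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_degenerate_inputs_error(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError):
            nipals_pls(X, np.ones(6), 1)  # constant y
        with pytest.raises(ValueError):
            nipals_pls(X, np.arange(6.0), 6)  # too many components


class TestLoo:
    def test_noiseless_linear_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 5.0
        dm = dm_from_matrix(X)
        q2, sep, opn = loo_validate(dm, y, 4)
        assert q2[3] >= 0.999  # full-rank fit of a noiseless linear response

    def test_equals_explicit_refit_loop(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 5))
        y = X @ rng.normal(size=5) + 0.3 * rng.normal(size=8)
        dm = dm_from_matrix(X)
        c_max = 3
        q2, sep, opn = loo_validate(dm, y, c_max)
        for c in range(1, c_max + 1):
            press = 0.0
            for i in range(8):
                rows = [r for r in range(8) if r != i]
                model = nipals_pls(X[rows], y[rows], c)
                press += (model.predict(X[i : i + 1])[0] - y[i]) ** 2
            q2_ref = 1.0 - press / ((y - y.mean()) ** 2).sum()
            assert abs(q2[c - 1] - q2_ref) < 1e-10
            assert abs(sep[c - 1] - np.sqrt(press / (8 - c - 1))) < 1e-10

    def test_scrambled_response_has_no_predictivity(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(16, 8))
        y = X @ rng.normal(size=8) + 0.2 * rng.normal(size=16)
        y_perm = rng.permutation(y)
        q2, _, _ = loo_validate(dm_from_matrix(X), y_perm, 4)
        assert (q2 <= 0.2).all()

    def test_preconditions(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            loo_validate(dm_from_matrix(X), y, 4)  # c_max >= n - 1
        with pytest.raises(ValueError):
            loo_validate(dm_from_matrix(X[:3]), y[:3], 1)  # too few rows

    def test_fold_filtering_recomputed(self):
        # a column whose variance collapses when one row is dropped must
        # be filtered inside that fold only
        X = np.zeros((6, 2))
        X[:, 0] = [0, 0, 0, 0, 0, 10.0]  # variance driven by the last row
        X[:, 1] = np.arange(6.0) * 3
        y = X[:, 1] * 0.5 + 2.0
        dm = dm_from_matrix(X, sigma_min=1.5)
        q2, _, _ = loo_validate(dm, y, 2)
        assert q2[1] > 0.99  # informative column survives in every fold


class TestSummary:
    def test_f_statistic_reference_values(self):
        assert abs(f_statistic(0.715, 57, 6) - 20.906) < 0.001
        assert abs(f_statistic(0.5, 12, 1) - 10.0) < 1e-12

    def test_model_summary_consistency(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 6))
        y = X @ rng.normal(size=6) + 0.5 * rng.normal(size=20)
        model = nipals_pls(X, y, 3)
        stats = model_summary(model, X, y)
        resid = y - model.predict(X)
        assert abs(stats.r2_ncv - (1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum())) < 1e-12
        assert abs(stats.see - np.sqrt((resid**2).sum() / (20 - 3 - 1))) < 1e-12
        f_ref = f_statistic(stats.r2_ncv, 20, 3)
        assert abs(stats.f_stat - f_ref) < 1e-9

    def test_perfect_fit_reports_infinite_f(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(10, 3))
        X, _ = np.linalg.qr(A - A.mean(axis=0))
        y = X[:, 0] * 2.0
        model = nipals_pls(X, y, 1)
        stats = model_summary(model, X, y)
        assert stats.see < 1e-8
        assert np.isinf(stats.f_stat)

    def test_monotone_r2_in_components(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=25)
        r2s = [model_summary(nipals_pls(X, y, c), X, y).r2_ncv for c in range(1, 8)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestFieldFractions:
    def test_single_block_is_one(self):
        rng = np.random.default_rng(13)
        dm = dm_from_matrix(rng.normal(size=(10, 4)))
        y = rng.normal(size=10)
        model = nipals_pls(dm, y, 2)
        fr = field_fractions(model, dm)
        assert abs(fr["comsia_steric"] - 1.0) < 1e-12

    def test_duplicated_blocks_split_evenly(self):
        rng = np.random.default_rng(14)
        block = rng.normal(size=(12, 5))
        grids = _grids("comfa_steric", block) + _grids("comfa_elec", block)
        dm = assemble_descriptors(grids, sigma_min=0.0)
        y = block @ rng.normal(size=5) + rng.normal(size=12) * 0.1
        model = nipals_pls(dm, y, 2)
        fr = field_fractions(model, dm)
        assert abs(fr["comfa_steric"] - 0.5) < 1e-9
        assert abs(sum(fr.values()) - 1.0) < 1e-9


class TestStatistics:
    def test_q2_examples(self):
        assert q2_statistic([1, 2, 3], [1, 2, 3]) == 1.0
        assert q2_statistic([1, 2, 3], [2, 2, 2]) == 0.0
        assert abs(q2_statistic([1, 2, 3], [1.1, 1.9, 3.2], 2.0) - 0.97) < 1e-12

    def test_q2_rejects_constant_observations(self):
        with pytest.raises(ValueError):
            q2_statistic([2, 2, 2], [1, 2, 3])

    def test_r2_pred_examples(self):
        assert r2_pred([1, 3], [1, 3], 2.0) == 1.0
        assert r2_pred([1, 3], [2, 2], 2.0) == 0.0
        assert abs(r2_pred([1, 3], [1.5, 2.5], 2.0) - 0.75) < 1e-12
        with pytest.raises(ValueError):
            r2_pred([2, 2], [1, 3], 2.0)  # SD about the train mean is zero

    @pytest.mark.parametrize("n, n_test, n_train", [(137, 27, 110), (69, 12, 57)])
    def test_split_sizes(self, n, n_test, n_train):
        y = np.random.default_rng(15).normal(7, 1, n)
        labels = split_train_test(y, n_test, seed=3)
        assert (labels == "test").sum() == n_test
        assert (labels == "train").sum() == n_train

    def test_split_deterministic_and_stratified(self):
        y = np.sort(np.random.default_rng(16).normal(7, 1, 50))
        l1 = split_train_test(y, 10, seed=5)
        l2 = split_train_test(y, 10, seed=5)
        assert (l1 == l2).all()
        # one test compound per activity quintile bin of 5
        test_idx = np.nonzero(l1 == "test")[0]
        assert all((test_idx // 5 == np.arange(10)))

    def test_endpoint_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert abs(endpoint_correlation(list(zip(x, x))) - 1.0) < 1e-12
        assert abs(endpoint_correlation(list(zip(x, [-v for v in x]))) - 1.0) < 1e-12
        with pytest.raises(ValueError):
            endpoint_correlation([(1, 1), (1, 2), (1, 3)])

    def test_endpoint_correlation_matches_least_squares(self):
        pairs = list(DUAL_ENDPOINT_PIC50.values())
        r2 = endpoint_correlation(pairs)
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        # least-squares oracle: R^2 of the simple regression of y on x
        A = np.column_stack([x, np.ones_like(x)])
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        r2_ref = 1 - ((A @ beta - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert abs(r2 - r2_ref) < 1e-10


def test_transform_like_reproduces_training_rows():
    rng = np.random.default_rng(17)
    X = rng.normal(0, 5, size=(10, 6))
    dm = block_scale(dm_from_matrix(X, sigma_min=1.0), "comfa_std")
    again = transform_like(dm, dm.raw)
    assert np.allclose(again, dm.retained(), atol=1e-12)
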