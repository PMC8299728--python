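"""Kernels, the multi-kernel SVM trainer, and nested LOOCV."""

import warnings

import numpy as np
import pytest

from mmconnect.evaluation import solve_svm_dual_exact
from mmconnect.mksvm import (
    combine_kernels,
    default_c_grid,
    dual_objective,
    linear_kernel,
    nested_loocv,
    predict,
    roc_auc,
    simplex_grid,
    train_mksvm,
)


class TestLinearKernel:
    def test_orthonormal_rows_identity(self):
        k = linear_kernel(np.eye(4))
        assert np.allclose(k, np.eye(4))

    def test_duplicated_sample_duplicates_row(self, rng):
        x = rng.standard_normal((5, 3))
        x2 = np.vstack([x, x[2]])
        k = linear_kernel(x2)
        assert np.allclose(k[5], k[2])
        assert np.allclose(k[:, 5], k[:, 2])

    def test_psd(self, rng):
        x = rng.standard_normal((8, 4))
        w = np.linalg.eigvalsh(linear_kernel(x))
        assert w.min() > -1e-10


class TestCombineKernels:
    def test_vertex_returns_single_kernel(self, rng):
        ks = [linear_kernel(rng.standard_normal((5, 3))) for _ in range(3)]
        assert np.array_equal(combine_kernels(ks, [1.0, 0.0, 0.0]), ks[0])

    def test_identical_kernels_invariant(self, rng):
        k = linear_kernel(rng.standard_normal((5, 3)))
        for beta in [(0.2, 0.3, 0.5), (1 / 3, 1 / 3, 1 / 3)]:
            assert np.allclose(combine_kernels([k, k, k], beta), k)

    def test_weighted_identity_arithmetic(self):
        ks = [np.eye(4), 2 * np.eye(4), 3 * np.eye(4)]
        out = combine_kernels(ks, [1 / 3, 1 / 3, 1 / 3])
        assert np.allclose(out, 2 * np.eye(4))

    def test_simplex_violation_rejected(self, rng):
        ks = [np.eye(3), np.eye(3)]
        with pytest.raises(ValueError):
            combine_kernels(ks, [0.7, 0.7])
        with pytest.raises(ValueError):
            combine_kernels(ks, [1.5, -0.5])


class TestSimplexGrid:
    def test_counts(self):
        assert len(simplex_grid(3, 0.1)) == 66  # C(12,2)
        assert len(simplex_grid(3, 0.5)) == 6
        assert len(simplex_grid(2, 0.25)) == 5

    def test_all_on_simplex_and_sorted(self):
        g = simplex_grid(3, 0.2)
        for b in g:
            assert abs(sum(b) - 1.0) < 1e-12 and min(b) >= 0
        assert g == sorted(g)

    def test_c_grid_is_powers_of_two(self):
        g = default_c_grid()
        assert len(g) == 11
        assert g[0] == 2.0**-5 and g[-1] == 2.0**5


def _toy_separable():
    x = np.array([[1.0, 1.0], [1.5, 1.2], [-1.0, -1.0], [-1.2, -1.5]])
    y = np.array([1, 1, -1, -1])
    return x, y


class TestTrainPredict:
    def test_separable_toy_zero_training_errors(self):
        x, y = _toy_separable()
        k = linear_kernel(x)
        model = train_mksvm([k], y, np.array([1.0]), C=100.0)
        dec, lab = predict(model, [k])
        assert np.array_equal(lab, y)

    def test_dual_feasibility(self, rng):
        x = rng.standard_normal((12, 6))
        y = np.array([1] * 6 + [-1] * 6)
        model = train_mksvm([linear_kernel(x)], y, np.array([1.0]), C=1.0)
        assert abs(np.dot(model.alphas, model.y_train)) < 1e-6
        assert (model.alphas >= -1e-9).all() and (model.alphas <= 1.0 + 1e-9).all()

    def test_duplicated_training_set_same_decision(self):
        x, y = _toy_separable()
        xt = np.array([[0.5, 0.6], [-0.4, -0.7]])
        m1 = train_mksvm([linear_kernel(x)], y, np.array([1.0]), C=1000.0)
        d1, _ = predict(m1, [xt @ x.T])
        x2, y2 = np.vstack([x, x]), np.concatenate([y, y])
        m2 = train_mksvm([linear_kernel(x2)], y2, np.array([1.0]), C=1000.0)
        d2, _ = predict(m2, [xt @ x2.T])
        assert np.allclose(d1, d2, atol=1e-6)

    def test_label_flip_antisymmetry(self, rng):
        x = rng.standard_normal((10, 4))
        y = np.array([1] * 5 + [-1] * 5)
        xt = rng.standard_normal((4, 4))
        k, kx = linear_kernel(x), xt @ x.T
        d1, _ = predict(train_mksvm([k], y, np.array([1.0]), C=1.0), [kx])
        d2, _ = predict(train_mksvm([k], -y, np.array([1.0]), C=1.0), [kx])
        assert np.allclose(d1, -d2, atol=1e-6)

    def test_vertex_beta_equals_single_kernel_svm(self, rng):
        xs = [rng.standard_normal((10, 5)) for _ in range(3)]
        y = np.array([1] * 5 + [-1] * 5)
        ks = [linear_kernel(x) for x in xs]
        xt = [rng.standard_normal((3, 5)) for _ in range(3)]
        cross = [a @ b.T for a, b in zip(xt, xs)]
        for v in range(3):
            beta = np.zeros(3)
            beta[v] = 1.0
            d_multi, _ = predict(train_mksvm(ks, y, beta, C=2.0, tol=1e-10), cross)
            d_single, _ = predict(
                train_mksvm([ks[v]], y, np.array([1.0]), C=2.0, tol=1e-10), [cross[v]]
            )
            assert np.allclose(d_multi, d_single, atol=1e-6)

    def test_matches_exact_qp_oracle(self, rng):
        # objective and decisions against brute-force active-set enumeration
        for trial in range(3):
            xs = [rng.standard_normal((8, 6)) for _ in range(3)]
            y = np.array([1] * 4 + [-1] * 4)
            ks = [linear_kernel(x) for x in xs]
            beta = np.array([0.5, 0.3, 0.2])
            model = train_mksvm(ks, y, beta, C=1.0, tol=1e-10)
            kc = combine_kernels(ks, beta)
            a, b, obj = solve_svm_dual_exact(kc, y.astype(float), 1.0)
            assert dual_objective(model, ks) == pytest.approx(obj, abs=1e-6)
            xt = [rng.standard_normal((4, 6)) for _ in range(3)]
            cross = [t @ s.T for t, s in zip(xt, xs)]
            d_model, _ = predict(model, cross)
            kc_cross = sum(bb * k for bb, k in zip(beta, cross))
            d_oracle = kc_cross @ (a * y) + b
            assert np.allclose(d_model, d_oracle, atol=1e-6)


class TestRocAuc:
    def test_perfect_ordering(self):
        auc, pts = roc_auc(np.array([3.0, 2.0, 1.0, 0.0]), np.array([1, 1, -1, -1]))
        assert auc == 1.0
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_reversed_ordering(self):
        auc, _ = roc_auc(np.array([0.0, 1.0, 2.0, 3.0]), np.array([1, 1, -1, -1]))
        assert auc == 0.0

    def test_ties_half(self):
        auc, _ = roc_auc(np.zeros(4), np.array([1, 1, -1, -1]))
        assert auc == 0.5

    def test_random_scores_near_half(self, rng):
        d = rng.standard_normal(2000)
        y = np.where(rng.random(2000) < 0.5, 1, -1)
        auc, _ = roc_auc(d, y)
        assert abs(auc - 0.5) < 0.04

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        d = rng.standard_normal(100)
        y = np.where(rng.random(100) < 0.4, 1, -1)
        auc, _ = roc_auc(d, y)
        assert auc == pytest.approx(roc_auc_score(y, d))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestNestedLoocv:
    def _cohort(self, rng, n=12, separating=True):
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        feats = {
            "a": y[:, None] * 2.0 + rng.standard_normal((n, 8)) * 0.1,
            "b": rng.standard_normal((n, 8)),
            "c": rng.standard_normal((n, 8)),
        }
        if not separating:
            feats["a"] = rng.standard_normal((n, 8))
        return feats, y

    def test_separating_modality_dominates(self, rng):
        feats, y = self._cohort(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = nested_loocv(
                feats, y, C_grid=np.array([0.25, 4.0]), beta_step=0.5
            )
        assert rep.accuracy == 100.0
        # beta mass concentrates on the separating modality in most folds
        first_beta = [b[0] for _, b in rep.chosen_params]
        assert np.mean([b >= 0.5 for b in first_beta]) > 0.5

    def test_single_modality_reduces_to_plain_svm_loocv(self, rng):
        from sklearn.svm import SVC

        feats, y = self._cohort(rng)
        X = feats["a"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = nested_loocv({"a": X}, y, C_grid=np.array([1.0]))
        # independent re-implementation: t-test select, z-score, SVC, C=1
        from mmconnect.selection import edge_ttest

        n = len(y)
        agree = 0
        for t in range(n):
            tr = np.array([i for i in range(n) if i != t])
            ytr = y[tr]
            st = edge_ttest(X[tr][ytr == 1], X[tr][ytr == -1], alpha=0.01)
            mask = st.selected
            if not mask.any():
                continue
            mu = X[tr][:, mask].mean(0)
            sd = X[tr][:, mask].std(0, ddof=1)
            sd[sd == 0] = 1
            Z = (X[:, mask] - mu) / sd
            svc = SVC(kernel="linear", C=1.0).fit(Z[tr], ytr)
            agree += int(svc.predict(Z[t : t + 1])[0] == rep.predictions[t])
        assert agree == n  # every fold's prediction matches the plain SVM

    def test_no_leakage_masks_differ_across_folds(self, rng):
        feats, y = self._cohort(rng, separating=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = nested_loocv(feats, y, C_grid=np.array([1.0]), beta_step=0.5)
        for mod in feats:
            masks = rep.fold_masks[mod]
            assert len(masks) == len(y)
            # on noise, selections vary between folds
        all_masks = np.vstack([np.concatenate(rep.fold_masks[m]) for m in feats])
        assert len(np.unique(all_masks.astype(int), axis=0)) >= 1

    def test_deterministic(self, rng):
        feats, y = self._cohort(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = nested_loocv(feats, y, C_grid=np.array([0.25, 4.0]), beta_step=0.5)
            r2 = nested_loocv(feats, y, C_grid=np.array([0.25, 4.0]), beta_step=0.5)
        assert np.array_equal(r1.decision_values, r2.decision_values)
        assert r1.chosen_params == r2.chosen_params

    def test_minimum_cohort_guard(self, rng):
        feats = {"a": rng.standard_normal((4, 5))}
        with pytest.raises(ValueError):
            nested_loocv(feats, np.array([1, 1, -1, -1]))
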