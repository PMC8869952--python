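import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from admoe import MOEConfig, fit_moe, hard_assign, predict_diagnosis
from admoe.moe import (
    MOEModel,
    _svm_objective,
    fit_expert_svm,
    initialize_memberships,
    moe_objective,
    update_centroids,
    update_memberships,
)
from admoe.residualize import ResidualTable

import pandas as pd


def simplex_grid_minimum(h_row, D_row, C, t, resolution=200):
    """Brute-force minimum of the per-subject membership objective on the
    2-simplex (K=3), evaluated on a resolution x resolution grid."""
    best = np.inf
    arg = None
    for i in range(resolution + 1):
        m1 = i / resolution
        for j in range(resolution + 1 - i):
            m2 = j / resolution
            m3 = 1.0 - m1 - m2
            m = np.array([m1, m2, m3])
            val = float((C * m * h_row + t * m**2 * D_row).sum())
            if val < best:
                best, arg = val, m
    return best, arg


def row_objective(m, h, D, C, t):
    return float((C * m * h + t * m**2 * D).sum())


def residuals_from_arrays(X_cn, X_ad, modality="density"):
    n_cn, n_ad = len(X_cn), len(X_ad)
    df = pd.DataFrame(
        {
            "subject_id": [f"c{i}" for i in range(n_cn)] + [f"a{i}" for i in range(n_ad)],
            "diagnosis": ["CN"] * n_cn + ["AD"] * n_ad,
        }
    )
    X = np.vstack([X_cn, X_ad])
    roi = pd.DataFrame(X, columns=[f"r{j}" for j in range(X.shape[1])])
    return ResidualTable(pd.concat([df, roi], axis=1), modality)


class TestInitializeMemberships:
    def test_random_rows_on_simplex_and_deterministic(self):
        X = np.random.default_rng(0).normal(size=(12, 5))
        m1 = initialize_memberships(X, 3, seed=4, method="random")
        m2 = initialize_memberships(X, 3, seed=4, method="random")
        assert np.allclose(m1.sum(axis=1), 1.0)
        assert ((m1 >= 0) & (m1 <= 1)).all()
        assert np.array_equal(m1, m2)

    def test_kmeans_init_matches_separated_blobs(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(20, 4))
        b = rng.normal(0, 1, size=(20, 4)) + 10.0  # 10-sigma separation
        X = np.vstack([a, b])
        m = initialize_memberships(X, 2, seed=0, method="kmeans")
        labels = m.argmax(axis=1)
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            initialize_memberships(np.zeros((2, 3)), 4, seed=0)


class TestUpdateCentroids:
    def test_crisp_memberships_return_points(self):
        X = np.array([[1.0, 2.0], [5.0, -1.0]])
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        d = update_centroids(m, X, alpha=2.0)
        assert np.allclose(d, X)

    def test_uniform_memberships_give_grand_mean(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(7, 4))
        m = np.full((7, 3), 1 / 3)
        for alpha in (1.5, 2.0, 3.0):
            d = update_centroids(m, X, alpha=alpha)
            assert np.allclose(d, X.mean(axis=0))

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 3))
        m = rng.dirichlet(np.ones(2), size=5)
        d = update_centroids(m, X, alpha=2.0)
        for k in range(2):
            num = sum(m[i, k] ** 2 * X[i] for i in range(5))
            den = sum(m[i, k] ** 2 for i in range(5))
            assert np.allclose(d[k], num / den, atol=1e-12)

    def test_empty_expert_rejected(self):
        X = np.zeros((3, 2))
        m = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="zero total membership"):
            update_centroids(m, X, alpha=2.0)


class TestFitExpertSvm:
    def test_separable_data_reaches_zero_hinge(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-4, 0.3, size=(20, 2)), rng.normal(4, 0.3, size=(20, 2))])
        y = np.array([-1.0] * 20 + [1.0] * 20)
        X_aug = np.column_stack([X, np.ones(40)])
        w = fit_expert_svm(X_aug, y, np.ones(40), C=100.0, max_iter=5000)
        margins = y * (X_aug @ w)
        hinge = np.maximum(0, 1 - margins) ** 2
        assert hinge.sum() < 1e-3

    def test_single_weighted_pair_is_separated(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        X[0] = [2.0, 0.0]
        X[1] = [-2.0, 0.0]
        y = np.array([1.0, -1.0] + [1.0, -1.0] * 4)
        s = np.zeros(10)
        s[0] = s[1] = 1.0
        X_aug = np.column_stack([X, np.ones(10)])
        w = fit_expert_svm(X_aug, y, s, C=10.0, max_iter=5000)
        assert (X_aug[0] @ w) > 0
        assert (X_aug[1] @ w) < 0

    def test_descent_from_zero_start(self):
        rng = np.random.default_rng(7)
        X_aug = np.column_stack([rng.normal(size=(30, 4)), np.ones(30)])
        y = np.sign(rng.normal(size=30))
        s = rng.uniform(0.1, 1.0, size=30)
        C = 2.0
        w = fit_expert_svm(X_aug, y, s, C=C, w0=np.zeros(5), max_iter=50)
        f0 = _svm_objective(np.zeros(5), X_aug, y, s, C)
        assert np.isclose(f0, C * s.sum())
        assert _svm_objective(w, X_aug, y, s, C) <= f0 + 1e-12

    def test_never_exceeds_warm_start_objective(self):
        rng = np.random.default_rng(8)
        X_aug = np.column_stack([rng.normal(size=(25, 3)), np.ones(25)])
        y = np.sign(rng.normal(size=25))
        s = rng.uniform(0, 1, size=25)
        for trial in range(5):
            w0 = rng.normal(size=4)
            w = fit_expert_svm(X_aug, y, s, C=1.0, w0=w0, max_iter=20)
            assert (
                _svm_objective(w, X_aug, y, s, 1.0)
                <= _svm_objective(w0, X_aug, y, s, 1.0) + 1e-10
            )

    def test_one_empty_class_rejected(self):
        X_aug = np.column_stack([np.ones((4, 2)), np.ones(4)])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        s = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="class"):
            fit_expert_svm(X_aug, y, s, C=1.0)


class TestUpdateMemberships:
    def test_symmetric_instance_splits_evenly(self):
        m = update_memberships(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]), C=3.0, t=0.7)
        assert np.allclose(m, [[0.5, 0.5]])

    def test_boundary_minimizer(self):
        # K=2, C=1, t=1, h=(0,4), D=(1,1): all mass on the first expert
        m = update_memberships(np.array([[0.0, 4.0]]), np.array([[1.0, 1.0]]), C=1.0, t=1.0)
        assert np.allclose(m, [[1.0, 0.0]], atol=1e-12)

    def test_matches_simplex_grid_oracle_k3(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            h = rng.uniform(0, 5, size=(1, 3))
            D = rng.uniform(0.1, 4, size=(1, 3))
            C, t = rng.uniform(0.1, 4, size=2)
            m = update_memberships(h, D, C, t)
            val = row_objective(m[0], h[0], D[0], C, t)
            best, _ = simplex_grid_minimum(h[0], D[0], C, t, resolution=200)
            assert val <= best + 1e-4

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            update_memberships(np.array([[-1.0, 0.0]]), np.array([[1.0, 1.0]]), 1.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 6))
    def test_rows_on_simplex_and_beat_random_points(self, seed, K):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0, 10, size=(3, K))
        D = rng.uniform(1e-6, 5, size=(3, K))
        C, t = rng.uniform(0.05, 8, size=2)
        m = update_memberships(h, D, C, t)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)
        assert (m >= -1e-12).all()
        # exact minimizer beats random feasible candidates
        for i in range(3):
            val = row_objective(m[i], h[i], D[i], C, t)
            for cand in rng.dirichlet(np.ones(K), size=20):
                assert val <= row_objective(cand, h[i], D[i], C, t) + 1e-9


class TestObjective:
    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(10)
        K, P, n_ad, n_cn = 3, 4, 6, 5
        W = rng.normal(size=(K, P + 1))
        X_ad = rng.normal(size=(n_ad, P))
        X_cn = rng.normal(size=(n_cn, P))
        m = rng.dirichlet(np.ones(K), size=n_ad)
        d = rng.normal(size=(K, P))
        cfg = MOEConfig(K=K, C=1.7, t=0.9, cn_weight=0.5)
        J = moe_objective(W, m, d, X_ad, X_cn, cfg)
        # direct summation
        total = 0.0
        for k in range(K):
            total += 0.5 * np.abs(W[k, :-1]).sum()
            for i in range(n_ad):
                hin = max(0.0, 1 - (W[k, :-1] @ X_ad[i] + W[k, -1])) ** 2
                total += cfg.C * m[i, k] * hin
                total += cfg.t * m[i, k] ** 2 * max(
                    ((X_ad[i] - d[k]) ** 2).sum(), cfg.d_floor
                )
            for j in range(n_cn):
                hin = max(0.0, 1 + (W[k, :-1] @ X_cn[j] + W[k, -1])) ** 2
                total += cfg.C * cfg.cn_weight * hin
        assert np.isclose(J, total, rtol=1e-12)

    def test_single_point_hand_case(self):
        # K=1, one AD point at its centroid, w=0: J = C * 1 (unit hinge)
        x = np.array([[0.5, -0.2]])
        cfg = MOEConfig(K=2, C=3.0, t=1.0, cn_weight=1.0)
        W = np.zeros((1, 3))
        m = np.ones((1, 1))
        J = moe_objective(W, m, x, x, np.empty((0, 2)), cfg)
        assert np.isclose(J, cfg.C * 1.0 + cfg.t * cfg.d_floor)

    def test_hinge_component_linear_in_C(self):
        rng = np.random.default_rng(11)
        W = np.zeros((2, 4))
        X_ad = rng.normal(size=(5, 3))
        X_cn = rng.normal(size=(4, 3))
        m = rng.dirichlet(np.ones(2), size=5)
        d = rng.normal(size=(2, 3))
        base = MOEConfig(K=2, C=1.0, t=0.5)
        doubled = MOEConfig(K=2, C=2.0, t=0.5)
        j1 = moe_objective(W, m, d, X_ad, X_cn, base)
        j2 = moe_objective(W, m, d, X_ad, X_cn, doubled)
        scatter = base.t * float((m**2 * np.maximum(
            ((X_ad[:, None, :] - d[None]) ** 2).sum(-1), base.d_floor)).sum())
        assert np.isclose(j2 - scatter, 2 * (j1 - scatter), rtol=1e-12)


def two_cluster_residuals(seed=0, n_cn=40, n_ad=40, sep=6.0):
    rng = np.random.default_rng(seed)
    X_cn = rng.normal(0, 1, size=(n_cn, 6))
    half = n_ad // 2
    X_a = rng.normal(0, 1, size=(half, 6))
    X_a[:, :3] -= sep
    X_b = rng.normal(0, 1, size=(n_ad - half, 6))
    X_b[:, 3:] -= sep
    labels = np.array([1] * half + [2] * (n_ad - half))
    return residuals_from_arrays(X_cn, np.vstack([X_a, X_b])), labels


class TestFitMoe:
    def test_recovers_two_well_separated_subtypes(self):
        residuals, labels = two_cluster_residuals(seed=12)
        model = fit_moe(residuals, MOEConfig(K=2, seed=0))
        sol = hard_assign(model)
        assert adjusted_rand_score(labels, sol.labels) >= 0.9

    def test_objective_trace_non_increasing_over_seeds(self):
        residuals, _ = two_cluster_residuals(seed=13)
        for seed in range(5):
            model = fit_moe(residuals, MOEConfig(K=2, seed=seed, init="random"))
            tr = model.objective_trace
            assert (np.diff(tr) <= 1e-6 * (1 + np.abs(tr[:-1]))).all()

    def test_membership_rows_on_simplex(self):
        residuals, _ = two_cluster_residuals(seed=14)
        model = fit_moe(residuals, MOEConfig(K=2, seed=1))
        m = model.memberships
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)
        assert ((m >= -1e-12) & (m <= 1 + 1e-12)).all()

    def test_deterministic_given_seed(self):
        residuals, _ = two_cluster_residuals(seed=15)
        m1 = fit_moe(residuals, MOEConfig(K=2, seed=3))
        m2 = fit_moe(residuals, MOEConfig(K=2, seed=3))
        assert np.array_equal(m1.memberships, m2.memberships)
        assert np.array_equal(m1.weights, m2.weights)


class TestHardAssignAndPredict:
    def _model(self, memberships, weights=None):
        K = memberships.shape[1]
        P = 2
        return MOEModel(
            weights=np.zeros((K, P + 1)) if weights is None else weights,
            centroids=np.zeros((K, P)),
            memberships=memberships,
            objective_trace=np.array([0.0]),
            config=MOEConfig(K=K),
            ad_subject_ids=[f"a{i}" for i in range(len(memberships))],
            roi_names=["r0", "r1"],
            modality="density",
            cn_mean=np.zeros(P),
            cn_sd=np.ones(P),
        )

    def test_argmax_label(self):
        sol = hard_assign(self._model(np.array([[0.7, 0.1, 0.1, 0.1]])))
        assert sol.labels[0] == 1

    def test_tie_goes_to_lowest_index(self):
        sol = hard_assign(self._model(np.array([[0.5, 0.5, 0.0, 0.0]])))
        assert sol.labels[0] == 1

    def test_prediction_max_rule_and_reorder_invariance(self):
        W = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0]])
        model = self._model(np.array([[0.5, 0.5]]), weights=W)
        # on the AD side of exactly one expert
        assert predict_diagnosis(model, np.array([3.0, 0.0])) == "AD"
        # far on the CN side of all experts
        assert predict_diagnosis(model, np.array([-5.0, -5.0])) == "CN"
        model_swapped = self._model(np.array([[0.5, 0.5]]), weights=W[::-1].copy())
        for x in (np.array([3.0, 0.0]), np.array([-5.0, -5.0]), np.array([0.2, 0.9])):
            assert predict_diagnosis(model, x) == predict_diagnosis(model_swapped, x)
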