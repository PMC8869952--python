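"""Joint mixture-of-experts model: K sparse linear SVMs + fuzzy c-means.

The model assigns each AD subject a fuzzy membership row ``m_i`` on the
K-simplex while simultaneously training K L1-regularized squared-hinge
linear discriminants ("experts") that separate AD from CN, and K fuzzy
centroids that summarize the AD residual cloud.  The joint objective is

    J = sum_k [ 1/2 ||w_k||_1
                + C ( sum_{i in AD} m_ik h_ik + sum_{j in CN} s_CN h_jk )
                + t sum_{i in AD} m_ik^2 ||x_i - d_k||^2 ]

with h_ik = max(0, 1 - y_i w_k^T [x_i; 1])^2 the squared hinge, memberships
constrained to the simplex, and centroids d_k = sum_i m_ik^a x_i / sum_i
m_ik^a.  CN subjects carry the fixed weight ``cn_weight`` in every expert's
hinge term (they have no memberships); the fuzzification exponent defaults
to a = 2 so the centroid step is the exact minimizer of the m^2-weighted
scatter.  The intercept coordinate is appended to each weight vector and is
excluded from the L1 penalty.

Optimization alternates three block updates, each of which cannot increase
J: (a) the closed-form centroid update, (b) a warm-started monotone
proximal-gradient solve of each expert's L1 + weighted squared-hinge
subproblem, and (c) the exact per-subject KKT membership update.  The
objective trace is therefore non-increasing, and the fit is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .config import MOEConfig
from .residualize import ResidualTable

__all__ = [
    "MOEConfig",
    "MOEModel",
    "SubtypeSolution",
    "initialize_memberships",
    "update_centroids",
    "fit_expert_svm",
    "update_memberships",
    "moe_objective",
    "fit_moe",
    "hard_assign",
    "predict_diagnosis",
]


@dataclass
class MOEModel:
    """Fitted joint model for one modality.

    ``weights`` is K x (P+1) with the intercept appended last; ``centroids``
    K x P; ``memberships`` N_AD x K, rows on the simplex;
    ``objective_trace`` the J value after initialization and after each
    outer iteration.  ``cn_mean``/``cn_sd`` record the per-ROI
    standardization applied before fitting (identity when standardization
    is off) so that prediction uses the same feature space.
    """

    weights: np.ndarray
    centroids: np.ndarray
    memberships: np.ndarray
    objective_trace: np.ndarray
    config: MOEConfig
    ad_subject_ids: list[str]
    roi_names: list[str]
    modality: str
    cn_mean: np.ndarray
    cn_sd: np.ndarray
    n_restarts: int = 0

    @property
    def K(self) -> int:
        return self.weights.shape[0]


@dataclass
class SubtypeSolution:
    """Hard subtype labels (1..K) for the AD subjects of one modality."""

    subject_ids: list[str]
    labels: np.ndarray
    memberships: np.ndarray
    modality: str

    @property
    def K(self) -> int:
        return self.memberships.shape[1]

    def members(self, k: int) -> set[str]:
        """Subject-id set of subtype ``k`` (1-based)."""
        return {s for s, lab in zip(self.subject_ids, self.labels) if lab == k}


def _check_simplex(m: np.ndarray, atol: float = 1e-9) -> None:
    if (m < -atol).any() or (m > 1 + atol).any():
        raise ValueError("membership entries outside [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=atol):
        raise ValueError("membership rows must sum to 1")


def initialize_memberships(
    residuals_ad: np.ndarray,
    K: int,
    seed: int,
    method: str = "kmeans",
) -> np.ndarray:
    """Initial membership matrix for the AD subjects.

    ``kmeans`` runs K-means on the residuals and smooths the crisp labels
    to 0.9 on the assigned cluster and uniform elsewhere; ``random`` draws
    flat-Dirichlet rows.  Reproducible from ``seed``.
    """
    X = np.asarray(residuals_ad, dtype=float)
    n = X.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} AD subjects, got {n}")
    rng = np.random.default_rng(seed)
    if method == "random":
        return rng.dirichlet(np.ones(K), size=n)
    if method == "kmeans":
        km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2**31))
        labels = km.fit_predict(X)
        m = np.full((n, K), 0.1 / (K - 1))
        m[np.arange(n), labels] = 0.9
        return m
    raise ValueError(f"unknown initialization method {method!r}")


def update_centroids(
    memberships: np.ndarray, X_ad: np.ndarray, alpha: float
) -> np.ndarray:
    """Fuzzified centroid update d_k = sum_i m_ik^a x_i / sum_i m_ik^a."""
    m = np.asarray(memberships, dtype=float)
    _check_simplex(m)
    ma = m**alpha
    mass = ma.sum(axis=0)
    if (mass <= 0).any():
        k = int(np.argmax(mass <= 0))
        raise ValueError(f"expert {k + 1} has zero total membership mass")
    return (ma.T @ X_ad) / mass[:, None]


def _svm_objective(
    w: np.ndarray, X_aug: np.ndarray, y: np.ndarray, s: np.ndarray, C: float
) -> float:
    margins = 1.0 - y * (X_aug @ w)
    hinge = np.square(np.maximum(margins, 0.0))
    return 0.5 * np.abs(w[:-1]).sum() + C * float(s @ hinge)


def _soft_threshold(z: np.ndarray, r: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - r, 0.0)


def fit_expert_svm(
    X_aug: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray,
    C: float,
    w0: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> np.ndarray:
    """One expert's subproblem: 1/2 ||w||_1 + C sum_i s_i hinge_i^2.

    ``X_aug`` carries the intercept column last; the intercept coordinate is
    not penalized.  Solved by monotone proximal-gradient descent
    (ISTA with backtracking): a step is only accepted when the composite
    objective does not increase, so the returned objective never exceeds
    the objective at the warm start ``w0``.
    """
    X_aug = np.asarray(X_aug, dtype=float)
    y = np.asarray(y, dtype=float)
    s = np.asarray(sample_weights, dtype=float)
    if (s < 0).any():
        raise ValueError("sample weights must be nonnegative")
    if s[y > 0].sum() <= 0 or s[y < 0].sum() <= 0:
        raise ValueError("each class needs positive total weight")
    n, p = X_aug.shape
    w = np.zeros(p) if w0 is None else np.asarray(w0, dtype=float).copy()

    # Lipschitz constant of the smooth part: 2C lambda_max(X^T S X)
    Xs = X_aug * np.sqrt(s)[:, None]
    gram = Xs.T @ Xs
    L = 2.0 * C * float(np.linalg.eigvalsh(gram)[-1])
    base_step = 1.0 / max(L, 1e-12)

    f = _svm_objective(w, X_aug, y, s, C)
    for it in range(max_iter):
        margins = 1.0 - y * (X_aug @ w)
        active = np.maximum(margins, 0.0)
        grad = -2.0 * C * (X_aug.T @ (s * y * active))
        eta = base_step
        w_new, f_new = w, f
        for _ in range(30):
            cand = w - eta * grad
            cand[:-1] = _soft_threshold(cand[:-1], 0.5 * eta)
            f_cand = _svm_objective(cand, X_aug, y, s, C)
            if f_cand <= f + 1e-12:
                w_new, f_new = cand, f_cand
                break
            eta *= 0.5
        if f - f_new <= tol * (1.0 + abs(f)):
            w, f = w_new, f_new
            break
        w, f = w_new, f_new
    return w


def update_memberships(
    hinge_losses: np.ndarray,
    distances_sq: np.ndarray,
    C: float,
    t: float,
) -> np.ndarray:
    """Exact per-subject membership update on the simplex.

    For each AD subject the row minimizes sum_k [C m_k h_k + t m_k^2 D_k]
    subject to sum_k m_k = 1, m_k >= 0.  The KKT conditions give
    m_k = max(0, (lambda - C h_k) / (2 t D_k)) with the scalar lambda fixed
    by the sum constraint; the active set is found exactly by water-filling
    over the h-sorted experts (no iterative root-finding).
    """
    h = np.asarray(hinge_losses, dtype=float)
    D = np.asarray(distances_sq, dtype=float)
    if (h < 0).any() or (D <= 0).any():
        raise ValueError("hinge losses must be >= 0 and distances > 0 (floored)")
    if h.shape != D.shape:
        raise ValueError("hinge and distance matrices must have equal shape")
    a = C * h  # linear coefficient
    b = 2.0 * t * D  # quadratic coefficient: objective = a m + (b/2) m^2

    order = np.argsort(a, axis=1, kind="stable")
    a_s = np.take_along_axis(a, order, axis=1)
    b_s = np.take_along_axis(b, order, axis=1)
    inv_b = 1.0 / b_s
    lam_r = (1.0 + np.cumsum(a_s * inv_b, axis=1)) / np.cumsum(inv_b, axis=1)
    # active set = first r sorted experts; valid iff lambda_r exceeds the
    # largest included a; pick the largest valid r (classical water-filling)
    valid = lam_r > a_s
    r_star = valid.shape[1] - 1 - np.argmax(valid[:, ::-1], axis=1)
    lam = np.take_along_axis(lam_r, r_star[:, None], axis=1)
    m_s = np.maximum(0.0, (lam - a_s) * inv_b)
    m = np.empty_like(m_s)
    np.put_along_axis(m, order, m_s, axis=1)
    m /= m.sum(axis=1, keepdims=True)
    return m


def _split_residuals(residuals: ResidualTable):
    diag = residuals.diagnosis.to_numpy()
    ad_mask = diag == "AD"
    cn_mask = diag == "CN"
    if not ad_mask.any() or not cn_mask.any():
        raise ValueError("residual table must contain both CN and AD subjects")
    return ad_mask, cn_mask


def _standardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


def _hinge_sq(X_aug: np.ndarray, y, W: np.ndarray) -> np.ndarray:
    """Squared hinge of each subject under each expert: N x K."""
    margins = 1.0 - np.asarray(y)[:, None] * (X_aug @ W.T)
    return np.square(np.maximum(margins, 0.0))


def moe_objective(
    weights: np.ndarray,
    memberships: np.ndarray,
    centroids: np.ndarray,
    X_ad: np.ndarray,
    X_cn: np.ndarray,
    config: MOEConfig,
) -> float:
    """Evaluate the joint objective J at the given block variables.

    ``X_ad``/``X_cn`` are residual matrices in the (standardized) feature
    space without the intercept column; it is appended internally.
    """
    K, p1 = weights.shape
    X_ad_aug = np.column_stack([X_ad, np.ones(len(X_ad))])
    X_cn_aug = np.column_stack([X_cn, np.ones(len(X_cn))])
    h_ad = _hinge_sq(X_ad_aug, np.ones(len(X_ad)), weights)  # y = +1
    h_cn = _hinge_sq(X_cn_aug, -np.ones(len(X_cn)), weights)  # y = -1
    D = np.maximum(cdist(X_ad, centroids, "sqeuclidean"), config.d_floor)
    l1 = 0.5 * np.abs(weights[:, :-1]).sum()
    hinge_term = config.C * (
        float((memberships * h_ad).sum()) + config.cn_weight * float(h_cn.sum())
    )
    scatter = config.t * float((memberships**2 * D).sum())
    return l1 + hinge_term + scatter


def _restart_empty_experts(
    m: np.ndarray, empty: np.ndarray, K: int
) -> np.ndarray:
    """Re-seed empty experts from the most ambiguous subjects.

    Documented rule: the max(1, N // (2K)) subjects with the smallest
    maximum membership (most ambiguous) are reassigned 0.9 to the empty
    expert and uniform elsewhere; with several empty experts the ambiguous
    pool is split evenly among them.
    """
    m = m.copy()
    n = m.shape[0]
    ambiguity = -m.max(axis=1)
    pool = np.argsort(ambiguity, kind="stable")[::-1]  # most ambiguous first
    per = max(1, n // (2 * K))
    for j, k in enumerate(np.flatnonzero(empty)):
        chosen = pool[j * per : (j + 1) * per]
        m[chosen] = 0.1 / (K - 1)
        m[chosen, k] = 0.9
    return m


def fit_moe(residuals: ResidualTable, config: MOEConfig) -> MOEModel:
    """Fit the joint model by alternating minimization.

    Per outer iteration: centroid update, warm-started expert SVM fits,
    exact membership update; stops when |J_prev - J| <= tol (1 + |J_prev|)
    or after ``max_iter`` iterations.  If an expert's total membership mass
    collapses, its memberships are re-seeded from the most ambiguous
    subjects (at most 3 such restarts; the objective trace restarts too,
    since a re-seed is a jump, not a descent step).
    """
    config.validate()
    K = config.K
    ad_mask, cn_mask = _split_residuals(residuals)
    X_raw = residuals.values
    if config.standardize_residuals:
        cn_mean = X_raw[cn_mask].mean(axis=0)
        cn_sd = X_raw[cn_mask].std(axis=0, ddof=1)
        cn_sd = np.where(cn_sd <= 0, 1.0, cn_sd)
    else:
        cn_mean = np.zeros(X_raw.shape[1])
        cn_sd = np.ones(X_raw.shape[1])
    X = _standardize(X_raw, cn_mean, cn_sd)
    X_ad, X_cn = X[ad_mask], X[cn_mask]
    n_ad = len(X_ad)
    if n_ad < K:
        raise ValueError(f"need at least K={K} AD subjects, got {n_ad}")

    X_all_aug = np.column_stack([X, np.ones(len(X))])
    y = np.where(ad_mask, 1.0, -1.0)
    ad_rows = np.flatnonzero(ad_mask)
    cn_rows = np.flatnonzero(cn_mask)
    X_ad_aug = X_all_aug[ad_rows]

    def expert_weights(m_col: np.ndarray) -> np.ndarray:
        s = np.empty(len(X))
        s[ad_rows] = m_col
        s[cn_rows] = config.cn_weight
        return s

    m = initialize_memberships(X_ad, K, config.seed, config.init)
    W = np.zeros((K, X.shape[1] + 1))
    d = update_centroids(m, X_ad, config.alpha)
    for k in range(K):
        W[k] = fit_expert_svm(
            X_all_aug, y, expert_weights(m[:, k]), config.C,
            w0=W[k], max_iter=config.inner_max_iter, tol=config.inner_tol,
        )
    J = moe_objective(W, m, d, X_ad, X_cn, config)
    trace = [J]
    n_restarts = 0

    for _ in range(config.max_iter):
        d = update_centroids(m, X_ad, config.alpha)
        for k in range(K):
            W[k] = fit_expert_svm(
                X_all_aug, y, expert_weights(m[:, k]), config.C,
                w0=W[k], max_iter=config.inner_max_iter, tol=config.inner_tol,
            )
        h = _hinge_sq(X_ad_aug, np.ones(n_ad), W)
        D = np.maximum(cdist(X_ad, d, "sqeuclidean"), config.d_floor)
        m_new = update_memberships(h, D, config.C, config.t)
        empty = m_new.sum(axis=0) < 1e-8
        if empty.any():
            if n_restarts >= 3:
                raise RuntimeError(
                    "an expert repeatedly collapsed to zero membership mass"
                )
            n_restarts += 1
            m = _restart_empty_experts(m_new, empty, K)
            d = update_centroids(m, X_ad, config.alpha)
            J = moe_objective(W, m, d, X_ad, X_cn, config)
            trace = [J]
            continue
        m = m_new
        J_new = moe_objective(W, m, d, X_ad, X_cn, config)
        trace.append(J_new)
        if abs(J - J_new) <= config.tol * (1.0 + abs(J)):
            J = J_new
            break
        J = J_new

    return MOEModel(
        weights=W,
        centroids=d,
        memberships=m,
        objective_trace=np.asarray(trace),
        config=replace(config),
        ad_subject_ids=list(residuals.subject_ids.to_numpy()[ad_mask]),
        roi_names=residuals.roi_names,
        modality=residuals.modality,
        cn_mean=cn_mean,
        cn_sd=cn_sd,
        n_restarts=n_restarts,
    )


def hard_assign(model: MOEModel) -> SubtypeSolution:
    """Hard labels from memberships: argmax, ties to the lowest index."""
    labels = np.argmax(model.memberships, axis=1) + 1
    return SubtypeSolution(
        subject_ids=list(model.ad_subject_ids),
        labels=labels,
        memberships=model.memberships.copy(),
        modality=model.modality,
    )


def predict_diagnosis(model: MOEModel, x: np.ndarray) -> np.ndarray:
    """Classify residual vectors: AD iff any expert scores them positive.

    ``x`` is one residual vector of length P or a matrix of rows in the
    *unstandardized* residual space; the model's stored CN standardization
    is applied first.  The decision rule is max_k w_k^T [x; 1] > 0, which is
    invariant under expert reordering.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Xz = _standardize(X, model.cn_mean, model.cn_sd)
    X_aug = np.column_stack([Xz, np.ones(len(Xz))])
    scores = (X_aug @ model.weights.T).max(axis=1)
    out = np.where(scores > 0, "AD", "CN")
    return out if np.asarray(x).ndim > 1 else out[0]
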