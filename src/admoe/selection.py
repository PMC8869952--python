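"""Hyperparameter selection: CV accuracy, partition coefficient, W_r.

The (C, t) grid — powers of two over 2^-3 .. 2^10 by default — is scored
with three indicators per cell, each summarized as mean and SD over
stratified ten-fold cross-validation:

* ACC — diagnostic accuracy of the fitted experts on held-out subjects;
* BPC — Bezdek partition coefficient, mean sum of squared memberships
  (1 for a crisp partition, 1/K for a fully uniform one);
* W_r — maximum pairwise normalized inner product (cosine) among expert
  weight vectors, intercept excluded; low values mean distinct experts.

Because no single scalar criterion combines the three indicators, the
default selection rule is lexicographic — maximize ACC, break ties within
0.5 percentage points by higher BPC, remaining ties by lower W_r — and the
full ranked grid is always returned for manual override.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import MOEConfig, grid_values
from .moe import fit_moe, predict_diagnosis
from .residualize import ResidualTable

GRID_COLUMNS = [
    "C", "t",
    "acc_mean", "acc_sd",
    "bpc_mean", "bpc_sd",
    "wr_mean", "wr_sd",
]


def bezdek_partition_coefficient(memberships: np.ndarray) -> float:
    """BPC = (1/N) sum_i sum_k m_ik^2 for simplex membership rows."""
    m = np.asarray(memberships, dtype=float)
    if m.size == 0:
        raise ValueError("empty membership matrix")
    return float(np.square(m).sum() / m.shape[0])


def max_pairwise_inner_product(weights: np.ndarray) -> float:
    """Largest |cosine| between any two expert weight vectors.

    The intercept coordinate (last column) is excluded; any pair involving
    a zero-norm vector contributes 0.  Invariant to positive rescaling.
    """
    W = np.asarray(weights, dtype=float)[:, :-1]
    K = W.shape[0]
    if K < 2:
        raise ValueError("need at least 2 experts")
    norms = np.linalg.norm(W, axis=1)
    best = 0.0
    for k in range(K):
        for l in range(k + 1, K):
            if norms[k] == 0 or norms[l] == 0:
                continue
            cos = abs(float(W[k] @ W[l])) / (norms[k] * norms[l])
            best = max(best, cos)
    return best


def cross_validated_metrics(
    residuals: ResidualTable,
    config: MOEConfig,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-fold ACC (%), BPC and W_r under stratified K-fold CV.

    Folds are stratified by diagnosis and fixed by ``seed``; each training
    fold fits the full joint model and the held-out subjects are classified
    with the expert max rule.  BPC and W_r are computed on the training-fit
    model of each fold.
    """
    y = (residuals.diagnosis == "AD").to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects < {n_folds} folds; "
            "increase n or reduce folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % 2**31)
    rows = []
    for fold, (train, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        train_tab = residuals.subset(train)
        model = fit_moe(train_tab, replace(config, seed=config.seed))
        pred = predict_diagnosis(model, residuals.values[test])
        truth = residuals.diagnosis.to_numpy()[test]
        rows.append(
            {
                "fold": fold,
                "acc": 100.0 * float(np.mean(pred == truth)),
                "bpc": bezdek_partition_coefficient(model.memberships),
                "wr": max_pairwise_inner_product(model.weights),
            }
        )
    return pd.DataFrame(rows)


def cross_validated_accuracy(
    residuals: ResidualTable,
    config: MOEConfig,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of ten-fold CV accuracy, in percent."""
    folds = cross_validated_metrics(residuals, config, n_folds, seed)
    return float(folds["acc"].mean()), float(folds["acc"].std(ddof=1))


def _cell_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % 2**31)


def grid_search(
    residuals: ResidualTable,
    c_values: list[float] | None = None,
    t_values: list[float] | None = None,
    config: MOEConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill the (C, t) indicator grid; cells are independently re-seeded.

    Returns a DataFrame with one row per cell and columns ``GRID_COLUMNS``.
    The default grid is the 14 x 14 powers-of-two range 2^-3 .. 2^10.
    """
    if c_values is None:
        c_values = grid_values()
    if t_values is None:
        t_values = grid_values()
    if len(c_values) == 0 or len(t_values) == 0:
        raise ValueError("grid must be non-empty")
    if any(c <= 0 for c in c_values) or any(t <= 0 for t in t_values):
        raise ValueError("C and t grid values must be positive")
    if config is None:
        config = MOEConfig()
    rows = []
    index = 0
    for C in c_values:
        for t in t_values:
            cell_cfg = replace(config, C=float(C), t=float(t),
                               seed=_cell_seed(seed, index))
            folds = cross_validated_metrics(
                residuals, cell_cfg, n_folds=n_folds, seed=_cell_seed(seed, index)
            )
            rows.append(
                {
                    "C": float(C),
                    "t": float(t),
                    "acc_mean": float(folds["acc"].mean()),
                    "acc_sd": float(folds["acc"].std(ddof=1)),
                    "bpc_mean": float(folds["bpc"].mean()),
                    "bpc_sd": float(folds["bpc"].std(ddof=1)),
                    "wr_mean": float(folds["wr"].mean()),
                    "wr_sd": float(folds["wr"].std(ddof=1)),
                }
            )
            index += 1
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def select_parameters(grid: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Deterministic lexicographic selection over a filled grid.

    Maximize ``acc_mean``; cells within 0.5 percentage points of the best
    accuracy are ranked by higher ``bpc_mean``, then lower ``wr_mean``, then
    grid order.  Returns (C*, t*, ranked grid with a ``rank`` column).
    """
    if len(grid) == 0:
        raise ValueError("empty selection grid")
    g = grid.reset_index(drop=True).copy()
    best_acc = g["acc_mean"].max()
    in_band = g["acc_mean"] >= best_acc - 0.5
    # rank key: accuracy band first, then bpc desc, wr asc, grid order
    order = sorted(
        g.index,
        key=lambda i: (
            0 if in_band[i] else 1,
            -g.loc[i, "acc_mean"] if not in_band[i] else 0.0,
            -g.loc[i, "bpc_mean"],
            g.loc[i, "wr_mean"],
            i,
        ),
    )
    g["rank"] = 0
    for r, i in enumerate(order, start=1):
        g.loc[i, "rank"] = r
    g = g.sort_values("rank").reset_index(drop=True)
    return float(g.loc[0, "C"]), float(g.loc[0, "t"]), g
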