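"""Linear-discriminant orientation decoding with temporal generalization.

A shrinkage-regularized LDA (w = S^-1 (mu_cw - mu_ccw), with
S = (1-lambda) S_emp + lambda (tr(S_emp)/p) I and a Ledoit-Wolf style
analytic lambda by default) is trained at every timepoint and tested at
every timepoint, yielding a train-time x test-time matrix of AUC
(generalization across time, GAT).  Within-task decoding uses stratified
10-fold cross-validation; cross-task decoding trains on a localizer (with
stratum-balanced undersampling) and tests per design subcondition.
Group inference on GAT matrices is a one-sided cluster-corrected t test
against chance (AUC > 0.5) with 4-connected 2D clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
from sklearn.covariance import ledoit_wolf

from . import stats as stats_core
from .erp import EpochSet
from .stats import ClusterResult

__all__ = [
    "LDAModel",
    "fit_lda",
    "decision_values",
    "auc",
    "balance_undersample",
    "gat_within",
    "gat_cross",
    "activation_pattern",
    "cluster_test_gat",
    "extract_cluster_auc",
]

CLASS_ORDER = ("ccw", "cw")  # higher decision value => "cw"


@dataclass
class LDAModel:
    weights: np.ndarray
    intercept: float
    shrinkage: float
    class_order: tuple[str, str] = CLASS_ORDER


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "SUO":
        return (y == CLASS_ORDER[1]).astype(int)
    return y.astype(int)


def fit_lda(X: np.ndarray, y, shrinkage: str | float = "ledoit_wolf") -> LDAModel:
    """Fit the two-class shrinkage LDA at a single timepoint.

    ``X`` is trials x channels; ``y`` holds class labels ("ccw"/"cw" or
    0/1).  ``shrinkage`` is "ledoit_wolf" or a fixed lambda in [0, 1].
    """
    X = np.asarray(X, dtype=float)
    yb = _as_binary(y)
    if len(np.unique(yb)) < 2:
        raise ValueError("both classes must be present to fit the LDA")
    x0, x1 = X[yb == 0], X[yb == 1]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    centered = np.concatenate([x0 - mu0, x1 - mu1])
    p = X.shape[1]
    if shrinkage == "ledoit_wolf":
        cov, lam = ledoit_wolf(centered, assume_centered=True)
    else:
        lam = float(shrinkage)
        if not 0 <= lam <= 1:
            raise ValueError("fixed shrinkage must lie in [0, 1]")
        s = centered.T @ centered / len(centered)
        cov = (1 - lam) * s + lam * (np.trace(s) / p) * np.eye(p)
    w = np.linalg.solve(cov, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return LDAModel(weights=w, intercept=b, shrinkage=float(lam))


def decision_values(model: LDAModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ model.weights + model.intercept


def auc(scores, labels) -> float:
    """Area under the ROC curve: P(random positive outscores a random
    negative), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    yb = _as_binary(labels)
    n_pos = int(yb.sum())
    n_neg = len(yb) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    r = rankdata(scores)
    return float((r[yb == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _auc_matrix(dv: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Vectorized AUC over trailing map axes; ``dv`` is (trials, ...)."""
    n_pos = int(yb.sum())
    n_neg = len(yb) - n_pos
    r = rankdata(dv, axis=0)
    return (r[yb == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def balance_undersample(
    strata: pd.DataFrame | np.ndarray, seed: int = 0
) -> np.ndarray:
    """Random subset of trial indices equalizing stratum counts.

    ``strata`` is either an array of stratum labels or a DataFrame whose
    rows define strata (e.g. stimulus x accuracy); every stratum is
    undersampled to the minimum count.  Deterministic given the seed.
    """
    if isinstance(strata, pd.DataFrame):
        labels = strata.astype(str).agg("|".join, axis=1).to_numpy()
    else:
        labels = np.asarray(strata).astype(str)
    rng = np.random.default_rng(seed)
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any():  # pragma: no cover - unique() cannot return 0
        raise ValueError("empty stratum")
    m = counts.min()
    keep = []
    for lab in uniq:
        idx = np.flatnonzero(labels == lab)
        keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def _gat_scores(train_X, train_y, test_X, shrinkage):
    """Decision values (test_trials, train_times, test_times) and weights."""
    nT = train_X.shape[2]
    p = train_X.shape[1]
    W = np.empty((nT, p))
    B = np.empty(nT)
    for t in range(nT):
        m = fit_lda(train_X[:, :, t], train_y, shrinkage)
        W[t] = m.weights
        B[t] = m.intercept
    dv = np.einsum("tc,ncs->nts", W, test_X) + B[None, :, None]
    return dv, W, B


def gat_within(
    epochs: EpochSet | np.ndarray,
    labels=None,
    k: int = 10,
    seed: int = 0,
    shrinkage: str | float = "ledoit_wolf",
) -> np.ndarray:
    """Stratified k-fold temporal-generalization decoding, AUC averaged
    over folds.  Returns a (train_times, test_times) matrix."""
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if labels is None:
        labels = epochs.metadata["stimulus"].to_numpy()
    yb = _as_binary(labels)
    n0, n1 = int((yb == 0).sum()), int((yb == 1).sum())
    if k > min(n0, n1):
        raise ValueError(f"k={k} exceeds the minority class count {min(n0, n1)}")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(yb), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(yb == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    nT = X.shape[2]
    acc = np.zeros((nT, nT))
    for f in range(k):
        tr, te = folds != f, folds == f
        dv, _, _ = _gat_scores(X[tr], yb[tr], X[te], shrinkage)
        acc += _auc_matrix(dv, yb[te])
    return acc / k


def gat_cross(
    train_epochs: EpochSet,
    test_epochs: EpochSet,
    *,
    train_labels=None,
    subconditions: list[dict] | None = None,
    balance_strata: tuple[str, ...] = ("stimulus", "accuracy"),
    seed: int = 0,
    shrinkage: str | float = "ledoit_wolf",
) -> dict:
    """Cross-task temporal generalization: train on the localizer, test on
    the main task per subcondition.

    ``subconditions`` is a list of metadata filters (e.g.
    ``{"drug": "ATX", "accuracy": "correct", "confidence": "high"}``);
    the key ``"all"`` maps to the full test set.  Training trials are
    balanced by undersampling over ``balance_strata`` (columns present in
    the training metadata).  Returns {name_or_tuple: (T_train, T_test)
    AUC matrix}.
    """
    if train_epochs.channels != test_epochs.channels:
        raise ValueError("train and test epochs must share the channel layout")
    meta = train_epochs.metadata
    if train_labels is None:
        train_labels = meta["stimulus"].to_numpy()
    strata_cols = [c for c in balance_strata if c in meta.columns]
    strata = meta[strata_cols] if strata_cols else pd.DataFrame(
        {"stimulus": np.asarray(train_labels)}
    )
    keep = balance_undersample(strata, seed=seed)
    yb = _as_binary(np.asarray(train_labels)[keep])
    dv, _, _ = _gat_scores(
        train_epochs.data[keep], yb, test_epochs.data, shrinkage
    )
    y_test = _as_binary(test_epochs.metadata["stimulus"].to_numpy())

    out = {}
    conds = subconditions if subconditions is not None else [{"all": None}]
    for cond in conds:
        if "all" in cond:
            sel = np.ones(len(y_test), dtype=bool)
            key = "all"
        else:
            sel = np.ones(len(y_test), dtype=bool)
            for col, val in cond.items():
                sel &= test_epochs.metadata[col].to_numpy() == val
            key = tuple(cond.values())
        if sel.sum() == 0 or len(np.unique(y_test[sel])) < 2:
            out[key] = np.full(dv.shape[1:], np.nan)
            continue
        out[key] = _auc_matrix(dv[sel], y_test[sel])
    return out


def activation_pattern(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Interpretable channel topography: data covariance times weights."""
    X = np.asarray(X, dtype=float)
    s = np.cov(X, rowvar=False)
    return s @ model.weights


def cluster_test_gat(
    matrices: np.ndarray,
    *,
    chance: float = 0.5,
    cluster_alpha: float = 0.05,
    n_perm: int = 1024,
    seed: int = 0,
) -> ClusterResult:
    """One-sided (AUC > chance) cluster-corrected t test over the GAT plane.

    ``matrices`` is (subjects, T_train, T_test); clusters use 4-connected
    adjacency and a sign-flip permutation null on AUC - chance.
    """
    m = np.asarray(matrices, dtype=float) - chance
    if m.ndim != 3 or m.shape[0] < 2:
        raise ValueError("need (subjects, T, T) matrices with >= 2 subjects")
    df = m.shape[0] - 1
    threshold = float(sps.t.isf(cluster_alpha, df))
    return stats_core.permutation_engine(
        stats_core.one_sample_t_map, m,
        threshold=threshold, scheme="sign_flip", n_perm=n_perm,
        cluster_alpha=cluster_alpha, tail="greater", seed=seed,
    )


def extract_cluster_auc(
    gat_by_subcondition: list[dict], mask: np.ndarray
) -> pd.DataFrame:
    """Mean AUC within a cluster mask per subject and subcondition.

    ``gat_by_subcondition[subject]`` maps subcondition keys to GAT
    matrices.  Feeds the factorial rmANOVA and one-sample tests against
    chance.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cluster mask")
    rows = []
    for s, d in enumerate(gat_by_subcondition):
        for key, mat in d.items():
            if np.asarray(mat).shape != mask.shape:
                raise ValueError("GAT matrix shape does not match the mask")
            rows.append({
                "subject": s,
                "subcondition": key if isinstance(key, str) else "|".join(map(str, key)),
                "auc": float(np.nanmean(np.asarray(mat)[mask])),
            })
    return pd.DataFrame(rows)
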