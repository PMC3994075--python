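"""Dissimilarity PLS-DA: discriminant PLS regression on a distance matrix.

Instead of regressing class membership on the VOC table directly, the table
(rank-transformed, restricted to the selected VOCs) is first converted to a
Euclidean dissimilarity matrix D between samples; a PLS1 model

    y = D b + r

is then fit with class membership coded -1/+1.  The number of latent
variables is chosen by leave-one-out cross-validation (minimum RMSECV,
smaller model on ties).  The dissimilarity step makes the classifier mildly
non-linear in the original variables, which is the point: a plain linear
PLS-DA on these data fails while the dissimilarity variant does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import rank_transform


@dataclass
class DPLSDAModel:
    """Fitted dissimilarity-PLS model (one coefficient per training sample)."""

    b: np.ndarray                 # regression vector at n_lv, over train columns
    b_per_lv: list[np.ndarray]    # coefficient vectors for 1..max_lv
    y: np.ndarray                 # class codes (-1/+1) in training order
    residuals: np.ndarray         # y - fitted at n_lv
    n_lv: int
    rmsecv: np.ndarray | None
    col_mean: np.ndarray          # training column means of D
    y_mean: float
    train_index: list[str]
    classes: tuple[str, str]      # (negative, positive)
    weights: np.ndarray | None = None   # PLS weight vectors W
    loadings: np.ndarray | None = None  # PLS loading vectors P


def rank_map_apply(
    train_col: np.ndarray, query_col: np.ndarray
) -> np.ndarray:
    """Place query values on a column's training rank scale.

    The training (value -> average rank) map is linearly interpolated;
    queries outside the training range clamp to rank 1 or n.
    """
    from scipy.stats import rankdata

    ranks = rankdata(train_col)
    xs = np.unique(train_col)
    # average rank for duplicated training values
    ys = np.array([ranks[train_col == v].mean() for v in xs])
    return np.interp(query_col, xs, ys)


def rank_table_for_queries(
    train_table: pd.DataFrame, query_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-transform training data and map queries onto the same scale."""
    train_r = rank_transform(train_table)
    q = np.column_stack(
        [
            rank_map_apply(
                train_table[c].to_numpy(dtype=float),
                query_table[c].to_numpy(dtype=float),
            )
            for c in train_table.columns
        ]
    )
    query_r = pd.DataFrame(q, index=query_table.index, columns=train_table.columns)
    return train_r, query_r


def dissimilarity_matrix(
    query_table: pd.DataFrame, train_table: pd.DataFrame
) -> pd.DataFrame:
    """Euclidean distances between query rows and training rows."""
    if list(query_table.columns) != list(train_table.columns):
        raise ValueError("query and training tables must share the variable set")
    Q = query_table.to_numpy(dtype=float)
    T = train_table.to_numpy(dtype=float)
    d2 = (
        (Q**2).sum(axis=1)[:, None]
        + (T**2).sum(axis=1)[None, :]
        - 2.0 * Q @ T.T
    )
    D = np.sqrt(np.clip(d2, 0.0, None))
    return pd.DataFrame(D, index=query_table.index, columns=train_table.index)


def _pls1(
    Xc: np.ndarray, yc: np.ndarray, max_lv: int, return_wp: bool = False
):
    """PLS1 with deflation; returns the regression vector at each LV count.

    With ``return_wp`` also returns the weight and loading matrices, from
    which LV scores of new data can be computed as ``Xc W (P'W)^-1``.
    """
    X = Xc.copy()
    y = yc.copy()
    W, P, Q = [], [], []
    bs = []
    for _ in range(max_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-12:
            break
        p = X.T @ t / tt
        q = y @ t / tt
        X = X - np.outer(t, p)
        y = y - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        b = Wm @ np.linalg.solve(Pm.T @ Wm, np.asarray(Q))
        bs.append(b)
    if return_wp:
        Wm = np.column_stack(W) if W else np.zeros((Xc.shape[1], 0))
        Pm = np.column_stack(P) if P else np.zeros((Xc.shape[1], 0))
        return bs, Wm, Pm
    return bs


def fit_pls(
    D_train: pd.DataFrame,
    y: np.ndarray | pd.Series,
    max_lv: int | None = None,
    classes: tuple[str, str] = ("transient_wheeze", "asthma"),
) -> DPLSDAModel:
    """Fit the dissimilarity-PLS model at every LV count up to ``max_lv``.

    ``y`` may be -1/+1 codes or class labels matching ``classes``
    (negative, positive).  D's columns and y are mean-centered; at full
    rank the PLS solution coincides with ordinary least squares on the
    centered system.
    """
    yv = np.asarray(y)
    if yv.dtype.kind in "OU":
        yv = np.where(yv == classes[1], 1.0, -1.0)
    yv = yv.astype(float)
    D = D_train.to_numpy(dtype=float)
    n = D.shape[0]
    if max_lv is None:
        max_lv = min(n - 1, 15)
    col_mean = D.mean(axis=0)
    y_mean = float(yv.mean())
    Xc = D - col_mean
    yc = yv - y_mean
    rank = np.linalg.matrix_rank(Xc)
    if max_lv > rank:
        warnings.warn(f"max_lv {max_lv} exceeds rank {rank}; truncating")
        max_lv = rank
    bs, W, P = _pls1(Xc, yc, max_lv, return_wp=True)
    if not bs:  # e.g. constant y: nothing to regress on after centering
        bs = [np.zeros(D.shape[1])]
    b = bs[-1]
    fitted = Xc @ b + y_mean
    model = DPLSDAModel(
        b=b,
        b_per_lv=bs,
        y=yv,
        residuals=yv - fitted,
        n_lv=len(bs),
        rmsecv=None,
        col_mean=col_mean,
        y_mean=y_mean,
        train_index=list(D_train.index),
        classes=classes,
    )
    model.weights = W
    model.loadings = P
    return model


def loo_rmsecv(
    D_train: pd.DataFrame,
    y: np.ndarray | pd.Series,
    max_lv: int | None = None,
    classes: tuple[str, str] = ("transient_wheeze", "asthma"),
) -> tuple[np.ndarray, int]:
    """Leave-one-out RMSECV curve and the selected number of LVs.

    Each left-out sample is removed from both axes of D (it is neither a
    training row nor a dissimilarity landmark); the model refit on the
    reduced matrix predicts the held-out y from the sample's distances to
    the retained training samples.  The LV count minimizing RMSECV wins,
    smaller counts on ties.
    """
    n = D_train.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    yv = np.asarray(y)
    if yv.dtype.kind in "OU":
        yv = np.where(yv == classes[1], 1.0, -1.0)
    yv = yv.astype(float)
    if max_lv is None:
        max_lv = min(n - 2, 15)
    D = D_train.to_numpy(dtype=float)
    errs = np.full((n, max_lv), np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        Dm = D[np.ix_(keep, keep)]
        ym = yv[keep]
        col_mean = Dm.mean(axis=0)
        bs = _pls1(Dm - col_mean, ym - ym.mean(), min(max_lv, len(ym) - 1))
        d_i = D[i, keep] - col_mean
        for k, b in enumerate(bs):
            errs[i, k] = yv[i] - (d_i @ b + ym.mean())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rmsecv = np.sqrt(np.nanmean(errs**2, axis=0))
    n_lv = int(np.nanargmin(rmsecv)) + 1
    return rmsecv, n_lv


def fit_with_cv(
    D_train: pd.DataFrame,
    y: np.ndarray | pd.Series,
    max_lv: int | None = None,
    classes: tuple[str, str] = ("transient_wheeze", "asthma"),
) -> DPLSDAModel:
    """Select the LV count by LOO RMSECV, then fit at that complexity."""
    rmsecv, n_lv = loo_rmsecv(D_train, y, max_lv=max_lv, classes=classes)
    model = fit_pls(D_train, y, max_lv=n_lv, classes=classes)
    model.rmsecv = rmsecv
    model.n_lv = n_lv
    model.b = model.b_per_lv[min(n_lv, len(model.b_per_lv)) - 1]
    return model


def predict_dplsda(
    model: DPLSDAModel, D_query: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Predict class membership for query rows of a dissimilarity matrix.

    ``y_hat = (D - training column means) b + y_mean``; the positive class
    is assigned when y_hat exceeds the class-code midpoint (0 for -1/+1
    coding), with exact boundary values going to the negative class.
    """
    if list(D_query.columns) != model.train_index:
        raise ValueError("query columns must match the training samples")
    Dq = D_query.to_numpy(dtype=float)
    y_hat = (Dq - model.col_mean) @ model.b + model.y_mean
    labels = np.where(y_hat > 0.0, model.classes[1], model.classes[0])
    return y_hat, labels


def lv_scores(
    model: DPLSDAModel, D: pd.DataFrame, n_lv: int | None = None
) -> pd.DataFrame:
    """Latent-variable scores of (query or training) rows of D.

    Scores are ``(D - column means) W (P'W)^-1`` truncated to ``n_lv``
    components; used for the two-LV score plot of the fitted model.
    """
    if model.weights is None or model.weights.shape[1] == 0:
        raise ValueError("model carries no weight vectors")
    k = model.n_lv if n_lv is None else n_lv
    k = min(k, model.weights.shape[1])
    W = model.weights[:, :k]
    P = model.loadings[:, :k]
    R = W @ np.linalg.inv(P.T @ W)
    T = (D.to_numpy(dtype=float) - model.col_mean) @ R
    return pd.DataFrame(
        T, index=D.index, columns=[f"LV{i + 1}" for i in range(k)]
    )
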