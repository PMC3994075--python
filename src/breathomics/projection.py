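"""Proximity-PCA projection: a common low-dimensional view of the cohort.

Each binary random-forest model yields a proximity matrix over its training
samples.  PCA on that matrix gives per-sample scores; samples not used in
the model (the other class, the held-out subjects) are passed down the
trained trees to obtain their proximity vector to the training samples and
projected with the training loadings.  Combining the first two scores of
the transient-vs-asthma model (score 1, score 2) with the first score of
the healthy-vs-asthma model (score 3) yields the three-axis view in which
the three clinical groups separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rf import RFResult, compute_proximity


@dataclass
class ProximityPCA:
    """PCA of a training proximity matrix, reusable for projection."""

    loadings: np.ndarray           # (n_train, n_components)
    center: np.ndarray             # training column means
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame           # training-sample scores
    train_index: list[str]


def pca_on_proximity(
    proximity: pd.DataFrame, n_components: int = 2
) -> ProximityPCA:
    """PCA of a symmetric proximity matrix.

    Columns (proximity-to-each-training-sample) are mean-centered and the
    covariance eigendecomposed.  Component signs are fixed by making each
    component's largest-magnitude loading positive, so the pipeline is
    deterministic end to end.
    """
    P = proximity.to_numpy(dtype=float)
    if P.shape[0] != P.shape[1]:
        raise ValueError("proximity matrix must be square")
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("proximity matrix must be symmetric")
    center = P.mean(axis=0)
    Xc = P - center
    if np.allclose(Xc, 0):
        raise ValueError("degenerate proximity matrix (rank 0 after centering)")
    # eigendecomposition of the covariance via SVD of the centered matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / max(P.shape[0] - 1, 1)
    ratio = var / var.sum()
    k = min(n_components, (s > 1e-12 * s[0]).sum())
    loadings = Vt[:k].T
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
    scores = Xc @ loadings
    return ProximityPCA(
        loadings=loadings,
        center=center,
        explained_variance_ratio=ratio[:k],
        scores=pd.DataFrame(
            scores,
            index=proximity.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        train_index=list(proximity.index),
    )


def project_samples(
    rf: RFResult,
    table_new: pd.DataFrame,
    pca: ProximityPCA,
) -> pd.DataFrame:
    """Project samples into a model's proximity-PCA space.

    The new samples' proximity vectors to the model's training samples are
    computed by dropping the mixed set down the trained trees; centering
    with the training column means and multiplying by the loadings yields
    their scores.  Projecting the training samples themselves reproduces
    their PCA scores exactly.
    """
    train_tbl = pd.DataFrame(
        rf.X_train, index=rf.train_index, columns=rf.feature_names
    )
    new_only = table_new.loc[[i for i in table_new.index if i not in set(rf.train_index)]]
    mixed = pd.concat([train_tbl, new_only], axis=0)
    prox = compute_proximity(rf, mixed)
    V = prox.loc[table_new.index, rf.train_index].to_numpy(dtype=float)
    scores = (V - pca.center) @ pca.loadings
    return pd.DataFrame(scores, index=table_new.index, columns=pca.scores.columns)


def combine_projection_scores(
    scores_wheeze_model: pd.DataFrame,
    scores_healthy_model: pd.DataFrame,
    meta: pd.DataFrame,
    subset: str = "all",
) -> pd.DataFrame:
    """Join the two models' scores into the combined visualization frame.

    ``scores_wheeze_model`` (transient-vs-asthma) supplies score1/score2,
    ``scores_healthy_model`` (healthy-vs-asthma) supplies score3/score4.
    ``subset`` filters to all samples, the inclusion visit (visit 1), or
    each subject's final visit ("age6").
    """
    missing = set(scores_wheeze_model.index) ^ set(scores_healthy_model.index)
    if missing:
        raise ValueError(f"samples missing from one score set: {sorted(missing)[:5]}")
    m = meta.set_index("sample_id").loc[scores_wheeze_model.index]
    out = pd.DataFrame(index=scores_wheeze_model.index)
    out["score1"] = scores_wheeze_model.iloc[:, 0]
    out["score2"] = (
        scores_wheeze_model.iloc[:, 1]
        if scores_wheeze_model.shape[1] > 1
        else 0.0
    )
    out["score3"] = scores_healthy_model.iloc[:, 0]
    out["score4"] = (
        scores_healthy_model.iloc[:, 1]
        if scores_healthy_model.shape[1] > 1
        else 0.0
    )
    out["subject_id"] = m["subject_id"]
    out["class"] = m["class"]
    out["visit"] = m["visit"]
    if subset == "inclusion":
        out = out[out["visit"] == 1]
    elif subset == "age6":
        last = out.groupby("subject_id")["visit"].transform("max")
        out = out[out["visit"] == last]
    elif subset != "all":
        raise ValueError("subset must be 'all', 'inclusion' or 'age6'")
    return out
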