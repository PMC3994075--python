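"""Supervised core: subject-grouped splits and random-forest VOC selection.

The cohort is repeated-measures data (3-7 breath samples per child), so the
train/test split operates on subjects, never on samples: the Duplex
farthest-point algorithm runs on subject-level mean VOC profiles within
each class, and all of a subject's samples follow it to one side.

The forest is a bagged ensemble of CART trees (scikit-learn trees, sqrt(p)
features per split, grown to purity).  Bootstraps can be drawn over samples
(classical bagging) or over subjects — the latter keeps a child's repeated
measurements together, accounting for cluster-correlated data.  Out-of-bag
(oob) votes give the internal error estimate, oob permutation importance
the variable ranking, and shared-terminal-node proximities the similarity
matrix used downstream for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.tree import DecisionTreeClassifier


class InvalidSplitError(ValueError):
    pass


@dataclass
class SplitPlan:
    """Subject-disjoint train/test assignment."""

    train_subjects: list[str]
    test_subjects: list[str]
    train_samples: list[str]
    test_samples: list[str]


@dataclass
class RFResult:
    """A trained forest with its bootstrap bookkeeping."""

    trees: list[DecisionTreeClassifier]
    inbag: np.ndarray            # (n_trees, n_samples) bootstrap counts
    classes_: np.ndarray         # label order used for votes
    feature_names: list[str]
    train_index: list[str]       # sample ids in training order
    oob_error: float
    oob_votes: np.ndarray        # (n_samples, 2) oob vote fractions
    X_train: np.ndarray

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float


def _duplex(X: np.ndarray, n_test: int) -> tuple[list[int], list[int]]:
    """Duplex assignment of rows of X: returns (train_idx, test_idx).

    The two mutually farthest points seed the training set; the two
    farthest of the remainder seed the test set; thereafter points are
    assigned alternately (train first) by maximal minimum distance to the
    receiving set, until the test set reaches ``n_test``; the remainder
    goes to training.
    """
    n = X.shape[0]
    D = cdist(X, X)
    remaining = set(range(n))

    def farthest_pair(pool):
        pool = sorted(pool)
        sub = D[np.ix_(pool, pool)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        return pool[i], pool[j]

    def next_point(pool, assigned):
        pool = sorted(pool)
        dmin = D[np.ix_(pool, sorted(assigned))].min(axis=1)
        return pool[int(np.argmax(dmin))]

    train: list[int] = []
    test: list[int] = []
    i, j = farthest_pair(remaining)
    train += [i, j]
    remaining -= {i, j}
    if n_test >= 1 and len(remaining) >= 2:
        i, j = farthest_pair(remaining)
        if n_test == 1:
            test.append(i)
            remaining.discard(i)
        else:
            test += [i, j]
            remaining -= {i, j}
    turn = "train"
    while remaining:
        if turn == "train" or len(test) >= n_test:
            p = next_point(remaining, train)
            train.append(p)
        else:
            p = next_point(remaining, test)
            test.append(p)
        remaining.discard(p)
        turn = "test" if turn == "train" else "train"
    return train, test


def duplex_split(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    test_fraction: float = 0.2,
    min_subjects: int = 5,
) -> SplitPlan:
    """Subject-grouped Duplex split, stratified by class.

    Within each class, subjects are represented by the mean VOC profile of
    their samples and split by the Duplex algorithm so the test set holds
    ``test_fraction`` of that class's subjects (at least one).  All samples
    of a test subject are held out together.  Deterministic given the table.
    """
    m = meta.set_index("sample_id").loc[table.index]
    train_subj: list[str] = []
    test_subj: list[str] = []
    for cls, sub in m.groupby("class", sort=True):
        subjects = sorted(sub["subject_id"].unique())
        if len(subjects) < min_subjects:
            raise InvalidSplitError(
                f"class {cls} has {len(subjects)} subjects; need >= {min_subjects}"
            )
        profiles = np.vstack(
            [
                table.loc[sub.index[sub["subject_id"] == s]].mean(axis=0).to_numpy()
                for s in subjects
            ]
        )
        n_test = max(1, round(test_fraction * len(subjects)))
        tr, te = _duplex(profiles, n_test)
        train_subj += [subjects[i] for i in tr]
        test_subj += [subjects[i] for i in te]
    train_samples = list(m.index[m["subject_id"].isin(train_subj)])
    test_samples = list(m.index[m["subject_id"].isin(test_subj)])
    return SplitPlan(
        train_subjects=sorted(train_subj),
        test_subjects=sorted(test_subj),
        train_samples=train_samples,
        test_samples=test_samples,
    )


def train_forest(
    train_table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_trees: int = 1000,
    resample_unit: str = "sample",
    subjects: pd.Series | None = None,
    seed: int = 0,
    max_features: str | float = "sqrt",
    min_samples_leaf: int = 1,
) -> RFResult:
    """Train a bagged CART ensemble on a binary problem.

    ``resample_unit="sample"`` draws classical n-out-of-n bootstraps;
    ``"subject"`` draws subjects with replacement and includes all of a
    drawn subject's samples, which respects the cluster-correlation of
    repeated measurements (``subjects`` is then required).  oob votes come
    only from trees whose bootstrap excluded the sample (for subject
    resampling: excluded the subject).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got {list(classes)}")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("need at least 2 samples per class")
    X = train_table.to_numpy(dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    if resample_unit == "subject":
        if subjects is None:
            raise ValueError("subject resampling requires a subjects vector")
        subj = np.asarray(subjects)
        uniq = np.unique(subj)
        subj_rows = {s: np.flatnonzero(subj == s) for s in uniq}
    elif resample_unit != "sample":
        raise ValueError("resample_unit must be 'sample' or 'subject'")

    trees = []
    inbag = np.zeros((n_trees, n), dtype=np.int32)
    vote_counts = np.zeros((n, 2))
    for t in range(n_trees):
        if resample_unit == "sample":
            draw = rng.integers(0, n, size=n)
            counts = np.bincount(draw, minlength=n)
        else:
            sdraw = rng.integers(0, len(uniq), size=len(uniq))
            counts = np.zeros(n, dtype=np.int64)
            for k in sdraw:
                counts[subj_rows[uniq[k]]] += 1
            draw = np.repeat(np.arange(n), counts)
        inbag[t] = counts
        tree = DecisionTreeClassifier(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[draw], y[draw])
        trees.append(tree)
        oob = counts == 0
        if oob.any():
            pred = tree.predict(X[oob])
            for ci, c in enumerate(classes):
                vote_counts[np.flatnonzero(oob)[pred == c], ci] += 1

    covered = vote_counts.sum(axis=1) > 0
    oob_votes = np.zeros_like(vote_counts)
    oob_votes[covered] = vote_counts[covered] / vote_counts[covered].sum(
        axis=1, keepdims=True
    )
    oob_pred = classes[np.argmax(vote_counts, axis=1)]
    oob_error = float(np.mean(oob_pred[covered] != y[covered]))
    return RFResult(
        trees=trees,
        inbag=inbag,
        classes_=classes,
        feature_names=list(train_table.columns),
        train_index=list(train_table.index),
        oob_error=oob_error,
        oob_votes=oob_votes,
        X_train=X,
    )


def permutation_importance(
    rf: RFResult,
    train_table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int = 0,
) -> pd.Series:
    """Mean decrease in per-tree oob accuracy under value permutation.

    For each tree, the accuracy on its oob cases is compared with the
    accuracy after permuting one variable's values among those oob cases;
    the drop, averaged over trees, is the variable's importance.  A
    constant variable is invariant under permutation, so its importance is
    exactly zero.
    """
    X = train_table.to_numpy(dtype=float)
    y = np.asarray(labels)
    p = X.shape[1]
    drops = np.zeros(p)
    n_used = 0
    rng = np.random.default_rng(seed)
    for t, tree in enumerate(rf.trees):
        oob = np.flatnonzero(rf.inbag[t] == 0)
        if len(oob) == 0:
            continue
        n_used += 1
        Xo = X[oob]
        yo = y[oob]
        acc0 = np.mean(tree.predict(Xo) == yo)
        perm = rng.permutation(len(oob))
        for j in range(p):
            col = Xo[:, j]
            if np.all(col == col[0]):
                continue  # permutation is a no-op
            Xp = Xo.copy()
            Xp[:, j] = col[perm]
            drops[j] += acc0 - np.mean(tree.predict(Xp) == yo)
    return pd.Series(drops / max(n_used, 1), index=train_table.columns,
                     name="importance")


def compute_proximity(rf: RFResult, table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of trees in which two samples share a terminal node.

    Works for any sample set the forest can score (training, held-out, or
    mixed), which is what the proximity-PCA projection needs.
    """
    if list(table.columns) != rf.feature_names:
        raise ValueError("table columns do not match the training variables")
    X = table.to_numpy(dtype=float)
    n = X.shape[0]
    prox = np.zeros((n, n))
    for tree in rf.trees:
        leaves = tree.apply(X)
        prox += leaves[:, None] == leaves[None, :]
    prox /= rf.n_trees
    return pd.DataFrame(prox, index=table.index, columns=table.index)


def predict_samples(
    rf: RFResult, table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample vote fractions and majority-vote classes.

    An exact 50/50 vote goes to the first class in label order (documented
    tie-break; with 1000 trees this is rare).
    """
    if list(table.columns) != rf.feature_names:
        raise ValueError("table columns do not match the training variables")
    X = table.to_numpy(dtype=float)
    counts = np.zeros((X.shape[0], 2))
    for tree in rf.trees:
        pred = tree.predict(X)
        for ci, c in enumerate(rf.classes_):
            counts[pred == c, ci] += 1
    votes = counts / rf.n_trees
    classes = pd.Series(
        rf.classes_[np.argmax(votes, axis=1)], index=table.index, name="predicted"
    )
    votes_df = pd.DataFrame(votes, index=table.index, columns=rf.classes_)
    return votes_df, classes


def aggregate_subject_votes(
    classes: pd.Series, meta: pd.DataFrame
) -> pd.Series:
    """Per-subject modal predicted class; exact ties become "undefined"."""
    subjects = meta.set_index("sample_id").loc[classes.index, "subject_id"]
    out = {}
    for subj, idx in subjects.groupby(subjects).groups.items():
        counts = classes.loc[idx].value_counts()
        top = counts[counts == counts.max()]
        out[subj] = top.index[0] if len(top) == 1 else "undefined"
    return pd.Series(out, name="subject_class").sort_index()


def roc_analysis(
    vote_fractions: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    positive_class=None,
) -> ROCResult:
    """ROC curve over the unique vote-fraction thresholds.

    ``vote_fractions`` scores the positive class.  AUC by trapezoid over
    (1-specificity, sensitivity); the optimal cutoff maximizes Youden's
    J = sensitivity + specificity - 1, ties resolved toward 0.5.
    """
    s = np.asarray(vote_fractions, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("ROC needs exactly two classes in the labels")
    pos = positive_class if positive_class is not None else classes[-1]
    yb = y == pos
    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = s >= thr
        sens[i] = np.mean(pred[yb]) if yb.any() else np.nan
        spec[i] = np.mean(~pred[~yb]) if (~yb).any() else np.nan
    fpr = 1 - spec
    auc = float(np.trapezoid(sens, fpr))
    j = sens + spec - 1
    best = j == j.max()
    finite = thresholds[best]
    finite = np.where(np.isinf(finite), 1.0, finite)
    optimal = float(finite[np.argmin(np.abs(finite - 0.5))])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=optimal,
    )


def select_discriminatory_vocs(
    importance_model1: pd.Series,
    importance_model2: pd.Series,
    k: int = 12,
) -> list[str]:
    """Union of the top-k variables of the two binary models.

    Ties at rank k break by variable id, keeping the selection
    deterministic.  Shared top variables collapse, so the union has between
    k and 2k members.
    """
    if set(importance_model1.index) != set(importance_model2.index):
        raise ValueError("importance vectors cover different variables")
    if k > len(importance_model1):
        raise ValueError("k exceeds the number of variables")
    union: set[str] = set()
    for imp in (importance_model1, importance_model2):
        df = imp.rename("imp").rename_axis("var").reset_index()
        df = df.sort_values(["imp", "var"], ascending=[False, True])
        union |= set(df["var"].head(k))
    return sorted(union)
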