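"""Forest training, validation and VOC selection contracts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from breathomics import rf


def toy_meta(n, subjects=None, classes=None):
    subjects = subjects or [f"p{i}" for i in range(n)]
    classes = classes or ["asthma"] * n
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "subject_id": subjects,
            "class": classes,
            "visit": 1,
        }
    )


def separable_toy(n=100, seed=0):
    """Two well-separated Gaussian clouds in 2-D."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, (n // 2, 2)), rng.normal(6, 1, (n // 2, 2))]
    )
    y = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
    table = pd.DataFrame(
        X, index=[f"s{i}" for i in range(n)], columns=["v1", "v2"]
    )
    return table, pd.Series(y, index=table.index)


class TestDuplex:
    def _cohort(self, n_per_class=10, seed=0):
        rng = np.random.default_rng(seed)
        rows, meta_rows = [], []
        i = 0
        for cls in ("healthy", "transient_wheeze", "asthma"):
            for _ in range(n_per_class):
                subj = f"p{i}"
                for v in range(1, 4):
                    rows.append(rng.normal(0, 1, 6))
                    meta_rows.append((f"s{i}_{v}", subj, cls, v))
                i += 1
        meta = pd.DataFrame(
            meta_rows, columns=["sample_id", "subject_id", "class", "visit"]
        )
        table = pd.DataFrame(
            rows, index=meta["sample_id"], columns=[f"v{j}" for j in range(6)]
        )
        return table, meta

    def test_subject_disjoint_stratified_split(self):
        table, meta = self._cohort()
        plan = rf.duplex_split(table, meta, 0.2)
        assert not set(plan.train_subjects) & set(plan.test_subjects)
        m = meta.set_index("sample_id")
        per_class = m.groupby("class")["subject_id"].nunique()
        test_cls = (
            m[m["subject_id"].isin(plan.test_subjects)]
            .groupby("class")["subject_id"]
            .nunique()
        )
        for cls in per_class.index:
            assert abs(test_cls[cls] - 0.2 * per_class[cls]) <= 1

    def test_all_samples_of_test_subject_held_out(self):
        table, meta = self._cohort()
        plan = rf.duplex_split(table, meta, 0.2)
        m = meta.set_index("sample_id")
        train_subj_seen = set(m.loc[plan.train_samples, "subject_id"])
        test_subj_seen = set(m.loc[plan.test_samples, "subject_id"])
        assert not train_subj_seen & test_subj_seen
        assert len(plan.train_samples) + len(plan.test_samples) == len(meta)

    def test_duplex_hand_trace_on_four_points(self):
        """First farthest pair -> train, second farthest pair -> test."""
        X = np.array([[0.0], [10.0], [4.0], [6.0]])
        train, test = rf._duplex(X, n_test=2)
        assert set(train[:2]) == {0, 1}  # the mutually farthest pair
        assert set(test[:2]) == {2, 3}

    def test_small_class_rejected(self):
        table, meta = self._cohort(n_per_class=4)
        with pytest.raises(rf.InvalidSplitError):
            rf.duplex_split(table, meta, 0.2)


class TestTrainForest:
    def test_separable_toy_low_oob_error(self):
        table, y = separable_toy()
        res = rf.train_forest(table, y, n_trees=200, seed=1)
        assert res.oob_error <= 0.05

    def test_deterministic_for_fixed_seed(self):
        table, y = separable_toy()
        a = rf.train_forest(table, y, n_trees=50, seed=3)
        b = rf.train_forest(table, y, n_trees=50, seed=3)
        assert a.oob_error == b.oob_error
        np.testing.assert_array_equal(a.inbag, b.inbag)
        np.testing.assert_array_equal(a.oob_votes, b.oob_votes)

    def test_subject_bootstrap_keeps_clusters_together(self):
        table, y = separable_toy(n=40, seed=2)
        subjects = pd.Series(
            [f"p{i // 4}" for i in range(40)], index=table.index
        )
        res = rf.train_forest(
            table, y, n_trees=30, resample_unit="subject",
            subjects=subjects, seed=4,
        )
        for t in range(res.n_trees):
            counts = res.inbag[t]
            for s in subjects.unique():
                rows = np.flatnonzero((subjects == s).to_numpy())
                assert len(set(counts[rows])) == 1  # all-in or all-out together

    def test_single_class_rejected(self):
        table, _ = separable_toy(n=10)
        with pytest.raises(ValueError):
            rf.train_forest(table, pd.Series(["a"] * 10, index=table.index))


class TestPermutationImportance:
    def test_constant_variable_importance_exactly_zero(self):
        table, y = separable_toy(n=60, seed=5)
        table["const"] = 3.14
        res = rf.train_forest(table, y, n_trees=50, seed=5)
        imp = rf.permutation_importance(res, table, y, seed=5)
        assert imp["const"] == 0.0

    def test_informative_variable_ranks_first(self):
        rng = np.random.default_rng(6)
        n = 120
        X = rng.normal(0, 1, (n, 10))
        y = np.array(["neg"] * (n // 2) + ["pos"] * (n // 2))
        X[n // 2 :, 0] += 3.0  # the single informative variable
        table = pd.DataFrame(
            X, index=[f"s{i}" for i in range(n)],
            columns=[f"v{j}" for j in range(10)],
        )
        res = rf.train_forest(table, pd.Series(y, index=table.index),
                              n_trees=200, seed=6)
        imp = rf.permutation_importance(res, table,
                                        pd.Series(y, index=table.index), seed=6)
        assert imp.idxmax() == "v0"
        noise = imp.drop("v0")
        assert imp["v0"] > 5 * noise.abs().max()

    def test_pure_noise_importance_near_zero(self):
        rng = np.random.default_rng(7)
        table, y = separable_toy(n=80, seed=7)
        table["noise"] = rng.normal(0, 1, 80)
        res = rf.train_forest(table, y, n_trees=200, seed=7)
        imp = rf.permutation_importance(res, table, y, seed=7)
        assert abs(imp["noise"]) < 0.02


class TestProximity:
    def test_diagonal_unit_and_symmetric(self):
        table, y = separable_toy(n=30, seed=8)
        res = rf.train_forest(table, y, n_trees=50, seed=8)
        prox = rf.compute_proximity(res, table)
        P = prox.to_numpy()
        np.testing.assert_allclose(np.diag(P), 1.0)
        np.testing.assert_allclose(P, P.T)
        assert (P >= 0).all() and (P <= 1).all()

    def test_identical_rows_have_unit_proximity(self):
        table, y = separable_toy(n=30, seed=9)
        table.iloc[1] = table.iloc[0]
        res = rf.train_forest(table, y, n_trees=50, seed=9)
        prox = rf.compute_proximity(res, table)
        assert prox.iloc[0, 1] == 1.0

    def test_hand_built_two_tree_forest(self):
        """A pair co-landing in 1 of 2 stumps has proximity 0.5."""
        X = pd.DataFrame({"v": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        t1 = DecisionTreeClassifier(max_depth=1).fit(
            [[0.0], [1.0], [2.0]], [0, 1, 1]
        )  # splits a | b, c
        t2 = DecisionTreeClassifier(max_depth=1).fit(
            [[0.0], [1.0], [2.0]], [0, 0, 1]
        )  # splits a, b | c
        res = rf.RFResult(
            trees=[t1, t2],
            inbag=np.ones((2, 3), dtype=np.int32),
            classes_=np.array([0, 1]),
            feature_names=["v"],
            train_index=["a", "b", "c"],
            oob_error=0.0,
            oob_votes=np.zeros((3, 2)),
            X_train=X.to_numpy(),
        )
        prox = rf.compute_proximity(res, X)
        assert prox.loc["a", "b"] == 0.5  # together only in t2
        assert prox.loc["b", "c"] == 0.5  # together only in t1
        assert prox.loc["a", "c"] == 0.0

    def test_schema_mismatch_rejected(self):
        table, y = separable_toy(n=20, seed=10)
        res = rf.train_forest(table, y, n_trees=10, seed=10)
        with pytest.raises(ValueError):
            rf.compute_proximity(res, table.rename(columns={"v1": "x"}))


class TestPredict:
    def test_resubstitution_on_separable_toy(self):
        table, y = separable_toy(n=60, seed=11)
        res = rf.train_forest(table, y, n_trees=100, seed=11)
        votes, classes = rf.predict_samples(res, table)
        assert (classes == y).mean() == 1.0
        np.testing.assert_allclose(votes.sum(axis=1), 1.0)
        assert ((votes >= 0) & (votes <= 1)).all().all()

    def test_single_stump_matches_its_rule(self):
        table = pd.DataFrame(
            {"v1": [0.0, 1.0, 5.0, 6.0], "v2": 0.0},
            index=list("abcd"),
        )
        y = pd.Series(["neg", "neg", "pos", "pos"], index=table.index)
        stump = DecisionTreeClassifier(max_depth=1).fit(table, y)
        res = rf.RFResult(
            trees=[stump],
            inbag=np.ones((1, 4), dtype=np.int32),
            classes_=np.array(["neg", "pos"]),
            feature_names=["v1", "v2"],
            train_index=list("abcd"),
            oob_error=0.0,
            oob_votes=np.zeros((4, 2)),
            X_train=table.to_numpy(),
        )
        votes, classes = rf.predict_samples(res, table)
        np.testing.assert_array_equal(classes.to_numpy(), stump.predict(table))
        assert set(votes.to_numpy().ravel()) <= {0.0, 1.0}


class TestSubjectVotes:
    def test_majority_and_tie(self):
        meta = toy_meta(5, subjects=["p1", "p1", "p1", "p2", "p2"])
        pred = pd.Series(
            ["asthma", "asthma", "transient_wheeze", "asthma",
             "transient_wheeze"],
            index=meta["sample_id"],
        )
        out = rf.aggregate_subject_votes(pred, meta)
        assert out["p1"] == "asthma"
        assert out["p2"] == "undefined"

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(12)
        n = 60
        subjects = [f"p{i // 3}" for i in range(n)]
        meta = toy_meta(n, subjects=subjects)
        pred = pd.Series(
            rng.choice(["a", "b", "c"], size=n), index=meta["sample_id"]
        )
        out = rf.aggregate_subject_votes(pred, meta)
        for subj in set(subjects):
            votes = [
                pred[f"s{i}"] for i in range(n) if subjects[i] == subj
            ]
            counts = {c: votes.count(c) for c in set(votes)}
            top = max(counts.values())
            winners = [c for c, k in counts.items() if k == top]
            expected = winners[0] if len(winners) == 1 else "undefined"
            assert out[subj] == expected


class TestRoc:
    def test_perfectly_ordered_scores(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["neg", "neg", "pos", "pos"])
        res = rf.roc_analysis(scores, labels, positive_class="pos")
        assert res.auc == 1.0

    def test_four_point_hand_case(self):
        res = rf.roc_analysis(
            np.array([0.1, 0.4, 0.6, 0.9]), np.array([0, 0, 1, 1]),
            positive_class=1,
        )
        assert res.auc == 1.0
        # at the reported cutoff both error rates vanish
        i = np.argmin(np.abs(res.thresholds - res.optimal_cutoff))
        assert res.sensitivity[i] == 1.0 and res.specificity[i] == 1.0

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(13)
        scores = rng.random(2000)
        labels = rng.choice(["neg", "pos"], size=2000)
        res = rf.roc_analysis(scores, labels, positive_class="pos")
        assert 0.45 <= res.auc <= 0.55

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rf.roc_analysis(np.array([0.1, 0.9]), np.array(["a", "a"]))


class TestVocSelection:
    def _imp(self, values):
        return pd.Series(values, index=[f"v{j}" for j in range(len(values))])

    def test_shared_top_variables_collapse(self):
        rng = np.random.default_rng(14)
        base = rng.random(40)
        imp1 = self._imp(base)
        imp2 = imp1.copy()
        # displace 5 of model 1's top 12 out of model 2's top 12
        top = imp1.sort_values(ascending=False).index[:12]
        imp2[top[:5]] = 0.0
        union = rf.select_discriminatory_vocs(imp1, imp2, k=12)
        assert len(union) == 17

    def test_identical_and_disjoint_models(self):
        imp1 = self._imp(np.arange(30, dtype=float))
        assert len(rf.select_discriminatory_vocs(imp1, imp1, k=12)) == 12
        imp2 = -imp1  # reversed ranking -> disjoint top lists
        assert len(rf.select_discriminatory_vocs(imp1, imp2, k=12)) == 24

    def test_excessive_k_rejected(self):
        imp = self._imp(np.arange(5, dtype=float))
        with pytest.raises(ValueError):
            rf.select_discriminatory_vocs(imp, imp, k=6)
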