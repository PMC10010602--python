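"""Feature selection, splitting, CV training, prediction and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lfqpipe as lp
from lfqpipe.modeling import greedy_prune
from conftest import make_design, make_matrix


def _de_and_matrix(n_sig=30, n_samples=12, seed=0):
    """Complete matrix plus a DEResult flagging the first n_sig proteins."""
    rng = np.random.default_rng(seed)
    n = n_sig + 20
    groups = ["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2)
    m = make_matrix(rng.normal(20, 1, (n, n_samples)), groups, stage="imputed")
    adj = np.r_[np.linspace(1e-6, 1e-3, n_sig), np.linspace(0.2, 0.9, 20)]
    table = pd.DataFrame({
        "protein_id": m.protein_ids,
        "log2FC": np.r_[np.full(n_sig, 2.0), np.zeros(20)],
        "t": np.zeros(n),
        "p_value": adj / 2,
        "adj_p_value": adj,
        "significant": np.r_[np.ones(n_sig, bool), np.zeros(20, bool)],
    }).sort_values("adj_p_value").reset_index(drop=True)
    return lp.DEResult(table=table, contrast=("a", "b")), m


class TestSelectFeatures:
    def test_top_n_caps_candidates(self):
        de, m = _de_and_matrix(n_sig=30)
        mf = lp.select_features(de, m, top_n=20, corr_cut=1.1)
        assert len(mf.features.columns) == 20
        assert mf.features.shape[0] == 12

    def test_fewer_significant_than_top_n_keeps_all(self):
        de, m = _de_and_matrix(n_sig=5)
        mf = lp.select_features(de, m, top_n=20, corr_cut=1.1)
        assert len(mf.features.columns) == 5

    def test_no_significant_proteins_is_error(self):
        de, m = _de_and_matrix(n_sig=1)
        de.table["significant"] = False
        with pytest.raises(ValueError, match="nothing to model"):
            lp.select_features(de, m)

    def test_zero_variance_feature_dropped(self):
        de, m = _de_and_matrix(n_sig=5)
        first = de.table["protein_id"].iloc[0]
        m.values.loc[first] = 7.0
        mf = lp.select_features(de, m, corr_cut=1.1)
        assert first not in mf.features.columns

    def test_greedy_rule_hand_example(self):
        corr = pd.DataFrame(
            [[1.0, 0.95, 0.60], [0.95, 1.0, 0.10], [0.60, 0.10, 1.0]],
            index=list("abc"), columns=list("abc"))
        # f1 has mean |r| 0.775 > f2's 0.525 -> f1 ("a") removed
        assert greedy_prune(corr, list("abc"), 0.90) == ["b", "c"]

    def test_greedy_tie_removes_later_feature(self):
        corr = pd.DataFrame([[1.0, 0.95], [0.95, 1.0]],
                            index=list("ab"), columns=list("ab"))
        assert greedy_prune(corr, list("ab"), 0.90) == ["a"]

    def test_selection_invariant_to_input_ordering(self):
        de, m = _de_and_matrix(n_sig=10)
        shuffled = lp.DEResult(
            table=de.table.sample(frac=1.0, random_state=1)
            .sort_values("adj_p_value").reset_index(drop=True),
            contrast=de.contrast)
        a = lp.select_features(de, m, corr_cut=1.1)
        b = lp.select_features(shuffled, m, corr_cut=1.1)
        assert list(a.features.columns) == list(b.features.columns)


class TestSplitData:
    def _mf(self, n_a=10, n_b=10):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(0, 1, (n_a + n_b, 3)),
                             index=[f"S{i}" for i in range(n_a + n_b)])
        labels = pd.Series(["a"] * n_a + ["b"] * n_b, index=feats.index)
        return lp.ModelFrame(features=feats, labels=labels, classes=["a", "b"],
                             provenance=pd.DataFrame())

    def test_per_class_rounding(self):
        split = lp.split_data(self._mf(10, 10), train_frac=0.7, seed=0)
        mf = self._mf(10, 10)
        train_labels = mf.labels.loc[split.train_ids]
        assert (train_labels == "a").sum() == 7 and (train_labels == "b").sum() == 7
        assert len(split.test_ids) == 6

    def test_partitions_disjoint_and_complete(self):
        mf = self._mf(9, 7)
        split = lp.split_data(mf, seed=3)
        assert set(split.train_ids).isdisjoint(split.test_ids)
        assert set(split.train_ids) | set(split.test_ids) == set(mf.features.index)

    def test_seed_contract(self):
        mf = self._mf(12, 12)
        a = lp.split_data(mf, seed=5)
        b = lp.split_data(mf, seed=5)
        c = lp.split_data(mf, seed=6)
        assert a.train_ids == b.train_ids
        assert sorted(a.train_ids) != sorted(c.train_ids)
        la = mf.labels.loc[a.train_ids].value_counts()
        lc = mf.labels.loc[c.train_ids].value_counts()
        assert la.equals(lc)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="need >=2"):
            lp.split_data(self._mf(1, 10), seed=0)

    def test_both_partitions_keep_every_class(self):
        split = lp.split_data(self._mf(2, 10), train_frac=0.9, seed=0)
        mf = self._mf(2, 10)
        for ids in (split.train_ids, split.test_ids):
            assert set(mf.labels.loc[ids]) == {"a", "b"}


class TestTrainModels:
    def test_resample_count_is_k_times_repeats(self, separable_models):
        _, ms, _ = separable_models
        counts = ms.resamples.groupby(["algorithm", "setting"]).size()
        assert (counts == 30).all()  # k=10 x repeats=3

    def test_separable_data_high_cv_accuracy(self, separable_models):
        _, ms, _ = separable_models
        for algo in lp.DEFAULT_ALGORITHMS:
            assert ms.mean_cv_accuracy(algo) >= 0.95

    def test_permuted_labels_give_chance_accuracy(self, null_models):
        _, _, ms = null_models
        accs = [ms.mean_cv_accuracy(a) for a in lp.DEFAULT_ALGORITHMS]
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_unknown_algorithm_lists_registry(self, separable_mf):
        split = lp.split_data(separable_mf, seed=0)
        with pytest.raises(ValueError, match="naive_bayes"):
            lp.train_models(split, separable_mf, algorithms=("mlp",), seed=0)

    def test_excessive_k_advises_smaller(self, separable_mf):
        split = lp.split_data(separable_mf, seed=0)
        with pytest.raises(ValueError, match="smaller k"):
            lp.train_models(split, separable_mf, algorithms=("glm",), k=50, seed=0)

    def test_training_is_deterministic(self, separable_mf):
        split = lp.split_data(separable_mf, seed=4)
        kwargs = dict(algorithms=("rf", "glm", "xgbLinear"), k=5, repeats=2, seed=4)
        a = lp.train_models(split, separable_mf, **kwargs)
        b = lp.train_models(split, separable_mf, **kwargs)
        pd.testing.assert_frame_equal(a.resamples, b.resamples)
        assert a.best == b.best


class TestTestModels:
    def test_probability_rows_normalized(self, separable_models):
        split, ms, probs = separable_models
        for algo, frame in probs.probabilities.items():
            np.testing.assert_allclose(frame.sum(axis=1), 1.0, atol=1e-9)
            assert ((frame >= 0) & (frame <= 1)).all().all()
            assert len(frame) == len(split.test_ids)

    def test_separable_data_perfect_test_accuracy(self, separable_mf, separable_models):
        split, _, probs = separable_models
        truth = separable_mf.labels.loc[split.test_ids]
        for algo in lp.DEFAULT_ALGORITHMS:
            assert probs.accuracy(algo, truth) == 1.0

    def test_feature_mismatch_rejected(self, separable_mf, separable_models):
        split, ms, _ = separable_models
        renamed = separable_mf.features.copy()
        renamed.columns = [f"X{j}" for j in range(renamed.shape[1])]
        bad = lp.ModelFrame(features=renamed, labels=separable_mf.labels,
                            classes=separable_mf.classes,
                            provenance=separable_mf.provenance)
        with pytest.raises(ValueError, match="feature mismatch"):
            lp.test_models(ms, split, bad)


class TestRocAuc:
    def test_perfect_and_reversed_ranking(self):
        labels = np.array(["p", "p", "n", "n"])
        _, auc = lp.roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), labels, "p")
        assert auc == 1.0
        _, auc = lp.roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), labels, "p")
        assert auc == 0.0

    def test_hand_example_three_quarters(self):
        curve, auc = lp.roc_auc(np.array([0.9, 0.8, 0.4, 0.3]),
                                np.array(["p", "n", "p", "n"]), "p")
        assert auc == 0.75
        assert curve.iloc[0].tolist() == [0.0, 0.0]
        assert curve.iloc[-1].tolist() == [1.0, 1.0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            lp.roc_auc(np.array([0.5, 0.6]), np.array(["p", "p"]), "p")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(2, 40))
    def test_auc_equals_trapezoid_of_curve(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 7), size=2 * n)  # force ties
        labels = np.array(["p"] * n + ["n"] * n)
        curve, auc = lp.roc_auc(scores, labels, "p")
        trap = np.trapezoid(curve["tpr"], curve["fpr"])
        assert abs(auc - trap) < 1e-12

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        labels = np.where(rng.random(200) < 0.4, "p", "n")
        _, auc = lp.roc_auc(scores, labels, "p")
        assert auc == pytest.approx(roc_auc_score(labels == "p", scores), abs=1e-12)


class TestStratification:
    def test_train_fraction_close_per_class(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.normal(0, 1, (40, 3)),
                             index=[f"S{i}" for i in range(40)])
        labels = pd.Series(["a"] * 25 + ["b"] * 15, index=feats.index)
        mf = lp.ModelFrame(features=feats, labels=labels, classes=["a", "b"],
                           provenance=pd.DataFrame())
        split = lp.split_data(mf, train_frac=0.7, seed=1)
        for cls, n_c in (("a", 25), ("b", 15)):
            got = (mf.labels.loc[split.train_ids] == cls).sum() / n_c
            assert abs(got - 0.7) < 1.0 / n_c
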