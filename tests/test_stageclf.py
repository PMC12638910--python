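import numpy as np
import pandas as pd
import pytest

from eegstages.stageclf import (
    Dataset, assemble_dataset, build_model, confusion, discrete_mi_bits,
    mrmr_rank, train_eval,
)
from eegstages.synth import make_feature_dataset


def gaussian_clusters(rng, n_per_class=60, n_features=84, sep=2.0):
    """Three well-separated Gaussian blobs in feature space.

    Class means differ by ~``sep`` per feature (unit within-class SD), so
    every feature is informative and the blobs stay separable after any
    per-feature standardization.
    """
    X, y = [], []
    for cls in (1, 2, 3):
        center = rng.normal(0.0, sep, size=n_features)
        X.append(rng.normal(center, 1.0, size=(n_per_class, n_features)))
        y.append(np.full(n_per_class, cls))
    X, y = np.vstack(X), np.concatenate(y)
    groups = np.arange(len(y)).astype(str)
    names = tuple(f"f{i}" for i in range(n_features))
    return Dataset(X=X, y=y, groups=groups, feature_names=names)


class TestAssembleDataset:
    def test_counts_and_feature_columns(self):
        df = make_feature_dataset(n_per_stage=4, effect_size=0.0, seed=0)
        ds = assemble_dataset(df)
        assert ds.X.shape == (12, 84)
        assert ds.class_counts() == {1: 4, 2: 4, 3: 4}
        assert not any(n.endswith("_amp") for n in ds.feature_names)

    def test_duplicate_segment_ids_rejected(self):
        df = make_feature_dataset(n_per_stage=3, effect_size=0.0, seed=0)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_dataset(dup)

    def test_row_order_deterministic(self):
        df = make_feature_dataset(n_per_stage=5, effect_size=0.0, seed=8)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = assemble_dataset(df)
        b = assemble_dataset(shuffled)
        assert np.array_equal(a.X, b.X)
        assert np.array_equal(a.y, b.y)


class TestMrmrRank:
    def test_planted_feature_ranked_first(self, rng):
        n = 300
        y = rng.integers(1, 4, size=n)
        X = rng.standard_normal((n, 20))
        X[:, 7] = y + 0.3 * rng.standard_normal(n)
        ds = Dataset(X=X, y=y, groups=np.arange(n).astype(str),
                     feature_names=tuple(f"f{i}" for i in range(20)))
        ranking = mrmr_rank(ds, k=5)
        assert ranking.order[0] == 7

    def test_duplicate_feature_penalized_by_redundancy(self, rng):
        n = 400
        y = rng.integers(1, 4, size=n)
        X = rng.standard_normal((n, 4))
        X[:, 0] = y + 0.2 * rng.standard_normal(n)   # strong
        X[:, 1] = X[:, 0]                            # exact duplicate
        X[:, 2] = y + 1.5 * rng.standard_normal(n)   # weaker but independent
        ds = Dataset(X=X, y=y, groups=np.arange(n).astype(str),
                     feature_names=("a", "dup", "weak", "noise"))
        ranking = mrmr_rank(ds)
        assert ranking.order[0] == 0
        # the exact copy carries full redundancy and must fall behind the
        # weaker independent feature
        assert ranking.order.index(2) < ranking.order.index(1)

    def test_constant_feature_never_precedes_informative(self, rng):
        n = 200
        y = rng.integers(1, 4, size=n)
        X = rng.standard_normal((n, 3))
        X[:, 0] = 1.0  # constant: zero relevance
        X[:, 1] = y + 0.5 * rng.standard_normal(n)
        ds = Dataset(X=X, y=y, groups=np.arange(n).astype(str),
                     feature_names=("const", "info", "noise"))
        ranking = mrmr_rank(ds)
        assert ranking.order.index(1) < ranking.order.index(0)

    def test_ranking_is_a_permutation(self, rng):
        ds = gaussian_clusters(rng, n_per_class=20, n_features=10)
        ranking = mrmr_rank(ds)
        assert sorted(ranking.order) == list(range(10))

    def test_discrete_mi_exact_value(self):
        a = np.tile([0, 1], 50).astype(np.intp)
        assert discrete_mi_bits(a, a) == pytest.approx(1.0)
        b = np.tile([0, 0, 1, 1], 25).astype(np.intp)
        assert discrete_mi_bits(a, b) == pytest.approx(0.0, abs=1e-12)


class TestTrainEval:
    def test_separable_clusters_near_perfect(self, rng):
        ds = gaussian_clusters(rng)
        for spec in ("svm", "knn"):
            rep = train_eval(ds, spec, split_seed=0)
            assert rep.test_accuracy >= 0.99
            assert rep.validation_accuracy >= 0.95

    def test_permuted_labels_fall_to_chance(self, rng):
        ds = gaussian_clusters(rng, n_per_class=100)
        perm = Dataset(X=ds.X, y=rng.permutation(ds.y), groups=ds.groups,
                       feature_names=ds.feature_names)
        rep = train_eval(perm, "knn", split_seed=0)
        # 60 test samples; 99% binomial band around 1/3
        assert 0.15 <= rep.test_accuracy <= 0.52

    def test_report_is_reproducible(self, rng):
        ds = gaussian_clusters(rng, n_per_class=40)
        a = train_eval(ds, "svm", split_seed=3)
        b = train_eval(ds, "svm", split_seed=3)
        assert a.test_accuracy == b.test_accuracy
        assert np.array_equal(a.confusion_test, b.confusion_test)
        assert np.array_equal(a.test_indices, b.test_indices)

    def test_no_leakage_between_folds_and_test(self, rng):
        ds = gaussian_clusters(rng, n_per_class=40)
        rep = train_eval(ds, "decision_tree", split_seed=1)
        assert np.all(rep.fold_assignments[rep.test_indices] == -1)
        pool = np.flatnonzero(rep.fold_assignments >= 0)
        assert np.intersect1d(pool, rep.test_indices).size == 0
        assert len(pool) + len(rep.test_indices) == ds.n_samples

    def test_grouped_split_respects_sessions(self, rng):
        ds = gaussian_clusters(rng, n_per_class=40)
        groups = np.repeat([f"g{i}" for i in range(12)], 10)
        ds = Dataset(X=ds.X, y=ds.y, groups=groups,
                     feature_names=ds.feature_names)
        rep = train_eval(ds, "knn", split_seed=0, grouped=True, n_folds=5)
        test_groups = set(groups[rep.test_indices])
        pool_groups = set(groups[np.flatnonzero(rep.fold_assignments >= 0)])
        assert not test_groups & pool_groups

    def test_confusion_matrix_conservation(self, rng):
        ds = gaussian_clusters(rng, n_per_class=40)
        rep = train_eval(ds, "qda", split_seed=0)
        conf = confusion(rep, "test")
        assert conf.sum() == len(rep.test_indices)
        assert conf.shape == (3, 3)
        counts = {c: n for c, n in zip(*np.unique(ds.y[rep.test_indices],
                                                  return_counts=True))}
        for row, cls in zip(conf, rep.classes):
            assert row.sum() == counts[cls]

    def test_unknown_model_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown model"):
            build_model("boosted_stumps", 0)


def test_synthetic_stage_dataset_all_models_beat_chance():
    df = make_feature_dataset(n_per_stage=80, effect_size=1.0, seed=42)
    ds = assemble_dataset(df)
    accs = {}
    for spec in ("svm", "knn", "decision_tree", "qda"):
        accs[spec] = train_eval(ds, spec, split_seed=0).test_accuracy
    assert all(a > 0.5 for a in accs.values())
    # kernel SVM should sit among the top performers on this feature set
    assert accs["svm"] >= np.median(list(accs.values()))
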