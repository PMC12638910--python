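"""Learning-stage classification from 84-feature segment samples.

Each kept 10-s segment contributes one sample of 84 relative-PSD
features (14 channels x 6 bands); segments pooled over subjects and
sessions form a three-class dataset labelled by learning stage.  A
stratified 20% test split is held out first; the remaining pool is
evaluated by 10-fold stratified cross-validation (9:1 train/validation
per fold), then the model refit on the whole pool is scored once on the
untouched test set.  Splitting is segment-level by default (segments of
one subject may appear on both sides); a grouped subject-level mode is
available as the leakage-safe alternative, at the cost of far fewer
effective samples.

Feature relevance is ranked with greedy MRMR (max-relevance
min-redundancy, difference criterion): features are discretized into
equal-frequency bins, the first pick maximizes mutual information with
the stage label, and each subsequent pick maximizes relevance minus the
mean MI with the already-selected set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.model_selection import (
    GroupShuffleSplit, StratifiedKFold, train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .spectral import LABEL_COLUMNS

__all__ = [
    "Dataset",
    "assemble_dataset",
    "FeatureRanking",
    "mrmr_rank",
    "ClassifierReport",
    "train_eval",
    "confusion",
    "MODEL_SPECS",
]

log = logging.getLogger(__name__)

MODEL_SPECS = ("svm", "knn", "decision_tree", "qda", "neural_network")


@dataclass
class Dataset:
    """Aligned feature matrix, stage labels and per-sample group ids."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X rows must align with y")
        if len(self.groups) != self.X.shape[0]:
            raise ValueError("groups must align with rows")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def assemble_dataset(features: pd.DataFrame) -> Dataset:
    """Build a stage-labelled dataset from a tidy feature table.

    Rows are ordered deterministically by (subject, session, task,
    segment); duplicate segment identities are rejected.  Only the
    84 relative-power columns (not the amplitude summaries) enter the
    feature matrix.  Per-stage sample counts are logged.
    """
    df = features.sort_values(
        ["subject", "session", "task", "segment"]).reset_index(drop=True)
    ids = df[["subject", "session", "task", "segment"]]
    if ids.duplicated().any():
        raise ValueError("duplicate segment identities in feature table")
    feat_cols = [c for c in df.columns
                 if c not in LABEL_COLUMNS and not c.endswith("_amp")]
    if not feat_cols:
        raise ValueError("no feature columns found")
    y = df["stage"].to_numpy(int)
    if np.unique(y).size < 2:
        raise ValueError("dataset needs at least two stage classes")
    groups = (df["subject"].astype(str) + "/" + df["session"].astype(str)).to_numpy()
    counts = dict(zip(*np.unique(y, return_counts=True)))
    log.info("assembled dataset: %d samples, per-stage counts %s",
             len(df), counts)
    return Dataset(X=df[feat_cols].to_numpy(float), y=y, groups=groups,
                   feature_names=tuple(feat_cols))


# ---------------------------------------------------------------- MRMR

def _equal_frequency_codes(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right").astype(np.intp)


def discrete_mi_bits(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information of two integer-coded series, in bits."""
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    n = joint.sum()
    pj = joint[joint > 0] / n
    pa = np.bincount(a, minlength=ka).astype(float) / n
    pb = np.bincount(b, minlength=kb).astype(float) / n
    h_a = -np.sum(pa[pa > 0] * np.log2(pa[pa > 0]))
    h_b = -np.sum(pb[pb > 0] * np.log2(pb[pb > 0]))
    h_ab = -np.sum(pj * np.log2(pj))
    return float(h_a + h_b - h_ab)


@dataclass(frozen=True)
class FeatureRanking:
    """Greedy MRMR order over all features with the greedy scores."""

    order: tuple[int, ...]
    scores: tuple[float, ...]
    names: tuple[str, ...]

    def top(self, k: int) -> list[str]:
        return [self.names[i] for i in self.order[:k]]


def mrmr_rank(ds: Dataset, k: int | None = None, bins: int = 4) -> FeatureRanking:
    """MRMR (difference criterion) ranking of the feature set.

    Features are discretized into ``bins`` equal-frequency bins.
    Relevance is MI with the stage label; redundancy is the mean MI with
    the already-selected features.  Ties break toward the lower feature
    index.  A constant feature has zero relevance and is never picked
    before an informative one.
    """
    n_feat = ds.X.shape[1]
    if k is None:
        k = n_feat
    if not 1 <= k <= n_feat:
        raise ValueError(f"k must be in 1..{n_feat}")
    y_codes = np.unique(ds.y, return_inverse=True)[1].astype(np.intp)
    codes = np.stack([_equal_frequency_codes(ds.X[:, j], bins)
                      for j in range(n_feat)], axis=1)
    relevance = np.array([discrete_mi_bits(codes[:, j], y_codes)
                          for j in range(n_feat)])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, bool)
    for _ in range(k):
        if selected:
            crit = relevance - redundancy_sum / len(selected)
        else:
            crit = relevance.copy()
        crit[~remaining] = -np.inf
        best = int(np.argmax(crit))  # argmax takes the lowest index on ties
        selected.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False
        for j in np.flatnonzero(remaining):
            redundancy_sum[j] += discrete_mi_bits(codes[:, j], codes[:, best])
    return FeatureRanking(order=tuple(selected), scores=tuple(scores),
                          names=ds.feature_names)


# ------------------------------------------------------------- models

def build_model(spec: str, seed: int):
    """Instantiate one of the five-model suite with fixed hyperparameters.

    Scale-sensitive models (SVM, KNN, NN) standardize features inside
    the pipeline, so the scaler is fit on training folds only.
    """
    if spec == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", C=1.0, gamma="scale",
                decision_function_shape="ovo", random_state=seed))
    if spec == "knn":
        return make_pipeline(StandardScaler(),
                             KNeighborsClassifier(n_neighbors=10))
    if spec == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", max_depth=20,
                                      random_state=seed)
    if spec == "qda":
        # relative-power features are exactly collinear (six bands per
        # channel sum to one), so class covariances are structurally
        # rank-deficient; the eigen solver with substantial shrinkage is
        # the well-posed quadratic-discriminant variant here
        return QuadraticDiscriminantAnalysis(solver="eigen", shrinkage=0.1)
    if spec == "neural_network":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(100,), activation="relu",
                          early_stopping=True, max_iter=300,
                          random_state=seed))
    raise ValueError(f"unknown model spec {spec!r}; choose from {MODEL_SPECS}")


@dataclass
class ClassifierReport:
    """Cross-validated and held-out performance of one model."""

    model: str
    validation_accuracy: float
    test_accuracy: float
    confusion_validation: np.ndarray
    confusion_test: np.ndarray
    classes: tuple[int, ...]
    split_seed: int
    fold_assignments: np.ndarray
    test_indices: np.ndarray
    fold_accuracies: tuple[float, ...]


def train_eval(
    ds: Dataset,
    model_spec: str = "svm",
    split_seed: int = 0,
    test_size: float = 0.2,
    n_folds: int = 10,
    grouped: bool = False,
) -> ClassifierReport:
    """Hold out a test set, run 10-fold CV on the pool, score the test set.

    Validation accuracy is the mean over folds; the test set never
    enters any fold (asserted).  ``grouped`` switches both splits to
    subject/session-group-aware splitting so no group straddles
    train/test or fold boundaries.
    """
    idx = np.arange(ds.n_samples)
    if grouped:
        gss = GroupShuffleSplit(n_splits=1, test_size=test_size,
                                random_state=split_seed)
        pool_idx, test_idx = next(gss.split(ds.X, ds.y, ds.groups))
    else:
        pool_idx, test_idx = train_test_split(
            idx, test_size=test_size, random_state=split_seed,
            stratify=ds.y)
    X_pool, y_pool = ds.X[pool_idx], ds.y[pool_idx]
    classes = tuple(np.unique(ds.y).tolist())
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=split_seed)
    fold_assign = np.full(ds.n_samples, -1, int)
    fold_accs = []
    conf_val = np.zeros((len(classes), len(classes)), int)
    for fold, (tr, va) in enumerate(skf.split(X_pool, y_pool)):
        if np.unique(y_pool[tr]).size < len(classes):
            raise ValueError(f"fold {fold} is missing a class")
        model = build_model(model_spec, split_seed)
        model.fit(X_pool[tr], y_pool[tr])
        pred = model.predict(X_pool[va])
        fold_accs.append(accuracy_score(y_pool[va], pred))
        conf_val += confusion_matrix(y_pool[va], pred, labels=classes)
        fold_assign[pool_idx[va]] = fold
    # leakage guard: the held-out test set belongs to no CV fold
    assert np.all(fold_assign[test_idx] == -1)
    assert np.intersect1d(pool_idx, test_idx).size == 0
    final = build_model(model_spec, split_seed)
    final.fit(X_pool, y_pool)
    test_pred = final.predict(ds.X[test_idx])
    test_acc = accuracy_score(ds.y[test_idx], test_pred)
    conf_test = confusion_matrix(ds.y[test_idx], test_pred, labels=classes)
    return ClassifierReport(
        model=model_spec,
        validation_accuracy=float(np.mean(fold_accs)),
        test_accuracy=float(test_acc),
        confusion_validation=conf_val,
        confusion_test=conf_test,
        classes=classes,
        split_seed=split_seed,
        fold_assignments=fold_assign,
        test_indices=np.asarray(test_idx),
        fold_accuracies=tuple(float(a) for a in fold_accs),
    )


def confusion(report: ClassifierReport, which: str = "test") -> np.ndarray:
    """Confusion matrix (rows = true stage, columns = predicted)."""
    if which == "test":
        return report.confusion_test
    if which == "validation":
        return report.confusion_validation
    raise ValueError("which must be 'test' or 'validation'")
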