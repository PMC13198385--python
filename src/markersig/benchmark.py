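"""Benchmark harness: A-vs-Rest signatures, top-k sweep, SVM test MCC.

Protocol: for every cluster label, rank features for that cluster against
the remaining samples with each method, take the top k features (k
sweeping 1..20 by default), train a classifier (default: RBF-kernel SVM
with library defaults) on a stratified 70/30 train/test split, and report
the Matthews correlation coefficient of the test-set predictions.

Feature ranking sees the training split only, so the test rows never leak
into selection (``select_on_full=True`` mimics the alternative protocol).
Feature columns are standardized with train-set mean/sd before the SVM
fit, since the RBF kernel's default scale is sensitive to feature
magnitudes; pass ``standardize=False`` to disable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .baselines import METHODS, rank_features
from .datasets import OmicsDataset, SampleSelection, ValidationError
from .signatures import mcc


def stratified_split(
    in_group_a,
    train_frac: float = 0.7,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified train/test split of sample indices.

    Per class, ``round(train_frac * class_size)`` samples go to the train
    set (each class keeps at least one train and one test sample); the
    class frequencies of the full data are thus preserved at rounding
    granularity.  Deterministic given ``seed``.
    """
    y = np.asarray(in_group_a, dtype=bool)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValidationError("each class needs at least 2 samples to split")
        n_train = int(np.floor(train_frac * idx.size + 0.5))  # round half up
        n_train = min(max(n_train, 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def evaluate_feature_set(
    dataset: OmicsDataset,
    features,
    in_group_a,
    split: tuple[np.ndarray, np.ndarray],
    classifier=None,
    standardize: bool = True,
) -> float:
    """Train a classifier on the given features and return the test MCC."""
    features = list(features)
    if not features:
        raise ValueError("empty feature list")
    cols = dataset.feature_index(features)
    y = np.asarray(in_group_a, dtype=bool)
    train_idx, test_idx = split
    y_train, y_test = y[train_idx], y[test_idx]
    if y_train.all() or not y_train.any():
        raise ValidationError("training set contains a single class")

    X_train = dataset.dense_block(train_idx, cols)
    X_test = dataset.dense_block(test_idx, cols)
    if standardize:
        mu = X_train.mean(axis=0)
        sd = X_train.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd

    clf = classifier if classifier is not None else SVC()
    clf.fit(X_train, y_train)
    pred = np.asarray(clf.predict(X_test), dtype=bool)
    tp = int((pred & y_test).sum())
    fp = int((pred & ~y_test).sum())
    fn = int((~pred & y_test).sum())
    tn = int((~pred & ~y_test).sum())
    return mcc(tp, tn, fp, fn)


@dataclass
class BenchmarkReport:
    """Per-(cluster, method, k, repetition) test MCCs plus protocol metadata."""

    records: pd.DataFrame
    protocol: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard deviation of test MCC per (method, k), over
        clusters and repetitions."""
        g = self.records.groupby(["method", "k"], sort=True)["mcc_test"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"mean": "mcc_mean", "std": "mcc_sd", "count": "n_runs"})


def run_benchmark(
    dataset: OmicsDataset,
    group_key: str,
    methods=METHODS,
    k_range=range(1, 21),
    reps: int = 10,
    seed: int = 0,
    train_frac: float = 0.7,
    classifier_factory=None,
    select_on_full: bool = False,
    standardize: bool = True,
) -> BenchmarkReport:
    """Full benchmark sweep over clusters, methods, top-k sizes and splits.

    For each label of ``group_key``: repeat ``reps`` stratified splits
    (seeds ``seed + rep``); rank features for label-vs-rest on the training
    rows only; for each ``k`` evaluate the top-k features with the
    classifier and record the test MCC.  Clusters with fewer than 4
    samples (or fewer than 4 out-of-cluster samples) are skipped with a
    warning.
    """
    if group_key not in dataset.annotations.columns:
        raise KeyError(f"unknown annotation key {group_key!r}")
    labels = dataset.annotations[group_key].astype(str)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValidationError("group key must have at least 2 labels")
    methods = list(methods)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    k_range = sorted(set(int(k) for k in k_range))
    k_max = max(k_range)

    rows = []
    for label in uniq:
        in_a = (labels == label).to_numpy()
        if in_a.sum() < 4 or (~in_a).sum() < 4:
            warnings.warn(f"cluster {label!r} has fewer than 4 samples; skipped")
            continue
        for rep in range(reps):
            split = stratified_split(in_a, train_frac=train_frac, seed=seed + rep)
            train_idx, _ = split
            if select_on_full:
                rank_ds, rank_in_a = dataset, in_a
            else:
                rank_ds = dataset.subset(train_idx)
                rank_in_a = in_a[train_idx]
            sel_a = SampleSelection(rank_in_a, provenance=f"label:{group_key}={label}")
            for method in methods:
                ranked = rank_features(rank_ds, sel_a, None, method, n_top=k_max)
                for k in k_range:
                    clf = classifier_factory() if classifier_factory is not None else None
                    score = evaluate_feature_set(
                        dataset, ranked.top(k), in_a, split,
                        classifier=clf, standardize=standardize,
                    )
                    rows.append(
                        {"cluster": label, "method": method, "k": k,
                         "rep": rep, "mcc_test": score}
                    )
    records = pd.DataFrame(rows, columns=["cluster", "method", "k", "rep", "mcc_test"])
    return BenchmarkReport(
        records=records,
        protocol={
            "group_key": group_key,
            "methods": methods,
            "k_range": k_range,
            "reps": reps,
            "seed": seed,
            "train_frac": train_frac,
            "classifier": "SVC(default)" if classifier_factory is None else "custom",
            "select_on_full": select_on_full,
            "standardize": standardize,
        },
    )
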