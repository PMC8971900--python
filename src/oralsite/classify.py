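"""Habitat-of-origin classification with a random-forest pipeline.

Procedure: a stratified 70/30 sample-level split, an importance ranking of
all features fitted on the training set only (mean impurity decrease), a
refit restricted to the top-k (default 30) features, and train/test
accuracies with per-class confusion counts.  Inputs are relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from ._util import ConfigurationError, stream_seed
from .feature_table import FeatureTable, RelativeAbundanceTable, SampleMetadata, to_relative

logger = logging.getLogger(__name__)

DEFAULT_N_ESTIMATORS = 500


@dataclass
class ClassifierReport:
    """Evaluation of the top-k refit; accuracies are percentages."""

    train_accuracy: float
    test_accuracy: float
    confusion: pd.DataFrame          # rows: true class, columns: predicted
    importances: pd.Series           # top-k features used, ranked
    seed: int
    top_k: int

    def as_dict(self) -> dict:
        return {
            "train_accuracy_pct": self.train_accuracy,
            "test_accuracy_pct": self.test_accuracy,
            "confusion": {c: self.confusion[c].to_dict() for c in self.confusion},
            "top_features": self.importances.index.tolist(),
            "seed": self.seed,
            "top_k": self.top_k,
        }


def split_samples(
    table: FeatureTable,
    metadata: SampleMetadata,
    train_fraction: float = 0.7,
    seed: int = 0,
    individual_aware: bool = False,
) -> tuple[list[str], list[str]]:
    """Stratified random train/test split at the sample level.

    With ``individual_aware`` both samples of one subject land on the same
    side of the split (grouped split instead of stratified).
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    ids = table.sample_ids
    labels = metadata.habitat_of().loc[ids]
    if labels.nunique() < 2:
        raise ConfigurationError("both habitats must be present to split")
    state = stream_seed(seed, "split")
    if individual_aware:
        groups = metadata.individual_of().loc[ids].to_numpy()
        for attempt in range(100):
            gss = GroupShuffleSplit(n_splits=1, train_size=train_fraction,
                                    random_state=(state + attempt) % 2**31)
            tr, te = next(gss.split(ids, labels, groups))
            train = [ids[i] for i in tr]
            test = [ids[i] for i in te]
            if labels.loc[train].nunique() == 2 and labels.loc[test].nunique() == 2:
                if attempt:
                    logger.warning("split_samples: re-drew %d time(s) to keep "
                                   "both classes on both sides", attempt)
                return train, test
        raise ConfigurationError("could not produce a split with both classes "
                                 "on both sides after 100 attempts")
    train, test = train_test_split(
        ids, train_size=train_fraction, random_state=state, stratify=labels)
    return list(train), list(test)


def rank_importance(
    rel_train: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> pd.Series:
    """Features sorted by mean impurity-decrease importance, descending.

    Fitted on training data only.  Ties are broken by feature id so the
    ranking is deterministic.
    """
    if rel_train.shape[1] < 2:
        raise ConfigurationError("importance ranking needs >= 2 features")
    y = labels.loc[rel_train.index]
    if y.nunique() < 2:
        raise ConfigurationError("single-class training data")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=stream_seed(seed, "rank"))
    forest.fit(rel_train.to_numpy(), y.to_numpy())
    imp = pd.Series(forest.feature_importances_, index=rel_train.columns)
    order = sorted(imp.index, key=lambda f: (-imp[f], f))
    return imp.loc[order]


def train_and_evaluate(
    rel: RelativeAbundanceTable,
    metadata: SampleMetadata,
    train_ids: list[str],
    test_ids: list[str],
    top_k: int = 30,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> ClassifierReport:
    """Rank features on the training split, refit on the top-k, evaluate."""
    if not test_ids:
        raise ConfigurationError("empty test set")
    labels = metadata.habitat_of()
    train = rel.data.loc[train_ids]
    test = rel.data.loc[test_ids]

    ranking = rank_importance(train, labels, seed=seed, n_estimators=n_estimators)
    if top_k > len(ranking):
        logger.warning("train_and_evaluate: only %d features available; "
                       "requested top_k=%d clipped", len(ranking), top_k)
    selected = ranking.index[: min(top_k, len(ranking))]

    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=stream_seed(seed, "refit"))
    forest.fit(train[selected].to_numpy(), labels.loc[train_ids].to_numpy())

    classes = sorted(labels.loc[train_ids].unique())
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    pred_test = forest.predict(test[selected].to_numpy())
    for truth, pred in zip(labels.loc[test_ids], pred_test):
        confusion.loc[truth, pred] += 1
    pred_train = forest.predict(train[selected].to_numpy())
    train_acc = 100.0 * float(np.mean(pred_train == labels.loc[train_ids].to_numpy()))
    test_acc = 100.0 * float(np.diag(confusion).sum() / confusion.to_numpy().sum())
    assert abs(test_acc - 100.0 * np.mean(pred_test == labels.loc[test_ids].to_numpy())) < 1e-9
    return ClassifierReport(
        train_accuracy=train_acc, test_accuracy=test_acc, confusion=confusion,
        importances=ranking.loc[selected], seed=seed, top_k=top_k)


def classify_habitat(
    table: FeatureTable,
    metadata: SampleMetadata,
    train_fraction: float = 0.7,
    top_k: int = 30,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    individual_aware: bool = False,
) -> ClassifierReport:
    """Full pipeline: normalize, split, rank, refit, evaluate."""
    rel = to_relative(table)
    train_ids, test_ids = split_samples(
        table, metadata, train_fraction=train_fraction, seed=seed,
        individual_aware=individual_aware)
    return train_and_evaluate(rel, metadata, train_ids, test_ids,
                              top_k=top_k, seed=seed, n_estimators=n_estimators)
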