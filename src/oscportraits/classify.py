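"""Pairwise discrimination of trial categories from portraits or elements.

For each of the 15 category pairs a linear random-intercept model is
trained with the 0/1 category label as target — a linear probability
model, reusing the same Gaussian engine as every other analysis — over 100
stratified 75/25 train/test splits.  The continuous model output scores
held-out trials and the area under the ROC curve measures separability;
AUC is rank-based, so no probability calibration is applied.  Shuffled
controls permute the labels within the training set only.

The central comparison is *portrait vs. element*: the full 48-element
portrait against each single element as the feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .elements import element_columns
from .io import validate_table
from .mixedlm import fit_lmm, predict_lmm

__all__ = [
    "DiscriminationResult",
    "roc_auc",
    "pairwise_discriminate",
    "shuffled_control",
    "discrimination_summary",
]


@dataclass
class DiscriminationResult:
    category_pair: tuple[str, str]
    feature_set: str  # "portrait" or a single element name
    auc_values: np.ndarray
    n_resamples: int
    seed: int
    shuffled: bool = False

    def __post_init__(self) -> None:
        self.auc_values = np.asarray(self.auc_values, dtype=float)
        if self.auc_values.size != self.n_resamples:
            raise ValueError("auc_values length must equal n_resamples")
        if ((self.auc_values < 0) | (self.auc_values > 1)).any():
            raise ValueError("AUC values must lie in [0, 1]")

    @property
    def mean_auc(self) -> float:
        return float(self.auc_values.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.auc_values.std(ddof=1))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve; ties contribute 1/2.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, scores))


def _resolve_features(features) -> list[str]:
    cols = element_columns()
    if features == "portrait" or features is None:
        return cols
    if isinstance(features, str):
        features = [features]
    bad = set(features) - set(cols)
    if bad:
        raise ValueError(f"features not element columns: {sorted(bad)}")
    return list(features)


def _discriminate(
    table: pd.DataFrame,
    catA: str,
    catB: str,
    features,
    n_resamples: int,
    seed: int,
    test_size: float,
    shuffle_train_labels: bool,
) -> DiscriminationResult:
    validate_table(table, require_behavior=False)
    cols = _resolve_features(features)
    sub = table[table["category"].isin([catA, catB])]
    for c in (catA, catB):
        if (sub["category"] == c).sum() < 10:
            raise ValueError(f"category {c!r} has fewer than 10 trials")
    X = sub[cols].to_numpy(dtype=float)
    y = (sub["category"] == catB).to_numpy(dtype=float)
    subjects = sub["subject"].to_numpy()
    splitter = StratifiedShuffleSplit(
        n_splits=n_resamples, test_size=test_size, random_state=seed
    )
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_resamples)
    for i, (tr, te) in enumerate(splitter.split(X, y)):
        y_train = y[tr]
        if shuffle_train_labels:
            y_train = rng.permutation(y_train)
        fit = fit_lmm(X[tr], y_train, subjects[tr], predictor_names=cols,
                      standardize=True)
        scores = predict_lmm(fit, X[te], subjects[te])
        aucs[i] = roc_auc(scores, y[te])
    name = "portrait" if len(cols) == len(element_columns()) else ",".join(cols)
    return DiscriminationResult(
        category_pair=(catA, catB),
        feature_set=name,
        auc_values=aucs,
        n_resamples=n_resamples,
        seed=seed,
        shuffled=shuffle_train_labels,
    )


def pairwise_discriminate(
    table: pd.DataFrame,
    catA: str,
    catB: str,
    features="portrait",
    n_resamples: int = 100,
    seed: int = 0,
    test_size: float = 0.25,
) -> DiscriminationResult:
    """AUC distribution for discriminating two categories.

    ``features`` is ``"portrait"`` (all 48 elements) or one or more
    element column names.  Deterministic given the seed.
    """
    return _discriminate(table, catA, catB, features, n_resamples, seed,
                         test_size, shuffle_train_labels=False)


def shuffled_control(
    table: pd.DataFrame,
    catA: str,
    catB: str,
    features="portrait",
    n_resamples: int = 100,
    seed: int = 0,
    test_size: float = 0.25,
) -> DiscriminationResult:
    """Chance-level control: labels permuted within each training set."""
    return _discriminate(table, catA, catB, features, n_resamples, seed,
                         test_size, shuffle_train_labels=True)


def discrimination_summary(results: list[DiscriminationResult]) -> pd.DataFrame:
    """Tidy table of mean/SD AUC per category pair and feature set."""
    rows = [
        {
            "catA": r.category_pair[0],
            "catB": r.category_pair[1],
            "feature_set": r.feature_set,
            "mean_auc": r.mean_auc,
            "sd_auc": r.sd_auc,
            "shuffled": r.shuffled,
            "n_resamples": r.n_resamples,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
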