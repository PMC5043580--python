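"""Model-based concordance between replicate binding experiments.

Coordinate overlap between replicate peak sets understates their agreement:
a model trained on one replicate typically recognizes far more of the other
replicate's peaks than the shared coordinates would suggest, because both
capture the same motif grammar.  This module quantifies that: cross-
prediction rates, per-subset (A/B1/B2/C) prediction rates over the overlap
partition, direct experiment-versus-experiment contrast models, and the
overlap of selected model features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import Featurizer, FeatureMatrix, train_test_split
from .intervals import OverlapPartition, PeakSet
from .models import (
    FittedModel,
    fit_lasso_path,
    model_at,
    predict,
    roc_auc,
    select_lambda_1se,
    select_lambda_knowledge,
)

_UNDEFINED = float("nan")


@dataclass
class SubsetRate:
    n: int
    rate: float  # fraction predicted positive; NaN when n == 0
    scores: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


@dataclass
class ConcordanceReport:
    trained_on: str
    cutoff: float
    subsets: dict[str, SubsetRate]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subset": list(self.subsets), "n": [s.n for s in self.subsets.values()],
             "rate": [s.rate for s in self.subsets.values()]}
        )

    def score_table(self) -> pd.DataFrame:
        rows = []
        for name, s in self.subsets.items():
            for v in s.scores:
                rows.append({"subset": name, "score": v})
        return pd.DataFrame(rows, columns=["subset", "score"])


@dataclass
class FeatureOverlap:
    features_1: set[str]
    features_2: set[str]
    intersection: set[str]
    jaccard: float


def cross_predict_rate(
    model: FittedModel,
    peaks: PeakSet,
    featurizer: Featurizer,
    cutoff: float = 0.5,
) -> float:
    """Fraction of a foreign peak set scored >= cutoff by the model."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    scores = predict(model, featurizer.features(peaks))
    return float(np.mean(scores >= cutoff))


def subset_prediction_rates(
    model: FittedModel,
    partition: OverlapPartition,
    featurizer: Featurizer,
    cutoff: float = 0.5,
    trained_on: str = "",
) -> ConcordanceReport:
    """Positive-prediction rate within each A/B1/B2/C subset."""
    subsets: dict[str, SubsetRate] = {}
    for name, peaks in partition.subsets().items():
        if len(peaks) == 0:
            subsets[name] = SubsetRate(0, _UNDEFINED)
            continue
        scores = predict(model, featurizer.features(peaks))
        subsets[name] = SubsetRate(len(peaks), float(np.mean(scores >= cutoff)), scores)
    return ConcordanceReport(trained_on=trained_on, cutoff=cutoff, subsets=subsets)


def direct_contrast_model(
    peaks1: PeakSet,
    peaks2: PeakSet,
    featurizer: Featurizer,
    fraction: float = 0.75,
    n_folds: int = 10,
    seed: int = 0,
    anchors=None,
) -> tuple[FittedModel, float]:
    """Classify experiment-of-origin directly (not peak versus background).

    Returns the selected sparse model and its held-out test AUC.  Near-random
    AUC means the two experiments share motif grammar.  The knowledge rule is
    used only when anchors are supplied; otherwise the 1-s.e. rule.
    """
    k1 = {(iv.chrom, iv.start, iv.end) for iv in peaks1}
    k2 = {(iv.chrom, iv.start, iv.end) for iv in peaks2}
    if k1 == k2:
        raise ValueError("peak sets are identical; contrast labels would duplicate rows")
    f1 = featurizer.features(peaks1)
    f2 = featurizer.features(peaks2)
    stacked = FeatureMatrix(
        [f"{peaks1.name}|{p}" for p in f1.peak_ids]
        + [f"{peaks2.name}|{p}" for p in f2.peak_ids],
        list(f1.motif_ids),
        np.vstack([f1.values, f2.values]),
        [peaks1.name] * f1.n_peaks + [peaks2.name] * f2.n_peaks,
        f1.normalized,
    )
    split = train_test_split(stacked, fraction=fraction, seed=seed)
    train = stacked.subset_rows(split.train_indices)
    test = stacked.subset_rows(split.test_indices)
    path = fit_lasso_path(
        train, n_folds=n_folds, seed=seed, positive_label=peaks1.name
    )
    if anchors:
        lam = select_lambda_knowledge(path, anchors)
    else:
        lam = select_lambda_1se(path)
    model = model_at(path, lam)
    scores = predict(model, test)
    auc = roc_auc(scores, test.labels, positive_label=peaks1.name).auc
    return model, float(auc)


def model_feature_overlap(m1: FittedModel, m2: FittedModel) -> FeatureOverlap:
    """Set overlap (and Jaccard index) of two models' active features."""
    f1, f2 = set(m1.active_features), set(m2.active_features)
    inter = f1 & f2
    union = f1 | f2
    return FeatureOverlap(f1, f2, inter, len(inter) / len(union) if union else _UNDEFINED)
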