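"""Confusion-matrix accuracy assessment and the 70/30 validation split."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = reference, cols = predicted
    class_order: tuple
    n: int


@dataclass
class AccuracyReport:
    oa: float
    per_class: dict  # class -> {"pa": .., "ua": .., "f1": ..}

    def to_dict(self) -> dict:
        return {"oa": self.oa, "per_class": self.per_class}


def split_validation(
    samples: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, deterministic, disjoint and exhaustive train/test split."""
    if not 0 < train_fraction < 1:
        raise ContractError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for _, grp in samples.groupby("class", sort=True):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            warnings.warn(f"class {grp['class'].iloc[0]!r} has < 2 samples")
        perm = idx[rng.permutation(len(idx))]
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), max(len(idx) - 1, 1))
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return samples.loc[sorted(train_idx)], samples.loc[sorted(test_idx)]


def confusion_matrix(
    reference: Sequence, predicted: Sequence, class_order: Sequence
) -> ConfusionMatrix:
    reference = list(reference)
    predicted = list(predicted)
    if len(reference) != len(predicted):
        raise ContractError("reference/predicted length mismatch")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for r, p in zip(reference, predicted):
        if r not in index or p not in index:
            raise ContractError(f"label outside class_order: {r!r}/{p!r}")
        counts[index[r], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order), n=int(counts.sum()))


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyReport:
    """OA = trace/N; per-class one-vs-rest PA (recall), UA (precision), F1."""
    if cm.n <= 0:
        raise ContractError("empty confusion matrix")
    counts = cm.counts
    oa = float(np.trace(counts) / cm.n)
    per_class = {}
    for i, cname in enumerate(cm.class_order):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        pa = float(tp / (tp + fn)) if tp + fn > 0 else 0.0
        ua = float(tp / (tp + fp)) if tp + fp > 0 else 0.0
        f1 = float(2 * pa * ua / (pa + ua)) if pa + ua > 0 else 0.0
        per_class[cname] = {"pa": pa, "ua": ua, "f1": f1}
    return AccuracyReport(oa=oa, per_class=per_class)
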