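"""The four single classifiers (AB, kNN, CT, RF) behind one uniform
contract: fit on a descriptor matrix, emit a positive and a negative
probability plus a hard label per compound.

All four delegate to scikit-learn estimators; the contract layer adds the
conventions that matter for stacking:

* kNN uses inverse-distance voting on z-scored descriptors (scaler fit on
  the training partition only); an exact match gets all the weight, so a
  query identical to a training record returns that record's label with
  probability 1.
* the classification tree reports Laplace-smoothed leaf probabilities
  (a+1)/(n+2) rather than raw leaf fractions, so stacking never sees a
  hard 0 or 1 from it.
* AdaBoost uses 50 rounds of depth-1 stumps; the random forest 100 trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from phenostack.descriptor_engine import DescriptorMatrix
from phenostack.synthetic_data import DEFAULT_SEED

ALGORITHMS = ("AB", "kNN", "CT", "RF")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "AB": {"n_rounds": 50},
    "kNN": {},          # K selected by cross-validation when absent
    "CT": {},
    "RF": {"n_trees": 100},
}


@dataclass
class ClassifierSpec:
    """Which algorithm to fit and with what hyperparameters."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")
        k = self.hyperparameters.get("K")
        if self.algorithm == "kNN" and k is not None and not (1 <= k <= 10):
            raise ValueError("kNN K must be in 1..10")


@dataclass
class ClassifierOutput:
    """Per-compound probabilities and labels; p_positive + p_negative = 1
    and predicted_label = 1 iff p_positive >= 0.5."""

    compound_ids: list[str]
    p_positive: np.ndarray
    p_negative: np.ndarray
    predicted_label: np.ndarray


def default_specs(seed: int = DEFAULT_SEED) -> list[ClassifierSpec]:
    """One spec per algorithm with the documented defaults."""
    return [ClassifierSpec(a, dict(DEFAULT_HYPERPARAMETERS[a]), seed=seed)
            for a in ALGORITHMS]


class FittedClassifier:
    """A fitted base model bound to its training descriptor columns."""

    def __init__(self, spec: ClassifierSpec, estimator, scaler,
                 descriptor_names: list[str], classes: np.ndarray):
        self.spec = spec
        self.estimator = estimator
        self.scaler = scaler
        self.descriptor_names = descriptor_names
        self.classes = classes

    def predict(self, data: DescriptorMatrix) -> ClassifierOutput:
        if data.descriptor_names != self.descriptor_names:
            missing = set(self.descriptor_names) - set(data.descriptor_names)
            extra = set(data.descriptor_names) - set(self.descriptor_names)
            if missing or extra:
                raise ValueError(
                    f"descriptor mismatch: missing {sorted(missing)}, "
                    f"extra {sorted(extra)}")
            data = data.select(self.descriptor_names)
        x = data.values
        if self.scaler is not None:
            x = self.scaler.transform(x)
        p_pos = self._proba_positive(x)
        p_pos = np.clip(p_pos, 0.0, 1.0)
        return ClassifierOutput(
            compound_ids=list(data.compound_ids),
            p_positive=p_pos,
            p_negative=1.0 - p_pos,
            predicted_label=(p_pos >= 0.5).astype(int),
        )

    def _proba_positive(self, x: np.ndarray) -> np.ndarray:
        if self.spec.algorithm == "CT":
            # Laplace-smoothed leaf class fractions instead of raw ones
            tree = self.estimator.tree_
            leaves = self.estimator.apply(x)
            counts = tree.value[leaves, 0, :] * tree.weighted_n_node_samples[leaves, None]
            pos_col = int(np.where(self.estimator.classes_ == 1)[0][0])
            a = counts[:, pos_col]
            n = counts.sum(axis=1)
            return (a + 1.0) / (n + 2.0)
        proba = self.estimator.predict_proba(x)
        pos_col = int(np.where(self.estimator.classes_ == 1)[0][0])
        return proba[:, pos_col]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "FittedClassifier":
        return joblib.load(path)


def _build_estimator(spec: ClassifierSpec, k: int | None = None):
    hp = spec.hyperparameters
    if spec.algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_trees", 100), random_state=spec.seed)
    if spec.algorithm == "AB":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=hp.get("n_rounds", 50), random_state=spec.seed)
    if spec.algorithm == "CT":
        return DecisionTreeClassifier(criterion="entropy", random_state=spec.seed)
    if spec.algorithm == "kNN":
        return KNeighborsClassifier(n_neighbors=k, weights="distance")
    raise AssertionError(spec.algorithm)


def fit(spec: ClassifierSpec, train: DescriptorMatrix) -> FittedClassifier:
    """Fit one base classifier on a labeled training matrix."""
    if train.labels is None:
        raise ValueError("training matrix must carry labels")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data contain a single class")
    scaler = None
    x = train.values
    k = None
    if spec.algorithm == "kNN":
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
        k = spec.hyperparameters.get("K")
        if k is None:
            k = select_k(train, seed=spec.seed)
    est = _build_estimator(spec, k)
    est.fit(x, train.labels)
    return FittedClassifier(spec, est, scaler, list(train.descriptor_names),
                            np.unique(train.labels))


def select_k(train: DescriptorMatrix, k_range: Sequence[int] = range(1, 11),
             seed: int = DEFAULT_SEED, n_folds: int = 5) -> int:
    """Pick kNN's K by maximising 5-fold cross-validated MCC on the
    training partition; ties go to the smallest K."""
    if train.labels is None or len(train.labels) < 10:
        raise ValueError("select_k needs a labeled training set of >= 10 records")
    x = StandardScaler().fit_transform(train.values)
    y = train.labels
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    best_k, best_mcc = None, -np.inf
    for k in k_range:
        preds = np.empty_like(y)
        for tr, va in folds:
            est = KNeighborsClassifier(n_neighbors=min(k, len(tr)),
                                       weights="distance")
            est.fit(x[tr], y[tr])
            preds[va] = est.predict(x[va])
        mcc = matthews_corrcoef(y, preds)
        if mcc > best_mcc + 1e-12:
            best_k, best_mcc = k, mcc
    return int(best_k)
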