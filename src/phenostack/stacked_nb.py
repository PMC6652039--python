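"""Stacked Laplacian-corrected naive Bayesian meta-classification.

The meta-model takes, for every compound, the positive/negative class
probabilities and the hard labels emitted by the four base classifiers
("quoting the probabilities as new descriptors"), optionally concatenates
the compound's fingerprint bits as replenishment descriptors, converts
everything to Boolean features, and classifies with a naive Bayes whose
per-feature probability estimates are shrunk toward the class prior
(Laplacian correction):

    P_base = n_active / n_total                    (class prior)
    K      = 1 / P_base                            (virtual sample count)
    p_F    = (A_F + P_base * K) / (N_F + K)        (corrected estimate)
    W_F    = ln(p_F / P_base)                      (additive feature weight)

where ``N_F`` is the number of training compounds containing feature F and
``A_F`` the number of those that are active.  With K = 1/P_base the
correction adds exactly one virtual active among 1/P_base virtual
compounds, so an unseen feature (N_F = 0) relaxes to the prior and gets
weight 0, and a feature present in every compound likewise carries no
information and gets weight 0.

A compound's relative score is the sum of the weights of its present
features; mapping it through the logistic function anchored at the prior
log-odds yields EstPGood, a probability-scaled score in [0, 1]:

    EstPGood = logistic( ln(P_base / (1 - P_base)) + sum_F W_F )

Meta-features are produced by out-of-fold stacking: the training set is
split into 5 stratified folds and each compound is scored by base models
fit on the other 4 folds, so no base model ever scores a compound it saw
during training.  The final base models are then refit on the full
training partition for use at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logit
from sklearn.model_selection import StratifiedKFold

from phenostack.base_classifiers import (
    ALGORITHMS,
    ClassifierSpec,
    FittedClassifier,
    default_specs,
    fit as fit_classifier,
)
from phenostack.descriptor_engine import (
    DescriptorMatrix,
    SelectionReport,
    fingerprint_matrix,
    select_descriptors,
)
from phenostack.synthetic_data import CompoundRecord, LabeledDataset

DEFAULT_N_BINS = 10


@dataclass
class StackedFeatureTable:
    """Per-compound meta-descriptors: 8 probabilities + 4 hard labels from
    the base models, plus fingerprint bits."""

    compound_ids: list[str]
    meta: np.ndarray                 # (n, 12): p_pos, p_neg per algo + labels
    meta_names: list[str]
    fp_bits: np.ndarray | None = None
    labels: np.ndarray | None = None


@dataclass
class BayesModel:
    """Fitted Laplacian-corrected naive Bayes over Boolean features."""

    p_base: float
    feature_names: list[str]
    a_f: np.ndarray          # active count containing each feature
    n_f: np.ndarray          # total count containing each feature
    weights: np.ndarray
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)
    threshold: float = 0.5
    #: decision cutoff in raw-score space; preferred over ``threshold`` when
    #: set, because EstPGood saturates to 1.0 in floating point for large
    #: scores while raw scores stay distinguishable
    score_threshold: float | None = None
    phenotype: str = ""

    def score(self, features: np.ndarray) -> np.ndarray:
        """Sum of present-feature weights, one score per row."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return features @ self.weights

    def est_p_good(self, features: np.ndarray) -> np.ndarray:
        return expit(logit(self.p_base) + self.score(features))

    def predict(self, features: np.ndarray,
                threshold: float | None = None) -> np.ndarray:
        """Hard labels; ``threshold`` (EstPGood scale) overrides the model
        default, which is the stored score cutoff when one was fitted."""
        if threshold is None and self.score_threshold is not None:
            return (self.score(features) >= self.score_threshold).astype(int)
        t = self.threshold if threshold is None else threshold
        return (self.est_p_good(features) >= t).astype(int)


def quantile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Interior quantile cut points for one continuous feature; duplicate
    edges collapse, so a constant feature yields no edges (one bin)."""
    values = np.asarray(values)
    if values.min() == values.max():
        return np.empty(0)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(values, qs)
    return np.unique(edges)


def booleanize(
    values: np.ndarray,
    names: Sequence[str],
    continuous: Sequence[bool],
    n_bins: int = DEFAULT_N_BINS,
    edges: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, np.ndarray]]:
    """Convert a mixed matrix to Boolean indicator features.

    Continuous columns are cut at training-set quantile edges into at most
    ``n_bins`` intervals, each interval one indicator; exactly one
    indicator per group fires per row, values outside the training range
    fall into the nearest edge bin.  Binary columns pass through unchanged.
    Pass ``edges`` to reuse stored cut points at prediction time.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    fitting = edges is None
    if fitting:
        edges = {}
    cols, out_names = [], []
    for j, name in enumerate(names):
        col = values[:, j]
        if not continuous[j]:
            cols.append(col.astype(np.int8))
            out_names.append(name)
            continue
        if fitting:
            edges[name] = quantile_edges(col, n_bins)
        e = edges[name]
        idx = np.searchsorted(e, col, side="right")
        for b in range(len(e) + 1):
            cols.append((idx == b).astype(np.int8))
            out_names.append(f"{name}__bin{b}")
    return np.column_stack(cols), out_names, edges


def fit_nb(features: np.ndarray, labels: np.ndarray,
           feature_names: Sequence[str] | None = None,
           phenotype: str = "") -> BayesModel:
    """Fit the Laplacian-corrected naive Bayes on a Boolean feature matrix."""
    features = np.atleast_2d(np.asarray(features))
    labels = np.asarray(labels, dtype=int)
    if features.size == 0:
        raise ValueError("empty feature matrix")
    classes = np.unique(labels)
    if not (0 in classes and 1 in classes):
        raise ValueError("both classes must be present to fit")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(features.shape[1])]
    p_base = labels.mean()
    k = 1.0 / p_base
    n_f = features.sum(axis=0).astype(float)
    a_f = features[labels == 1].sum(axis=0).astype(float)
    p_f = (a_f + p_base * k) / (n_f + k)
    weights = np.log(p_f / p_base)
    return BayesModel(p_base=float(p_base), feature_names=list(feature_names),
                      a_f=a_f, n_f=n_f, weights=weights, phenotype=phenotype)


def best_mcc_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """The raw-score cutoff maximising MCC over the given scores.

    Candidates are midpoints of consecutive distinct score values; the
    first maximiser in ascending order wins (deterministic).  Operating on
    raw scores rather than EstPGood avoids the floating-point saturation
    of the logistic at large scores."""
    from phenostack.evaluation import confusion, metrics  # cycle guard

    labels = np.asarray(labels, dtype=int)
    s = np.unique(scores)
    if len(s) == 1:
        return float(s[0])
    candidates = (s[1:] + s[:-1]) / 2
    best_t, best_m = candidates[0], -np.inf
    for t in candidates:
        m = metrics(confusion(labels, (scores >= t).astype(int))).mcc
        if m > best_m + 1e-12:
            best_t, best_m = t, m
    return float(best_t)


@dataclass
class StackedOutput:
    compound_ids: list[str]
    score: np.ndarray
    est_p_good: np.ndarray
    predicted_label: np.ndarray


class NaiveBayesClassifier:
    """A plain (non-stacked) Laplacian-corrected NB over booleanized
    descriptors; serves as the fifth single-model baseline."""

    def __init__(self, n_bins: int = DEFAULT_N_BINS):
        self.n_bins = n_bins
        self.model: BayesModel | None = None
        self.descriptor_names: list[str] | None = None

    def fit(self, train: DescriptorMatrix) -> "NaiveBayesClassifier":
        if train.labels is None:
            raise ValueError("training matrix must carry labels")
        cont = [True] * len(train.descriptor_names)
        feats, names, edges = booleanize(train.values, train.descriptor_names,
                                         cont, self.n_bins)
        self.model = fit_nb(feats, train.labels, names)
        self.model.bin_edges = edges
        self.descriptor_names = list(train.descriptor_names)
        return self

    def predict(self, data: DescriptorMatrix) -> StackedOutput:
        assert self.model is not None
        if data.descriptor_names != self.descriptor_names:
            data = data.select(self.descriptor_names)
        cont = [True] * len(self.descriptor_names)
        feats, _, _ = booleanize(data.values, self.descriptor_names, cont,
                                 self.n_bins, edges=self.model.bin_edges)
        est = self.model.est_p_good(feats)
        return StackedOutput(list(data.compound_ids), self.model.score(feats),
                             est, (est >= self.model.threshold).astype(int))


class StackedModel:
    """The full phenotype model: descriptor selection + four base
    classifiers + Laplacian-corrected NB meta-classifier.

    Self-contained: ``predict`` accepts raw compound records and reproduces
    the entire transformation (column selection, base probabilities,
    booleanization, Bayes scoring) with parameters frozen at fit time.
    """

    def __init__(self, phenotype: str, surviving_descriptors: list[str],
                 selection_report: SelectionReport,
                 base_models: dict[str, FittedClassifier],
                 nb: BayesModel, n_bins: int,
                 use_fingerprints: bool, fingerprint_bits: int | None,
                 training_actives: list[CompoundRecord]):
        self.phenotype = phenotype
        self.surviving_descriptors = surviving_descriptors
        self.selection_report = selection_report
        self.base_models = base_models
        self.nb = nb
        self.n_bins = n_bins
        self.use_fingerprints = use_fingerprints
        self.fingerprint_bits = fingerprint_bits
        #: training actives kept for similarity reporting during screening
        self.training_actives = training_actives

    # -- feature construction -------------------------------------------
    def _meta_from_outputs(self, outputs: dict[str, "ClassifierOutput"]) -> tuple[np.ndarray, list[str], list[bool]]:
        cols, names, continuous = [], [], []
        for algo in ALGORITHMS:
            out = outputs[algo]
            cols += [out.p_positive, out.p_negative]
            names += [f"{algo}_p_pos", f"{algo}_p_neg"]
            continuous += [True, True]
        for algo in ALGORITHMS:
            cols.append(outputs[algo].predicted_label.astype(float))
            names.append(f"{algo}_label")
            continuous.append(False)
        return np.column_stack(cols), names, continuous

    def features_for(self, records: Sequence[CompoundRecord]) -> np.ndarray:
        matrix = DescriptorMatrix.from_records(records, with_labels=False)
        matrix = matrix.select(self.surviving_descriptors)
        outputs = {a: m.predict(matrix) for a, m in self.base_models.items()}
        meta, names, cont = self._meta_from_outputs(outputs)
        feats, _, _ = booleanize(meta, names, cont, self.n_bins,
                                 edges=self.nb.bin_edges)
        if self.use_fingerprints:
            fp = fingerprint_matrix(records, self.fingerprint_bits)
            feats = np.hstack([feats, fp])
        return feats

    def predict(self, records: Sequence[CompoundRecord],
                threshold: float | None = None) -> StackedOutput:
        """Score records; ``threshold`` (EstPGood scale) overrides the
        model's default decision rule."""
        feats = self.features_for(records)
        est = self.nb.est_p_good(feats)
        labels = self.nb.predict(feats, threshold=threshold)
        return StackedOutput([r.id for r in records], self.nb.score(feats),
                             est, labels)


def fit_stacked(
    train: LabeledDataset,
    base_specs: Sequence[ClassifierSpec] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    n_folds: int = 5,
    use_fingerprints: bool = True,
    fingerprint_bits: int | None = None,
    threshold: float | str = "best_mcc",
    seed: int | None = None,
) -> StackedModel:
    """Fit the stacked NB phenotype model on a dataset's training partition.

    ``threshold`` is either a fixed EstPGood cutoff or ``"best_mcc"``
    (the default) to select the raw-score cutoff maximising MCC on the
    out-of-fold training scores — the analogue of a screening platform's
    best-split decision rule, and the reason predicted-active calls can
    occur at EstPGood values far from 0.5.
    """
    if seed is None:
        seed = train.config.seed if train.config else 0
    if base_specs is None:
        base_specs = default_specs(seed)
    specs = {s.algorithm: s for s in base_specs}
    if set(specs) != set(ALGORITHMS):
        raise ValueError(f"need exactly one spec per algorithm {ALGORITHMS}")

    records = train.subset("train")
    matrix = DescriptorMatrix.from_records(records)
    selected, report = select_descriptors(matrix)

    # out-of-fold meta-features: no base model scores its own training rows
    y = np.asarray(selected.labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n = len(records)
    oof = {a: {"p": np.empty(n), "lab": np.empty(n, dtype=int)} for a in ALGORITHMS}
    for tr_idx, va_idx in skf.split(selected.values, y):
        fold_train = DescriptorMatrix(
            [selected.compound_ids[i] for i in tr_idx],
            selected.descriptor_names, selected.values[tr_idx], y[tr_idx])
        fold_val = DescriptorMatrix(
            [selected.compound_ids[i] for i in va_idx],
            selected.descriptor_names, selected.values[va_idx])
        for algo, spec in specs.items():
            out = fit_classifier(spec, fold_train).predict(fold_val)
            oof[algo]["p"][va_idx] = out.p_positive
            oof[algo]["lab"][va_idx] = out.predicted_label

    cols, names, continuous = [], [], []
    for algo in ALGORITHMS:
        cols += [oof[algo]["p"], 1.0 - oof[algo]["p"]]
        names += [f"{algo}_p_pos", f"{algo}_p_neg"]
        continuous += [True, True]
    for algo in ALGORITHMS:
        cols.append(oof[algo]["lab"].astype(float))
        names.append(f"{algo}_label")
        continuous.append(False)
    meta = np.column_stack(cols)

    feats, feat_names, edges = booleanize(meta, names, continuous, n_bins)
    if use_fingerprints:
        fp = fingerprint_matrix(records, fingerprint_bits)
        feats = np.hstack([feats, fp])
        feat_names += [f"fp{j:04d}" for j in range(fp.shape[1])]

    nb = fit_nb(feats, y, feat_names, phenotype=train.phenotype)
    nb.bin_edges = edges
    if threshold == "best_mcc":
        nb.score_threshold = best_mcc_threshold(y, nb.score(feats))
    else:
        nb.threshold = float(threshold)

    # final base models refit on the full training partition
    base_models = {a: fit_classifier(spec, selected) for a, spec in specs.items()}
    actives = [r for r in records if r.label == 1]
    return StackedModel(train.phenotype, list(selected.descriptor_names),
                        report, base_models, nb, n_bins,
                        use_fingerprints, fingerprint_bits, actives)
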