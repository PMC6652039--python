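"""Descriptor matrices, the three-rule correlation-based selection
procedure, and fingerprint utilities.

Selection applies three rules strictly in order:

1. drop descriptors whose single most frequent value occurs in more than
   50% of compounds (near-constant columns);
2. drop descriptors whose absolute Pearson correlation with the 0/1
   activity label is below 0.1 (point-biserial, since the label is binary);
3. for every surviving pair with absolute pairwise correlation above 0.9,
   drop the member with the lower absolute activity correlation (ties: the
   lexicographically later name), visiting pairs in descending order of
   pairwise |r|.

Selection is intended to be fit on the training partition only and the
surviving column set applied unchanged to test and screening data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from phenostack.synthetic_data import CompoundRecord, LabeledDataset

logger = logging.getLogger(__name__)

FREQUENCY_THRESHOLD = 0.5
ACTIVITY_CORR_THRESHOLD = 0.1
PAIRWISE_CORR_THRESHOLD = 0.9


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors with aligned IDs and optional labels."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.compound_ids):
                raise ValueError("labels length mismatch")

    @classmethod
    def from_records(cls, records: Sequence[CompoundRecord],
                     names: Sequence[str] | None = None,
                     with_labels: bool = True) -> "DescriptorMatrix":
        values = np.array([r.descriptors for r in records])
        if names is None:
            names = [f"d{j:03d}" for j in range(values.shape[1])]
        labels = np.array([r.label for r in records]) if with_labels else None
        return cls([r.id for r in records], list(names), values, labels)

    @classmethod
    def from_dataset(cls, dataset: LabeledDataset,
                     partition: str | None = None) -> "DescriptorMatrix":
        records = dataset.records if partition is None else dataset.subset(partition)
        return cls.from_records(records, dataset.descriptor_names())

    def select(self, names: Sequence[str]) -> "DescriptorMatrix":
        """Restrict to the given descriptor columns, preserving their order
        as listed here."""
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(self.compound_ids, list(names),
                                self.values[:, idx], self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.compound_ids,
                          columns=self.descriptor_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        return cls(list(df.index.astype(str)), list(df.columns),
                   df.to_numpy(dtype=float), labels)


@dataclass
class SelectionReport:
    """Where each input descriptor ended up; the four lists partition the
    input names."""

    removed_high_frequency: list[str] = field(default_factory=list)
    removed_low_activity_corr: list[str] = field(default_factory=list)
    removed_pairwise_redundant: list[tuple[str, str]] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "removed_high_frequency": self.removed_high_frequency,
            "removed_low_activity_corr": self.removed_low_activity_corr,
            "removed_pairwise_redundant": [
                {"removed": a, "kept": b} for a, b in self.removed_pairwise_redundant],
            "surviving": self.surviving,
        }, indent=2))


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; 0 (not NaN) when either vector is
    constant, signalling "no association"."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _mode_frequency(column: np.ndarray) -> float:
    _, counts = np.unique(column, return_counts=True)
    return counts.max() / len(column)


def select_descriptors(
    m: DescriptorMatrix,
    frequency_threshold: float = FREQUENCY_THRESHOLD,
    activity_threshold: float = ACTIVITY_CORR_THRESHOLD,
    pairwise_threshold: float = PAIRWISE_CORR_THRESHOLD,
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Apply the three selection rules in order and report every removal.

    Columns containing missing values are unusable and are dropped before
    rule 1 with a warning; they are listed under ``removed_high_frequency``
    alongside the near-constant columns so that the report's four lists
    still partition the input names.  Raises if nothing survives.
    """
    if m.labels is None:
        raise ValueError("labels are required for descriptor selection")
    report = SelectionReport()
    names = list(m.descriptor_names)
    values = m.values

    # columns with missing entries are unusable; drop before rule 1
    has_nan = np.isnan(values).any(axis=0)
    if has_nan.any():
        dropped = [n for n, bad in zip(names, has_nan) if bad]
        warnings.warn(f"dropping descriptors with missing values: {dropped}")
        report.removed_high_frequency.extend(dropped)
        keep = ~has_nan
        names = [n for n, ok in zip(names, keep) if ok]
        values = values[:, keep]

    # rule 1: mode frequency strictly above 50%
    survivors = []
    for j, name in enumerate(names):
        if _mode_frequency(values[:, j]) > frequency_threshold:
            report.removed_high_frequency.append(name)
        else:
            survivors.append(name)
    names = survivors
    idx = {n: m.descriptor_names.index(n) for n in names}

    # rule 2: activity correlation below 0.1 in absolute value
    act_corr = {n: pearson_corr(m.values[:, idx[n]], m.labels) for n in names}
    survivors = []
    for name in names:
        if abs(act_corr[name]) < activity_threshold:
            report.removed_low_activity_corr.append(name)
        else:
            survivors.append(name)
    names = survivors

    # rule 3: pairwise redundancy above 0.9
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = pearson_corr(m.values[:, idx[names[i]]], m.values[:, idx[names[j]]])
            if abs(r) > pairwise_threshold:
                pairs.append((abs(r), names[i], names[j]))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(names)
    for _, a, b in pairs:
        if a not in alive or b not in alive:
            continue
        ca, cb = abs(act_corr[a]), abs(act_corr[b])
        if ca > cb:
            drop, keep_name = b, a
        elif cb > ca:
            drop, keep_name = a, b
        else:  # tie: drop the lexicographically later name
            drop, keep_name = max(a, b), min(a, b)
        alive.discard(drop)
        report.removed_pairwise_redundant.append((drop, keep_name))
    names = [n for n in names if n in alive]

    if not names:
        raise ValueError("no descriptors survive selection")
    report.surviving = names
    logger.info("descriptor selection: %d -> %d columns",
                len(m.descriptor_names), len(names))
    return m.select(names), report


def fold_fingerprints(fp_matrix: np.ndarray, n_bits: int) -> np.ndarray:
    """OR-fold fingerprint rows down to ``n_bits`` columns.

    Output bit j is the OR of input bits {j, j + n_bits, j + 2*n_bits, ...};
    folding to the input width is the identity.
    """
    if n_bits <= 0:
        raise ValueError("n_bits must be positive")
    fp_matrix = np.atleast_2d(np.asarray(fp_matrix))
    width = fp_matrix.shape[1]
    if n_bits > width:
        raise ValueError(f"cannot fold {width} bits up to {n_bits}")
    out = np.zeros((fp_matrix.shape[0], n_bits), dtype=np.int8)
    for start in range(0, width, n_bits):
        chunk = fp_matrix[:, start:start + n_bits]
        out[:, :chunk.shape[1]] |= chunk.astype(np.int8)
    return out


def fingerprint_matrix(records: Sequence[CompoundRecord],
                       n_bits: int | None = None) -> np.ndarray:
    """Stack record fingerprints, optionally OR-folded to ``n_bits``."""
    fp = np.array([r.fingerprint for r in records], dtype=np.int8)
    if n_bits is not None and n_bits != fp.shape[1]:
        fp = fold_fingerprints(fp, n_bits)
    return fp
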