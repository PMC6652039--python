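"""Dual-phenotype consensus virtual screening.

Two fitted phenotype models (hypoxia, "NIN", and peroxide, "NHN") score an
external compound library; compounds predicted active by BOTH form the
consensus set.  Consensus hits are ranked by EstPGood, clustered on
fingerprint Tanimoto distance (average linkage), and per-cluster
representatives are picked by combined EstPGood; each hit also reports its
Dice similarity to the nearest training active as an applicability check.

Per-model decision cutoffs are configurable; the default is the
posterior-majority rule (EstPGood >= 0.5), deliberately more permissive
than the best-split cutoff used for classification reporting, because hit
nomination favours recall and the dual-model consensus plus clustering
absorb the extra false positives.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from phenostack.stacked_nb import StackedModel
from phenostack.synthetic_data import CompoundRecord


@dataclass
class ScreeningHit:
    compound_id: str
    herb: str | None
    est_p_good_nin: float
    est_p_good_nhn: float
    predicted_nin: int
    predicted_nhn: int
    consensus: bool
    cluster_id: int | None = None
    dice_to_nearest_active: float | None = None
    nearest_active_id: str | None = None


def _binary(v: np.ndarray) -> np.ndarray:
    return np.asarray(v).astype(bool)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |a&b| / |a|b|; two empty vectors count as identical."""
    a, b = _binary(a), _binary(b)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|a&b| / (|a| + |b|); two empty vectors count as 1."""
    a, b = _binary(a), _binary(b)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def nearest_active(fp: np.ndarray, actives: Sequence[CompoundRecord]
                   ) -> tuple[float, str | None]:
    """Max Dice similarity of one fingerprint over a set of actives."""
    best, best_id = -1.0, None
    for r in actives:
        d = dice(fp, r.fingerprint)
        if d > best:
            best, best_id = d, r.id
    return best, best_id


def screen(library: Sequence[CompoundRecord],
           model_nin: StackedModel,
           model_nhn: StackedModel,
           threshold_nin: float | None = 0.5,
           threshold_nhn: float | None = 0.5) -> list[ScreeningHit]:
    """Score a library under both phenotype models and flag the consensus.

    Per-model cutoffs default to the posterior-majority rule
    (EstPGood >= 0.5): hit nomination is recall-oriented, since the
    consensus already stacks two filters and downstream clustering and
    manual triage absorb false positives.  Pass ``None`` to use a model's
    own fitted decision rule (typically the precision-oriented best-split
    cutoff used for classification reporting), or any explicit EstPGood
    cutoff.

    Dice similarity to the nearest training active is computed against the
    union of both models' training actives.
    """
    out_nin = model_nin.predict(library, threshold=threshold_nin)
    out_nhn = model_nhn.predict(library, threshold=threshold_nhn)
    reference = {r.id: r for r in (model_nin.training_actives
                                   + model_nhn.training_actives)}
    ref_actives = list(reference.values())
    hits = []
    for i, rec in enumerate(library):
        d, d_id = (nearest_active(rec.fingerprint, ref_actives)
                   if ref_actives else (None, None))
        p_nin = int(out_nin.predicted_label[i])
        p_nhn = int(out_nhn.predicted_label[i])
        hits.append(ScreeningHit(
            compound_id=rec.id, herb=rec.herb,
            est_p_good_nin=float(out_nin.est_p_good[i]),
            est_p_good_nhn=float(out_nhn.est_p_good[i]),
            predicted_nin=p_nin, predicted_nhn=p_nhn,
            consensus=bool(p_nin and p_nhn),
            dice_to_nearest_active=d, nearest_active_id=d_id))
    return hits


def cluster_hits(hits: Sequence[ScreeningHit],
                 fingerprints: dict[str, np.ndarray],
                 k: int) -> dict[str, int]:
    """Cluster hits into k groups by average-linkage agglomeration on
    Tanimoto distance (1 - Tanimoto); assigns ``cluster_id`` in place and
    returns {compound_id: cluster}.  Hits are processed in compound-ID
    order so the assignment is independent of input order."""
    if len(hits) < k:
        raise ValueError(f"need at least k={k} hits, got {len(hits)}")
    ordered = sorted(hits, key=lambda h: h.compound_id)
    fp = np.array([fingerprints[h.compound_id] for h in ordered], dtype=bool)
    if len(ordered) == k:
        assignment = {h.compound_id: i + 1 for i, h in enumerate(ordered)}
    else:
        dist = pdist(fp, metric="jaccard")   # 1 - Tanimoto
        z = linkage(dist, method="average")
        labels = fcluster(z, t=k, criterion="maxclust")
        assignment = {h.compound_id: int(c) for h, c in zip(ordered, labels)}
    for h in hits:
        h.cluster_id = assignment[h.compound_id]
    return assignment


def select_representatives(hits: Sequence[ScreeningHit],
                           n_per_cluster: int = 2) -> list[str]:
    """Per cluster, the top hits by combined EstPGood (NIN + NHN); ties
    broken by compound ID.  Scaffold-novelty judgment is left to the user."""
    by_cluster: dict[int, list[ScreeningHit]] = {}
    for h in hits:
        if h.cluster_id is None:
            raise ValueError("hits must be clustered first")
        by_cluster.setdefault(h.cluster_id, []).append(h)
    chosen = []
    for cid in sorted(by_cluster):
        ranked = sorted(by_cluster[cid],
                        key=lambda h: (-(h.est_p_good_nin + h.est_p_good_nhn),
                                       h.compound_id))
        chosen += [h.compound_id for h in ranked[:n_per_cluster]]
    return chosen


def composition_summary(hits: Sequence[ScreeningHit]) -> pd.DataFrame:
    """Per-herb counts and fractions of compounds predicted NIN-only,
    NHN-only, both, or inactive; untagged compounds group under
    "untagged".  The four fractions sum to 1 per herb."""
    rows = []
    for h in hits:
        if h.consensus:
            cat = "both"
        elif h.predicted_nin:
            cat = "nin_only"
        elif h.predicted_nhn:
            cat = "nhn_only"
        else:
            cat = "inactive"
        rows.append({"herb": h.herb or "untagged", "category": cat})
    df = pd.DataFrame(rows)
    counts = (df.groupby(["herb", "category"]).size()
                .unstack(fill_value=0)
                .reindex(columns=["both", "nin_only", "nhn_only", "inactive"],
                         fill_value=0))
    fractions = counts.div(counts.sum(axis=1), axis=0)
    fractions.columns = [f"frac_{c}" for c in fractions.columns]
    return pd.concat([counts, fractions], axis=1)


def write_hits_csv(hits: Sequence[ScreeningHit], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "herb", "est_p_good_nin", "est_p_good_nhn",
                    "predicted_nin", "predicted_nhn", "consensus",
                    "cluster_id", "dice_to_nearest_active", "nearest_active_id"])
        for h in hits:
            w.writerow([h.compound_id, h.herb or "",
                        repr(h.est_p_good_nin), repr(h.est_p_good_nhn),
                        h.predicted_nin, h.predicted_nhn, int(h.consensus),
                        "" if h.cluster_id is None else h.cluster_id,
                        "" if h.dice_to_nearest_active is None
                        else repr(h.dice_to_nearest_active),
                        h.nearest_active_id or ""])


def read_library_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES file (one compound per line, ID after whitespace);
    returns (smiles, id) pairs.  Fingerprints must be supplied separately
    when structures cannot be perceived."""
    pairs = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        smi = parts[0]
        cid = parts[1] if len(parts) > 1 else f"L{i:04d}"
        pairs.append((smi, cid))
    return pairs
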