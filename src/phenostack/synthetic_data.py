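"""Synthetic compound datasets with clustered active chemotypes and
property-matched decoys.

The generator emulates the statistical structure of a ligand-based
virtual-screening benchmark: actives fall into a small number of chemotype
clusters, each cluster sharing a block of enriched fingerprint bits and a
characteristic region of continuous 2D-descriptor space; decoys are
property-matched to actives on a configurable subset of descriptors
(mimicking physicochemical matching a la DUD-E) while their fingerprints
contain no chemotype signal.  Inactives outnumber actives by a fixed
decoy ratio (default 4:1) and datasets are split 3:1 into train and test,
stratified by class.

Property matching is deliberately partial: the matched descriptor subset is
class-uninformative by construction (decoys copy active values), while the
unmatched subset separates the classes, so that descriptor selection has
real work to do and the base classifiers have signal to find.  Making the
match total would render every descriptor uninformative and the
descriptor-selection step degenerate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

Partition = Literal["train", "test", "unassigned"]

#: Default seed used throughout the package for reproducible runs.
DEFAULT_SEED = 20190710


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic compound generator.

    Attributes
    ----------
    n_actives:
        Number of active compounds (default 116, the size of the smaller
        peroxide-phenotype active set).
    decoy_ratio:
        Decoys generated per active (default 4, i.e. a 4:1 inactive:active
        class balance).
    split_ratio:
        Train:test proportions as a pair of positive integers (default 3:1).
    n_chemotypes:
        Number of active clusters; each owns a disjoint block of signal
        fingerprint bits and a descriptor-space centroid.
    n_fp_bits:
        Fingerprint length in bits.
    n_descriptors:
        Number of continuous 2D-descriptor surrogates.
    signal_bits_per_chemotype:
        Fingerprint bits enriched in each active cluster.
    enrichment:
        Probability in (0, 1] that a signal bit is set in its own cluster's
        actives.
    background_rate:
        Probability in (0, 1) that any bit is set at random.
    noise_sd:
        Standard deviation of descriptor noise around cluster centroids
        (and of the matching noise added to decoy descriptors).
    mean_scale:
        Standard deviation of the chemotype centroid coordinates; controls
        how far apart the active clusters sit in descriptor space.
    matched_fraction:
        Fraction of descriptor dimensions on which decoys are
        property-matched to actives (copied plus noise); the remaining
        dimensions are drawn from the background distribution
        N(0, mean_scale) and therefore carry class signal.
    signal_bit_offset:
        First fingerprint bit of the chemotype signal blocks.  Two
        phenotypes sharing a fingerprint layout use disjoint offsets so a
        compound can carry both signals at once.
    mean_seed:
        Seed of the chemotype-centroid draw.  Defaults to ``seed``; two
        phenotype configs given the same ``mean_seed`` share a centroid
        pool, which lets a single library compound be plausibly active
        under both phenotype models.
    seed:
        Master random seed.
    """

    n_actives: int = 116
    decoy_ratio: int = 4
    split_ratio: tuple[int, int] = (3, 1)
    n_chemotypes: int = 5
    n_fp_bits: int = 256
    n_descriptors: int = 20
    signal_bits_per_chemotype: int = 8
    enrichment: float = 0.9
    background_rate: float = 0.05
    noise_sd: float = 0.5
    mean_scale: float = 2.5
    matched_fraction: float = 0.5
    signal_bit_offset: int = 0
    mean_seed: int | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("n_actives", "decoy_ratio", "n_chemotypes", "n_fp_bits",
                     "n_descriptors", "signal_bits_per_chemotype"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 < self.enrichment <= 1.0):
            raise ValueError("enrichment must be in (0, 1]")
        if not (0.0 < self.background_rate < 1.0):
            raise ValueError("background_rate must be in (0, 1)")
        if self.enrichment <= self.background_rate:
            raise ValueError("enrichment must exceed background_rate; "
                             "otherwise classes are indistinguishable")
        if not (0.0 <= self.matched_fraction <= 1.0):
            raise ValueError("matched_fraction must be in [0, 1]")
        if len(self.split_ratio) != 2 or min(self.split_ratio) < 1:
            raise ValueError("split_ratio must be a pair of positive integers")
        need = self.signal_bit_offset + self.n_chemotypes * self.signal_bits_per_chemotype
        if need > self.n_fp_bits:
            raise ValueError(
                f"signal blocks need {need} bits but fingerprint has {self.n_fp_bits}")

    @property
    def test_fraction(self) -> float:
        a, b = self.split_ratio
        return b / (a + b)

    def signal_bits(self, chemotype: int) -> np.ndarray:
        """Indices of the fingerprint bits owned by one chemotype."""
        s = self.signal_bits_per_chemotype
        start = self.signal_bit_offset + chemotype * s
        return np.arange(start, start + s)


@dataclass
class CompoundRecord:
    """One compound: identity, structure surrogates, label and bookkeeping."""

    id: str
    fingerprint: np.ndarray
    descriptors: np.ndarray
    label: int
    smiles: str | None = None
    chemotype: int | None = None
    herb: str | None = None
    partition: Partition = "unassigned"

    def __post_init__(self) -> None:
        self.fingerprint = np.asarray(self.fingerprint, dtype=np.int8)
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        vals = np.unique(self.fingerprint)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("fingerprint entries must be 0/1")


@dataclass
class LabeledDataset:
    """A phenotype-tagged collection of compounds with a train/test split."""

    phenotype: str
    records: list[CompoundRecord]
    config: GeneratorConfig | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("compound IDs must be unique within a dataset")

    def subset(self, partition: Partition) -> list[CompoundRecord]:
        return [r for r in self.records if r.partition == partition]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def descriptor_names(self) -> list[str]:
        n = len(self.records[0].descriptors)
        return [f"d{j:03d}" for j in range(n)]


def chemotype_means(config: GeneratorConfig) -> np.ndarray:
    """Descriptor-space centroids of the active chemotype clusters.

    Drawn from an RNG seeded only by ``mean_seed`` so that two configs with
    the same value (and the same dimensions) share centroids exactly.
    """
    seed = config.seed if config.mean_seed is None else config.mean_seed
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, config.mean_scale,
                      size=(config.n_chemotypes, config.n_descriptors))


def _sample_fingerprint(rng: np.random.Generator, config: GeneratorConfig,
                        signal_chemotypes: Sequence[int] = ()) -> np.ndarray:
    fp = (rng.random(config.n_fp_bits) < config.background_rate).astype(np.int8)
    for c in signal_chemotypes:
        bits = config.signal_bits(c)
        fp[bits] = (rng.random(len(bits)) < config.enrichment).astype(np.int8)
    return fp


def generate_actives(config: GeneratorConfig) -> list[CompoundRecord]:
    """Generate ``n_actives`` label-1 compounds in chemotype clusters.

    Each active is assigned a chemotype uniformly at random; its fingerprint
    sets the chemotype's signal-bit block with probability ``enrichment``
    (all other bits at ``background_rate``) and its descriptors sit at the
    chemotype centroid plus N(0, noise_sd) noise.
    """
    rng = np.random.default_rng(config.seed)
    means = chemotype_means(config)
    chems = rng.integers(0, config.n_chemotypes, size=config.n_actives)
    records = []
    for i, c in enumerate(chems):
        fp = _sample_fingerprint(rng, config, [int(c)])
        desc = means[c] + rng.normal(0.0, config.noise_sd, config.n_descriptors)
        records.append(CompoundRecord(
            id=f"A{i:04d}", fingerprint=fp, descriptors=desc,
            label=1, chemotype=int(c)))
    return records


def generate_decoys(actives: Sequence[CompoundRecord],
                    config: GeneratorConfig) -> list[CompoundRecord]:
    """Generate ``decoy_ratio`` property-matched label-0 decoys per active.

    Each decoy picks a source active at random; the first
    ``matched_fraction`` of descriptor dimensions are copied from it plus
    N(0, noise_sd) matching noise, the remainder drawn from the background
    distribution N(0, mean_scale).  Fingerprints are pure background: no
    chemotype signal block is enriched.
    """
    if len(actives) == 0:
        raise ValueError("no actives to match")
    rng = np.random.default_rng(config.seed + 1)
    n_decoys = config.decoy_ratio * len(actives)
    n_matched = int(round(config.matched_fraction * config.n_descriptors))
    sources = rng.integers(0, len(actives), size=n_decoys)
    records = []
    for i, s in enumerate(sources):
        fp = _sample_fingerprint(rng, config)
        desc = np.empty(config.n_descriptors)
        desc[:n_matched] = (actives[s].descriptors[:n_matched]
                            + rng.normal(0.0, config.noise_sd, n_matched))
        desc[n_matched:] = rng.normal(0.0, config.mean_scale,
                                      config.n_descriptors - n_matched)
        records.append(CompoundRecord(
            id=f"D{i:04d}", fingerprint=fp, descriptors=desc, label=0))
    return records


def split_train_test(dataset: LabeledDataset,
                     split_ratio: tuple[int, int] | None = None,
                     seed: int | None = None) -> LabeledDataset:
    """Assign every record to train or test, stratified by class.

    Per class, ``n_test = floor(n * test_fraction + 0.5)`` records go to the
    test partition uniformly at random; the rest train.  With 116 actives
    and 464 decoys at 3:1 this yields the canonical 87/348 train and
    29/116 test counts.
    """
    if any(r.partition != "unassigned" for r in dataset.records):
        raise ValueError("dataset already split")
    config = dataset.config
    if split_ratio is None:
        split_ratio = config.split_ratio if config else (3, 1)
    if seed is None:
        seed = (config.seed if config else DEFAULT_SEED) + 2
    a, b = split_ratio
    test_fraction = b / (a + b)
    rng = np.random.default_rng(seed)
    for cls in (0, 1):
        idx = [i for i, r in enumerate(dataset.records) if r.label == cls]
        if not idx:
            raise ValueError(f"class {cls} has no members; cannot split")
        n_test = int(np.floor(len(idx) * test_fraction + 0.5))
        test_idx = set(rng.choice(idx, size=n_test, replace=False).tolist())
        for i in idx:
            dataset.records[i].partition = "test" if i in test_idx else "train"
    return dataset


def generate_dataset(config: GeneratorConfig, phenotype: str = "NHN") -> LabeledDataset:
    """Generate actives + decoys and split them; the one-call entry point."""
    actives = generate_actives(config)
    decoys = generate_decoys(actives, config)
    ds = LabeledDataset(phenotype=phenotype, records=actives + decoys, config=config)
    return split_train_test(ds)


def generate_screening_library(
    nin_config: GeneratorConfig,
    nhn_config: GeneratorConfig,
    n_compounds: int = 200,
    fractions: tuple[float, float, float] = (0.15, 0.15, 0.15),
    herbs: Sequence[str] = tuple("herb%02d" % i for i in range(1, 13)),
    seed: int = DEFAULT_SEED,
) -> tuple[list[CompoundRecord], dict[str, list[str]]]:
    """Generate an external screening library with planted activity signals.

    ``fractions`` gives the proportion of compounds carrying (dual, NIN-only,
    NHN-only) signal; the remainder are background.  The two phenotype
    configs must share fingerprint length and descriptor count and should
    use disjoint ``signal_bit_offset`` blocks and a common ``mean_seed`` so
    dual compounds are geometrically consistent under both models.

    Returns the records (labels set to 0 as a placeholder; library truth is
    carried separately) and a dict with the planted ID lists under keys
    ``dual``, ``nin``, ``nhn``.
    """
    if nin_config.n_fp_bits != nhn_config.n_fp_bits:
        raise ValueError("phenotype configs must share fingerprint length")
    if nin_config.n_descriptors != nhn_config.n_descriptors:
        raise ValueError("phenotype configs must share descriptor count")
    herbs = list(herbs)
    rng = np.random.default_rng(seed)
    f_dual, f_nin, f_nhn = fractions
    n_dual = int(round(f_dual * n_compounds))
    n_nin = int(round(f_nin * n_compounds))
    n_nhn = int(round(f_nhn * n_compounds))
    kinds = (["dual"] * n_dual + ["nin"] * n_nin + ["nhn"] * n_nhn
             + ["none"] * (n_compounds - n_dual - n_nin - n_nhn))
    rng.shuffle(kinds)
    means = chemotype_means(nin_config)
    planted: dict[str, list[str]] = {"dual": [], "nin": [], "nhn": []}
    records = []
    for i, kind in enumerate(kinds):
        cid = f"L{i:04d}"
        herb = herbs[int(rng.integers(0, len(herbs)))]
        c_nin = int(rng.integers(0, nin_config.n_chemotypes))
        c_nhn = int(rng.integers(0, nhn_config.n_chemotypes))
        fp = (rng.random(nin_config.n_fp_bits) < nin_config.background_rate).astype(np.int8)
        if kind in ("dual", "nin"):
            bits = nin_config.signal_bits(c_nin)
            fp[bits] = (rng.random(len(bits)) < nin_config.enrichment).astype(np.int8)
        if kind in ("dual", "nhn"):
            bits = nhn_config.signal_bits(c_nhn)
            fp[bits] = (rng.random(len(bits)) < nhn_config.enrichment).astype(np.int8)
        if kind == "none":
            desc = rng.normal(0.0, nin_config.mean_scale, nin_config.n_descriptors)
        else:
            c = c_nin if kind in ("dual", "nin") else c_nhn
            desc = means[c] + rng.normal(0.0, nin_config.noise_sd,
                                         nin_config.n_descriptors)
        if kind != "none":
            planted[kind].append(cid)
        records.append(CompoundRecord(id=cid, fingerprint=fp, descriptors=desc,
                                      label=0, herb=herb))
    return records, planted


# ---------------------------------------------------------------------------
# CSV round-trip

def write_dataset_csv(dataset: LabeledDataset, path: str | Path) -> None:
    """One row per compound: id, label, partition, herb, chemotype,
    descriptor columns, fingerprint as a 0/1 bitstring."""
    path = Path(path)
    names = dataset.descriptor_names()
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label", "partition", "herb", "chemotype",
                    *names, "fingerprint"])
        for r in dataset.records:
            w.writerow([
                r.id, r.label, r.partition,
                r.herb or "", "" if r.chemotype is None else r.chemotype,
                *(repr(float(v)) for v in r.descriptors),
                "".join(map(str, r.fingerprint)),
            ])
    smiles = [(r.id, r.smiles) for r in dataset.records if r.smiles]
    if smiles:
        with path.with_suffix(".smi").open("w") as fh:
            for cid, smi in smiles:
                fh.write(f"{smi}\t{cid}\n")


def read_dataset_csv(path: str | Path, phenotype: str = "NHN") -> LabeledDataset:
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        names = header[5:-1]
        for row in reader:
            cid, label, partition, herb, chem = row[:5]
            desc = np.array([float(v) for v in row[5:5 + len(names)]])
            fp = np.frombuffer(row[-1].encode(), dtype=np.uint8) - ord("0")
            records.append(CompoundRecord(
                id=cid, fingerprint=fp.astype(np.int8), descriptors=desc,
                label=int(label), herb=herb or None,
                chemotype=int(chem) if chem else None,
                partition=partition))  # type: ignore[arg-type]
    return LabeledDataset(phenotype=phenotype, records=records)
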