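"""End-to-end orchestration: generate -> select -> fit bases -> stack ->
evaluate -> screen, with a run manifest for reproducibility.

The default run emulates the published study conditions: a hypoxia
phenotype ("NIN") dataset of 263 actives and a peroxide phenotype ("NHN")
dataset of 116 actives, each with 4:1 property-matched decoys and a
stratified 3:1 train:test split.  The two phenotype generators share the
chemotype centroid pool (same ``mean_seed``) but own disjoint fingerprint
signal-bit blocks, so a screening-library compound can plausibly carry
either or both activity signals.

Every model in {AB, kNN, CT, RF, NB, s-NB} is evaluated by stratified
5-fold cross-validation (the entire pipeline, descriptor selection
included, refit inside every fold) and on the held-out test partition,
yielding a 12-row model-comparison table per phenotype.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from phenostack import __version__
from phenostack.base_classifiers import ALGORITHMS, ClassifierSpec, default_specs, fit as fit_classifier
from phenostack.descriptor_engine import DescriptorMatrix, select_descriptors
from phenostack.evaluation import cross_validate, evaluate_predictions, report_table, roc_auc
from phenostack.screening import (
    cluster_hits,
    composition_summary,
    screen,
    select_representatives,
    write_hits_csv,
)
from phenostack.stacked_nb import NaiveBayesClassifier, StackedModel, fit_stacked
from phenostack.synthetic_data import (
    DEFAULT_SEED,
    GeneratorConfig,
    LabeledDataset,
    generate_dataset,
    generate_screening_library,
    write_dataset_csv,
)

logger = logging.getLogger(__name__)

XXMD_HERBS = (
    "mahuang", "fangji", "renshen", "huangqin", "guizhi", "gancao",
    "shaoyao", "chuanxiong", "xingren", "fangfeng", "fuzi", "shengjiang",
)


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on; YAML round-trippable."""

    seed: int = DEFAULT_SEED
    nin_n_actives: int = 263
    nhn_n_actives: int = 116
    generator: dict = field(default_factory=dict)   # overrides for both phenotypes
    frequency_threshold: float = 0.5
    activity_threshold: float = 0.1
    pairwise_threshold: float = 0.9
    n_bins: int = 10
    stacking_folds: int = 5
    use_fingerprints: bool = True
    fingerprint_bits: int | None = None
    cv_folds: int = 5
    screening_threshold: str | float = "best_mcc"
    library_size: int = 200
    k_clusters: int = 5
    n_per_cluster: int = 2

    def phenotype_config(self, phenotype: str) -> GeneratorConfig:
        base = GeneratorConfig(seed=self.seed)
        n_signal = base.n_chemotypes * base.signal_bits_per_chemotype
        kwargs = dict(
            seed=self.seed if phenotype == "NIN" else self.seed + 1000,
            mean_seed=self.seed,
            n_actives=self.nin_n_actives if phenotype == "NIN" else self.nhn_n_actives,
            signal_bit_offset=0 if phenotype == "NIN" else n_signal,
        )
        kwargs.update(self.generator)
        return GeneratorConfig(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _single_model_fit_predict(algo: str, config: RunConfig, seed: int
                              ) -> Callable:
    """A fold-refittable closure for one single-model pipeline."""

    def fit_predict(train_records, val_records):
        matrix = DescriptorMatrix.from_records(train_records)
        selected, _ = select_descriptors(
            matrix, config.frequency_threshold, config.activity_threshold,
            config.pairwise_threshold)
        val = DescriptorMatrix.from_records(val_records, with_labels=False)
        val = val.select(selected.descriptor_names)
        if algo == "NB":
            model = NaiveBayesClassifier(config.n_bins).fit(selected)
            out = model.predict(val)
            return out.predicted_label, out.est_p_good
        spec = ClassifierSpec(algo, seed=seed)
        out = fit_classifier(spec, selected).predict(val)
        return out.predicted_label, out.p_positive

    return fit_predict


def _stacked_fit_predict(config: RunConfig, phenotype: str, seed: int) -> Callable:
    def fit_predict(train_records, val_records):
        ds = LabeledDataset(phenotype=phenotype, records=[
            dataclasses.replace(r, partition="train") for r in train_records])
        model = fit_stacked(
            ds, default_specs(seed), n_bins=config.n_bins,
            n_folds=config.stacking_folds,
            use_fingerprints=config.use_fingerprints,
            fingerprint_bits=config.fingerprint_bits, seed=seed)
        out = model.predict(val_records)
        return out.predicted_label, out.est_p_good

    return fit_predict


def evaluate_phenotype(dataset: LabeledDataset, config: RunConfig
                       ) -> tuple[pd.DataFrame, StackedModel, dict]:
    """Fit and evaluate all six models on one phenotype dataset.

    Returns the 12-row comparison table, the final stacked model (fit on
    the full training partition, screening threshold applied), and ROC
    data for the stacked model on train and test.
    """
    seed = dataset.config.seed if dataset.config else config.seed
    rows = []
    test_records = dataset.subset("test")
    test_labels = np.array([r.label for r in test_records])

    for algo in (*ALGORITHMS, "NB"):
        fp = _single_model_fit_predict(algo, config, seed)
        cv_mean, cv_sd = cross_validate(fp, dataset, k=config.cv_folds, seed=seed)
        rows.append({"model": algo, "phase": "cv", "metrics": cv_mean, "sd": cv_sd})
        preds, scores = fp(dataset.subset("train"), test_records)
        rows.append({"model": algo, "phase": "test",
                     "metrics": evaluate_predictions(test_labels, preds, scores)})

    sfp = _stacked_fit_predict(config, dataset.phenotype, seed)
    cv_mean, cv_sd = cross_validate(sfp, dataset, k=config.cv_folds, seed=seed)
    rows.append({"model": "s-NB", "phase": "cv", "metrics": cv_mean, "sd": cv_sd})

    stacked = fit_stacked(
        dataset, default_specs(seed), n_bins=config.n_bins,
        n_folds=config.stacking_folds,
        use_fingerprints=config.use_fingerprints,
        fingerprint_bits=config.fingerprint_bits,
        threshold=config.screening_threshold, seed=seed)
    out_test = stacked.predict(test_records)
    rows.append({"model": "s-NB", "phase": "test",
                 "metrics": evaluate_predictions(
                     test_labels, out_test.predicted_label, out_test.est_p_good)})

    train_records = dataset.subset("train")
    train_labels = np.array([r.label for r in train_records])
    out_train = stacked.predict(train_records)
    roc = {
        "train": roc_auc(train_labels, out_train.est_p_good),
        "test": roc_auc(test_labels, out_test.est_p_good),
    }
    return report_table(rows), stacked, roc


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full workflow and write every artifact under ``outdir``.

    Identical config and seed give byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "generate"
        datasets = {}
        for phenotype in ("NIN", "NHN"):
            ds = generate_dataset(config.phenotype_config(phenotype), phenotype)
            write_dataset_csv(ds, outdir / f"dataset_{phenotype.lower()}.csv")
            datasets[phenotype] = ds

        stage = "evaluate"
        models, tables = {}, []
        for phenotype, ds in datasets.items():
            table, stacked, roc = evaluate_phenotype(ds, config)
            table.insert(0, "phenotype", phenotype)
            tables.append(table)
            models[phenotype] = stacked
            stacked.selection_report.to_json(
                outdir / f"selection_{phenotype.lower()}.json")
            pd.DataFrame(roc["test"][0], columns=["fpr", "tpr"]).to_csv(
                outdir / f"roc_test_{phenotype.lower()}.csv", index=False)
            pd.DataFrame(roc["train"][0], columns=["fpr", "tpr"]).to_csv(
                outdir / f"roc_train_{phenotype.lower()}.csv", index=False)
        metrics_table = pd.concat(tables, ignore_index=True)
        metrics_table.to_csv(outdir / "metrics.csv", index=False)

        stage = "screen"
        nin_cfg = config.phenotype_config("NIN")
        nhn_cfg = config.phenotype_config("NHN")
        library, planted = generate_screening_library(
            nin_cfg, nhn_cfg, n_compounds=config.library_size,
            herbs=XXMD_HERBS, seed=config.seed + 2000)
        hits = screen(library, models["NIN"], models["NHN"])
        consensus = [h for h in hits if h.consensus]
        fps = {r.id: r.fingerprint for r in library}
        representatives: list[str] = []
        if len(consensus) >= config.k_clusters:
            cluster_hits(consensus, fps, config.k_clusters)
            representatives = select_representatives(consensus, config.n_per_cluster)
        write_hits_csv(hits, outdir / "screening_hits.csv")
        composition_summary(hits).to_csv(outdir / "composition_summary.csv")
        (outdir / "representatives.json").write_text(json.dumps({
            "representatives": representatives,
            "planted": planted,
            "n_predicted_nin": int(sum(h.predicted_nin for h in hits)),
            "n_predicted_nhn": int(sum(h.predicted_nhn for h in hits)),
            "n_consensus": len(consensus),
        }, indent=2))

        stage = "manifest"
        config.to_yaml(outdir / "config.yaml")
        (outdir / "manifest.json").write_text(json.dumps({
            "package": "phenostack",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "artifacts": sorted(p.name for p in outdir.iterdir()
                                if p.name != "manifest.json"),
        }, indent=2))
    except Exception:
        logger.exception("pipeline failed during stage %r", stage)
        raise
    return outdir
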