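"""Shared fixtures: the default synthetic study conditions and models
fitted on them, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from phenostack import (
    GeneratorConfig,
    fit_stacked,
    generate_dataset,
)
from phenostack.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_dataset(default_config):
    return generate_dataset(default_config, "NHN")


@pytest.fixture(scope="session")
def stacked_model(default_dataset):
    return fit_stacked(default_dataset)


@pytest.fixture(scope="session")
def stacked_model_no_fp(default_dataset):
    return fit_stacked(default_dataset, use_fingerprints=False)


@pytest.fixture(scope="session")
def perfect_signal_models():
    """Two phenotype models at default study size with deterministic
    (enrichment 1.0) chemotype signals, sharing descriptor geometry but
    owning disjoint fingerprint signal blocks."""
    common = dict(n_actives=116, mean_seed=99, enrichment=1.0)
    nin_cfg = GeneratorConfig(seed=101, signal_bit_offset=0, **common)
    nhn_cfg = GeneratorConfig(seed=202, signal_bit_offset=40, **common)
    return (fit_stacked(generate_dataset(nin_cfg, "NIN")),
            fit_stacked(generate_dataset(nhn_cfg, "NHN")),
            nin_cfg, nhn_cfg)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """One full default pipeline run, shared by pipeline and acceptance
    tests."""
    out = tmp_path_factory.mktemp("demo") / "run1"
    run_pipeline(RunConfig(), out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
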