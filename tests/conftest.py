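import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hacf import (
    FeatureRecipe,
    GeneratorConfig,
    KFoldScheme,
    SVMConfig,
    build_labeled_dataset,
    cross_validate,
    feature_matrix,
    train_classifier,
)

EXAMPLE_WORD = "AAGCAGTCGG"  # the 10-base worked example


@pytest.fixture(scope="session")
def example_word() -> str:
    return EXAMPLE_WORD


def random_word(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_training_set():
    """A compact 300 bp labeled dataset for model/scan unit tests."""
    cfg = GeneratorConfig(seed=42, n_pos=12, neg_pos_ratio=5, seq_len=300,
                          insertion_rate=25.0)
    seqs, y = build_labeled_dataset(cfg)
    return cfg, seqs, y


@pytest.fixture(scope="session")
def small_model(small_training_set):
    """Full-SACF + TNF model trained on the 300 bp synthetic set."""
    cfg, seqs, y = small_training_set
    recipe = FeatureRecipe(kind="hacf", seq_len=cfg.seq_len)
    X = feature_matrix(seqs, recipe)
    model = train_classifier(X, y, config=SVMConfig(seed=0), recipe=recipe)
    return model, X, y, seqs


def _cv_auc(seed: int, insertion_rate: float, n_pos: int) -> float:
    cfg = GeneratorConfig(seed=seed, n_pos=n_pos, insertion_rate=insertion_rate)
    seqs, y = build_labeled_dataset(cfg)
    X = feature_matrix(seqs, FeatureRecipe(kind="hacf"))
    report, _ = cross_validate(X, y, KFoldScheme(5), seed=seed)
    return report.auc


@pytest.fixture(scope="session")
def null_pipeline_aucs():
    """5-fold CV AUC of the full pipeline on three null datasets.

    insertion_rate 0 makes positives distributionally identical to
    background, so the pipeline should have no signal to learn.
    n = 825 samples per replicate (75 positives, 1:10 ratio).
    """
    return [_cv_auc(seed, insertion_rate=0.0, n_pos=75) for seed in (101, 102, 103)]


@pytest.fixture(scope="session")
def effect_gradient_aucs():
    """CV AUCs at three increasing motif-insertion rates (one seed family)."""
    return {rate: _cv_auc(7, insertion_rate=rate, n_pos=60) for rate in (2.0, 8.0, 32.0)}
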