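"""Shared fixtures.

The expensive artifacts — the phantom study set, the trained vessel model,
the classifier triples, and the trained classifiers — are built once per
session and shared by the unit and acceptance tests.  All seeds are fixed
so every run of the suite exercises the identical study.
"""

from __future__ import annotations

import numpy as np
import pytest

from fundustruct import nn
from fundustruct.classifier import (BranchSpec, ClassifierTrainConfig, FusionMode,
                                    HeadSpec, train_classifier)
from fundustruct.evaluation import evaluate_model
from fundustruct.phantom import generate_dataset, vessel_patch_pairs
from fundustruct.pipeline import PipelineConfig, sample_to_triple
from fundustruct.vessels import VesselTrainConfig, train_vessel_model

# desk-scale network configuration used by the training fixtures; the
# full-size defaults (branch 64..512, head 2048/4096/4096) are exercised
# structurally in the architecture tests
SMOKE_BRANCH = BranchSpec(conv_filters=(8, 16, 32, 32))
SMOKE_HEAD = HeadSpec(conv_filters=(32, 64, 64), dense_units=(64, 2))

N_PER_CLASS = 32
N_VAL_PER_CLASS = 8
STUDY_SEED = 11


@pytest.fixture(scope="session")
def study_samples():
    """32 phantoms per class, split 24 train / 8 validation per class."""
    samples, table = generate_dataset(N_PER_CLASS, seed=STUDY_SEED)
    train, val = [], []
    count = {"glaucoma": 0, "normal": 0}
    for s in samples:
        if count[s.label] < N_VAL_PER_CLASS:
            val.append(s)
            count[s.label] += 1
        else:
            train.append(s)
    return {"all": samples, "train": train, "val": val, "table": table}


@pytest.fixture(scope="session")
def vessel_run(study_samples):
    """ResU-Net trained on 64 patch pairs from the training phantoms."""
    pairs = vessel_patch_pairs(study_samples["train"], 64, seed=12)
    model, history = train_vessel_model(pairs, VesselTrainConfig(seed=13))
    return {"model": model, "history": history, "pairs": pairs}


@pytest.fixture(scope="session")
def study_triples(study_samples, vessel_run):
    """(image, vessel, disc) classifier triples for train and val phantoms."""
    cfg = PipelineConfig()
    build = lambda ss: [(sample_to_triple(s, vessel_run["model"], cfg), s.label) for s in ss]
    return {"train": build(study_samples["train"]), "val": build(study_samples["val"])}


def _train_run(study_triples, mode: str):
    model, history = train_classifier(
        study_triples["train"], ClassifierTrainConfig(epochs=20, seed=15),
        FusionMode(mode), val_set=study_triples["val"],
        branch_spec=SMOKE_BRANCH, head_spec=SMOKE_HEAD)
    report = evaluate_model(model, study_triples["val"])
    return {"model": model, "history": history, "report": report}


@pytest.fixture(scope="session")
def attention_run(study_triples):
    return _train_run(study_triples, "attention")


@pytest.fixture(scope="session")
def ablation_run(study_triples):
    return _train_run(study_triples, "concat-ablation")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
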