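"""Shared fixtures: small random bags and the cached study models.

The trained-model cache is session-scoped because several acceptance
properties (planted-signal recovery, non-inferiority, enrichment, LOD)
interrogate the same trained models.
"""

import functools

import numpy as np
import pytest

import caremil as cm
from caremil.gated import GatedMilConfig

SEEDS = (0, 1, 2, 3, 4)

# the scaled-down study conditions used by every training-based check
STUDY_PATIENTS = (25, 25)
STUDY_CELLS = 250
STUDY_D = 32

TASK = cm.TaskSpec("al_vs_nl", ("NL", "AL"))


def study_cohort(signal: str, seed: int):
    cfg = cm.two_class_config(signal, n_patients=STUDY_PATIENTS,
                              n_cells_mean=STUDY_CELLS, D=STUDY_D, seed=seed)
    records = cm.generate_cohort(cfg)
    split = cm.split_by_patient(records, (0.6, 0.2, 0.2), seed=seed + 100,
                                stratify_by_label=True)
    return cfg, split


def study_model_config(arch: str, seed: int):
    if arch == "caremil":
        return cm.CaremilConfig(D=STUDY_D, H=32, n_heads=4, n_classes=2, seed=seed,
                                dropout=0.1, aggregator_hidden=(32,),
                                parallel_hidden=(32,), mlp_hidden=(32,))
    return GatedMilConfig(D=STUDY_D, H=32, n_classes=2, seed=seed, dropout=0.1,
                          instance_hidden=(32,), mlp_hidden=(32,))


def study_train_config(seed: int):
    return cm.TrainConfig(epochs=60, learning_rate=3e-3, seed=seed,
                          early_stop_patience=15)


@functools.lru_cache(maxsize=None)
def trained_study_model(arch: str, signal: str, seed: int):
    """Train (once per session) a study model; returns (model, split, test AUROC)."""
    cfg, split = study_cohort(signal, seed)
    model, _ = cm.train_model(arch, split, TASK, study_train_config(seed),
                              model_config=study_model_config(arch, seed))
    auc = cm.evaluate_auroc(model, split.test, TASK)["macro"]
    return model, split, auc


@pytest.fixture(scope="session")
def train_study():
    return trained_study_model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_bag(rng):
    return cm.CellBag("bag-small", rng.normal(size=(12, 6)),
                      cell_types=["lymphocyte"] * 6 + ["blast"] * 6)


@pytest.fixture()
def tiny_cohort(rng):
    """Nine slides over five patients, two embedding dims, typed cells."""
    records = []
    for i in range(9):
        pid = f"P{i % 5}"
        n = 3 + i
        bag = cm.CellBag(f"S{i}", rng.normal(size=(n, 4)),
                         cell_types=list(np.random.default_rng(i).choice(
                             ["blast", "lymphocyte", "monocyte"], size=n)))
        records.append(cm.SlideRecord(bag=bag, patient_id=pid,
                                      label=["AL", "NL"][i % 2],
                                      blast_fraction=0.1 * (i % 5)))
    return records
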