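"""Shared fixtures: phantom cohorts and a trained model.

The expensive fixtures are session-scoped so the end-to-end recovery,
Grad-CAM and evaluation tests share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import neurofuse as nf
from neurofuse import io_preprocess as iop
from neurofuse import synthetic as syn
from neurofuse import train_eval as te

COHORT_SEED = 7
EXPERIMENT_SEED = 0


@pytest.fixture(scope="session")
def phantom_cohort():
    """90-patient preprocessed phantom cohort (30 per class)."""
    spec = syn.PhantomSpec(patients_per_class=30, seed=COHORT_SEED)
    records = syn.generate_cohort(spec)
    return [iop.preprocess_patient(r, syn.brain_masks_for(r)) for r in records]


@pytest.fixture(scope="session")
def trained_model(phantom_cohort):
    """Model trained on folds 1-4 of the phantom cohort, fold 0 held out.

    Returns (model, report, fold0_records).
    """
    split = te.make_folds(phantom_cohort, 5, EXPERIMENT_SEED)
    train_cfg = te.TrainConfig(epochs=4, learning_rate=1e-3, batch_size=8,
                               folds=5, seed=EXPERIMENT_SEED)
    report, preds, history, model = te.evaluate_fold(
        nf.small_config(seed=EXPERIMENT_SEED), phantom_cohort, split, 0, train_cfg)
    fold0 = [r for r in phantom_cohort if split.assignments[r.patient_id] == 0]
    return model, report, fold0


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
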