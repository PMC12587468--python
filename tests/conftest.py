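"""Shared fixtures: a deterministic 6-mouse synthetic cohort with extracted
features, reused by the classifier and acceptance tests (generation is the
expensive step, so it is session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

import electosleep as es
from electosleep.pipeline import PipelineConfig, compute_features

COHORT_SEED = 0
N_MICE = 6
RECORDING_S = 1200.0


@pytest.fixture(scope="session")
def cohort():
    """(recordings, truths) for the default 6-mouse cohort."""
    spec = es.SyntheticCohortSpec(
        n_mice=N_MICE, recording_length_s=RECORDING_S, seed=COHORT_SEED
    )
    pairs = es.generate_cohort(spec)
    return spec, pairs


@pytest.fixture(scope="session")
def cohort_features(cohort):
    """Normalized feature tensors plus flattened features and truth labels
    (invalid windows relabeled UNKNOWN) for every mouse."""
    _spec, pairs = cohort
    cfg = PipelineConfig(out_dir=".")
    tensors, feats, labels = [], [], []
    for rec, truth in pairs:
        tensor = compute_features(rec, cfg)
        y = truth.state_sequence.copy()
        y[~tensor.valid_mask] = es.UNKNOWN
        tensors.append(tensor)
        feats.append(es.flatten(tensor))
        labels.append(y)
    return tensors, feats, labels


@pytest.fixture(scope="session")
def heldout_model(cohort_features):
    """SAE trained on mice 0-4; mouse 5 is held out."""
    _t, feats, labels = cohort_features
    config = es.TrainingConfig(epochs=80, seed=0)
    return es.fit(feats[:5], labels[:5], config, mu=1e-2)


@pytest.fixture(scope="session")
def final_model(cohort_features):
    """SAE trained on all six mice (for factor inspection)."""
    _t, feats, labels = cohort_features
    config = es.TrainingConfig(epochs=80, seed=0)
    return es.fit(feats, labels, config, mu=1e-2)
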