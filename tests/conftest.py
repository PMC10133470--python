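"""Shared fixtures: synthetic cohorts and the full end-to-end experiment.

The heavy ``synthetic_experiment`` fixture runs the complete study protocol
(three repeated LOSO rounds for STGATE and the convolutional baseline on the
default cohort, plus the structure-recovery experiment) once per session; the
acceptance tests assert on its results.
"""

from __future__ import annotations

import numpy as np
import pytest

from stgate.features import FeatureConfig, extract_features
from stgate.model import ModelConfig
from stgate.synthetic import (
    SyntheticSpec,
    generate_dataset,
    random_precision_baseline,
    structure_recovery_score,
)
from stgate.training import (
    FeatureScaler,
    SampleSet,
    TrainConfig,
    build_samples,
    loso_cross_validation,
    train,
    train_profiles,
)
from stgate.viz import average_adjacency

MICRO_SPEC = SyntheticSpec(
    n_subjects=4, n_channels=8, n_classes=2, trials_per_class=2,
    trial_seconds=10.0,
)


def micro_dataset(seed: int = 0):
    """Tiny cohort for fast protocol-level tests."""
    recordings, truth, _ = generate_dataset(MICRO_SPEC, seed)
    tensors = [extract_features(r, FeatureConfig()) for r in recordings]
    return build_samples(tensors), truth


@pytest.fixture(scope="session")
def micro_cohort():
    return micro_dataset(0)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study cohort: 8 subjects, 24 channels, 3 classes."""
    spec = SyntheticSpec()
    recordings, truth, manifest = generate_dataset(spec, 0)
    tensors = [extract_features(r, FeatureConfig()) for r in recordings]
    dataset = build_samples(tensors)
    return {"spec": spec, "truth": truth, "dataset": dataset,
            "manifest": manifest}


@pytest.fixture(scope="session")
def synthetic_experiment(default_cohort):
    """Three repeated LOSO rounds plus the structure-recovery experiment."""
    dataset = default_cohort["dataset"]
    truth = default_cohort["truth"]
    profile = train_profiles()["test"]
    rounds = {}
    for seed in (0, 1, 2):
        tcfg = TrainConfig(learning_rate=profile.learning_rate,
                           max_epochs=profile.max_epochs, seed=seed)
        res_stgate = loso_cross_validation(dataset, ModelConfig(variant="stgate"), tcfg)
        res_base = loso_cross_validation(dataset, ModelConfig(variant="baseline"), tcfg)
        rounds[seed] = {"stgate": res_stgate, "baseline": res_base}
    # structure recovery: models trained on the full cohort, seeds 0-2
    scaler = FeatureScaler().fit(dataset.X)
    scaled = SampleSet(scaler.transform(dataset.X), dataset.y, dataset.subjects)
    adjacencies = []
    for seed in (0, 1, 2):
        tcfg = TrainConfig(learning_rate=profile.learning_rate,
                           max_epochs=profile.max_epochs, seed=seed)
        model, _ = train(scaled, ModelConfig(variant="stgate"), tcfg)
        adjacencies.append(average_adjacency(model, scaled.X))
    a_mean = np.mean(adjacencies, axis=0)
    return {
        "rounds": rounds,
        "precision_at_10": structure_recovery_score(a_mean, truth, 10),
        "random_baseline": random_precision_baseline(truth),
        "adjacency": a_mean,
    }
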