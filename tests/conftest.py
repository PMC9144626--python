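"""Shared fixtures. The expensive ones (trained segmenters, the full-frame
cohort) are session-scoped so the whole suite pays for them once."""

from __future__ import annotations

import numpy as np
import pytest

from phylloseg import (
    CohortSpec,
    DatasetManifest,
    split_dataset,
)
from phylloseg.segmentation import NetworkConfig, TrainingConfig, train as train_op
from phylloseg.synthetic import generate_cohort

COHORT_SEED = 1
DESK_NET = NetworkConfig(encoder_depth=2, base_filters=8)
DESK_EPOCHS = 120


@pytest.fixture(scope="session")
def cohort128() -> DatasetManifest:
    """Default study-design cohort (33 FA + 43 PT, 5+5 patients) rendered at
    128 px for desk-scale segmentation experiments."""
    return generate_cohort(CohortSpec(seed=COHORT_SEED), frame_size=128)


@pytest.fixture(scope="session")
def cohort512() -> DatasetManifest:
    """Default cohort at the full 512 px acquisition frame, for the 4x4
    block subdivision analysis."""
    return generate_cohort(CohortSpec(seed=COHORT_SEED), frame_size=512)


@pytest.fixture(scope="session")
def split50(cohort128) -> DatasetManifest:
    return split_dataset(cohort128, 0.5, rng_seed=7)


@pytest.fixture(scope="session")
def split20(cohort128) -> DatasetManifest:
    return split_dataset(cohort128, 0.2, rng_seed=7)


@pytest.fixture(scope="session")
def model50(split50):
    """Segmenter trained on the 38-image (50%) split with the reported
    optimizer settings at desk scale."""
    return train_op(split50, DESK_NET, TrainingConfig(epochs=DESK_EPOCHS, seed=3))


@pytest.fixture(scope="session")
def model20(split20):
    """Segmenter trained on the 15-image (20%) split."""
    return train_op(split20, DESK_NET, TrainingConfig(epochs=DESK_EPOCHS, seed=3))


@pytest.fixture(scope="session")
def tiny_cohort() -> DatasetManifest:
    """Eight 64-px images (2 patients per class, 2 regions each)."""
    spec = CohortSpec(
        n_patients_per_class=2,
        regions_per_patient_range=(2, 2),
        target_totals={"FA": 4, "PT": 4},
        seed=11,
    )
    return generate_cohort(spec, frame_size=64)


@pytest.fixture(scope="session")
def tiny_model(tiny_cohort):
    """Quickly trained model on the tiny cohort (for plumbing tests, not
    performance claims)."""
    man = split_dataset(tiny_cohort, 0.5, rng_seed=5)
    return train_op(
        man, DESK_NET, TrainingConfig(epochs=25, mini_batch=2, seed=5)
    ), man


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
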