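"""Shared fixtures: the desk-scale synthetic study, trained once per session.

Two models are trained: one on the plain 4-class dataset (the held-out
accuracy probe) and one on the pair-augmented version (the change-point and
attention-structure probes). Training is seeded and takes a couple of
minutes on one CPU; downstream tests reuse the fitted models.
"""

import numpy as np
import pytest

from harformer.augment import PairRule, build_augmented_dataset, plan_counts
from harformer.datasets import stratified_split
from harformer.estimator import TransformerSequenceClassifier
from harformer.synthetic import desk_preset, generate_dataset

STUDY_SEED = 3

TINY_MODEL = dict(d_model=32, d_ff=64, n_heads=2, n_layers=2, batch_size=64)


@pytest.fixture(scope="session")
def desk_dataset():
    return generate_dataset(desk_preset(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def desk_split(desk_dataset):
    return stratified_split(desk_dataset, (0.70, 0.15, 0.15), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def plain_model(desk_split):
    train, val, _ = desk_split
    clf = TransformerSequenceClassifier(
        epochs=30, random_state=STUDY_SEED, **TINY_MODEL
    )
    clf.fit(*train.to_arrays(), validation_data=val.to_arrays())
    return clf


@pytest.fixture(scope="session")
def augmented_dataset(desk_dataset):
    rules = tuple(
        PairRule(a, b) for a in range(4) for b in range(4) if a != b
    )
    plan = plan_counts(rules, desk_dataset.manifest)
    return build_augmented_dataset(desk_dataset, plan, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def augmented_split(augmented_dataset):
    return stratified_split(augmented_dataset, (0.70, 0.15, 0.15), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def pair_model(augmented_split):
    train, val, _ = augmented_split
    clf = TransformerSequenceClassifier(
        epochs=25, random_state=STUDY_SEED, **TINY_MODEL
    )
    clf.fit(*train.to_arrays(), validation_data=val.to_arrays())
    return clf
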