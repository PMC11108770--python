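"""Shared fixtures: cohorts and trained models are expensive, so they are
session-scoped and cached per seed."""
from __future__ import annotations

import numpy as np
import pytest

from echovlm.encoders import EncoderConfig
from echovlm.synthetic import (default_grammar, generate_cohort,
                               standard_cohort_spec)
from echovlm.training import TrainConfig, train


def split_cohort(cohort, n_train_patients=100):
    """Patient-level split of the standard cohort: 100/32 patients, i.e.
    200 training and 64 validation studies."""
    patients = sorted({r.patient_id for r in cohort})
    train_set = set(patients[:n_train_patients])
    tr = [r for r in cohort if r.patient_id in train_set]
    va = [r for r in cohort if r.patient_id not in train_set]
    return tr, va


@pytest.fixture(scope="session")
def vocab():
    return default_grammar()


@pytest.fixture(scope="session")
def cohort_cache():
    cache: dict[int, list] = {}

    def get(seed: int):
        if seed not in cache:
            cache[seed] = generate_cohort(standard_cohort_spec(seed=seed))
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def standard_cohort(cohort_cache):
    return cohort_cache(0)


@pytest.fixture(scope="session")
def trained_cache(cohort_cache):
    """Factory returning (model, train_records, val_records, metrics) for a
    seed, training once per seed for the whole session."""
    cache: dict[int, tuple] = {}

    def get(seed: int):
        if seed not in cache:
            tr, va = split_cohort(cohort_cache(seed))
            res = train(tr, va, EncoderConfig(),
                        TrainConfig(epochs=30, seed=seed))
            cache[seed] = (res.model, tr, va, res.metrics)
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def trained(trained_cache):
    """The seed-0 trained dual encoder and its splits."""
    return trained_cache(0)


@pytest.fixture(scope="session")
def tiny_cohort():
    from echovlm.synthetic import CohortSpec
    return generate_cohort(CohortSpec(
        n_patients=4, studies_per_patient=(2, 2), videos_per_study=(1, 2),
        frames_per_video=(3, 5), seed=11))


def unit_vectors(n, d, seed):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
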