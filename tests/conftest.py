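from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trajalign as ta

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(individuals: dict[str, tuple[list[float], dict[str, list[float]]]]):
    """Hand-build a dataset from {individual: (times, {feature: values})}.

    All individuals must supply the same features; columns are appended in
    the given per-individual sample order.
    """
    first = next(iter(individuals.values()))
    feature_names = list(first[1])
    samples, columns = [], []
    for ind, (times, feats) in individuals.items():
        for k, t in enumerate(times):
            samples.append(ta.SampleRecord(f"{ind}_s{k}", ind, float(t)))
            columns.append([feats[f][k] for f in feature_names])
    return ta.LongitudinalDataset(
        feature_names=feature_names,
        samples=samples,
        values=np.array(columns, dtype=float).T,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Compact synthetic cohort for unit-level checks."""
    return ta.simulate_cohort(
        n_individuals=6,
        timepoints_range=(4, 7),
        n_seed_features=12,
        n_noise_features=30,
        rng_seed=5,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at generator defaults (the documented study conditions)."""
    return ta.simulate_cohort(rng_seed=1)


@pytest.fixture(scope="session")
def default_model(default_cohort):
    return ta.fit(default_cohort.dataset, K=50, n_members=10, rng_seed=1)
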