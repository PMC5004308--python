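"""Shared fixtures and helpers for the test suite."""

import numpy as np
import pandas as pd
import pytest

from omicslink import (
    SimulationConfig,
    SurvivalOutcome,
    generate_two_layer_cohort,
)


def random_outcome(rng, n, event_fraction=0.7, ties=False):
    """Random right-censored outcome; with ``ties`` times are rounded so tied
    event times occur."""
    time = rng.exponential(1.0, size=n)
    if ties:
        time = np.round(time, 1) + 0.05
    event = (rng.random(n) < event_fraction).astype(int)
    if event.sum() < 2:
        event[:2] = 1
    ids = np.array([f"p{i:04d}" for i in range(n)], dtype=object)
    return SurvivalOutcome(time=time, event=event, sample_ids=ids)


def random_matrix(rng, ids, n_cols, prefix):
    return pd.DataFrame(
        rng.standard_normal((len(ids), n_cols)),
        index=pd.Index(ids),
        columns=[f"{prefix}{j}" for j in range(n_cols)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-sample two-layer cohort with planted effects and 50% overlap."""
    cfg = SimulationConfig(
        n_samples=120,
        k_layer_a=30,
        q_layer_b=30,
        n_clinical=3,
        n_true_a=3,
        n_true_b=3,
        effect_a=0.8,
        effect_b=0.6,
        clinical_effect=0.5,
        linkage=0.8,
        overlap_fraction=0.5,
        layer_a_kind="gaussian",
        seed=42,
    )
    return generate_two_layer_cohort(cfg)
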