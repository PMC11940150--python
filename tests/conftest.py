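"""Shared fixtures: tiny simulated cohorts and their feature tables.

Session scope keeps the expensive simulate -> filter -> segment ->
featurize chain to a handful of executions across the whole suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from parkisense.features import FeatureTable, assemble_feature_table
from parkisense.simulate import (
    ClassEffect,
    SimulationConfig,
    cohort_labels,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 participants (6 majority, 2 minority), default class effects."""
    return simulate_cohort(SimulationConfig(n_majority=6, n_minority=2, seed=42))


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    return assemble_feature_table(tiny_cohort)


@pytest.fixture(scope="session")
def tiny_labels(tiny_cohort):
    return cohort_labels(tiny_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """24 participants (18:6) with TUG-restricted class effects: enough for
    cross-validation with 2 minority participants per fold."""
    cfg = SimulationConfig(
        n_majority=18, n_minority=6, seed=7, effect_tasks=frozenset({"tug"})
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return assemble_feature_table(small_cohort)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    return cohort_labels(small_cohort)


def make_gaussian_table(
    n: int = 60,
    p: int = 40,
    n_minority: int = 12,
    n_signal: int = 3,
    shift: float = 2.0,
    seed: int = 0,
    task: str = "tug",
) -> tuple[FeatureTable, np.ndarray]:
    """Plain Gaussian feature table with a few shifted signal columns —
    for classifier-level tests that do not need the signal pipeline."""
    rng = np.random.default_rng(seed)
    y = np.array(["pd"] * (n - n_minority) + ["nonpd"] * n_minority)
    X = rng.standard_normal((n, p))
    for j in range(n_signal):
        X[:, j] += shift * (y == "nonpd")
    cols = [f"{task}.trial1.walk1.acc_v.f{j}" for j in range(p)]
    meta = pd.DataFrame(
        {
            "column": cols,
            "task": task,
            "subtask": "walk1",
            "channel": "acc_v",
            "domain": "time",
            "derivation": "trial1",
            "feature": [f"f{j}" for j in range(p)],
        }
    ).set_index("column")
    values = pd.DataFrame(X, index=[f"P{i:03d}" for i in range(n)], columns=cols)
    return FeatureTable(values, meta), y
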