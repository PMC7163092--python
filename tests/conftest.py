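"""Shared fixtures: small deterministic cohorts and survival instances."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from irgpsig import ExpressionMatrix, SimulationConfig, SurvivalCohort, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A 40-gene, 200-patient cohort with three planted pairs (session-wide)."""
    cfg = SimulationConfig(n_genes=40, n_patients=200, seed=3)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    data = pd.DataFrame(
        {
            "S1": [5.0, 3.0, 1.0, 2.0],
            "S2": [2.0, 2.0, 4.0, 1.0],
            "S3": [1.0, 6.0, 2.0, 2.0],
        },
        index=["GA", "GB", "GC", "GD"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_cohort() -> SurvivalCohort:
    data = pd.DataFrame(
        {
            "time": [3.0, 5.0, 8.0, 12.0, 20.0, 30.0],
            "event": [1, 1, 0, 1, 0, 1],
            "age": [55, 65, 70, 45, 62, 58],
            "sex": ["male", "female", "male", "male", "female", "male"],
            "stage": ["I", "III", "II", "IV", "I", "II"],
        },
        index=pd.Index([f"P{i}" for i in range(6)], name="patient_id"),
    )
    return SurvivalCohort(data)


def random_survival(seed: int, n: int, p: int, betas: np.ndarray | None = None):
    """Binary design + censored exponential survival, for solver tests."""
    rng = np.random.default_rng(seed)
    X = (rng.random((n, p)) < 0.5).astype(float)
    lp = X @ betas if betas is not None else np.zeros(n)
    T = rng.exponential(1.0 / (0.05 * np.exp(lp)))
    C = rng.exponential(30.0, n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return X, time, event
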