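import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from uratepath import AnalysisConfig, SimulationParams, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-sample default-parameter synthetic cohort (fixed seed)."""
    return simulate_cohort(SimulationParams(n=2000, seed=42))


@pytest.fixture(scope="session")
def big_cohort():
    """20,000-sample cohort for parameter-recovery checks (fixed seed)."""
    return simulate_cohort(SimulationParams(n=20000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_cohort(dosages: dict, urate, status=None, sex=None, age=None, bmi=None):
    """Hand-built minimal cohort frame for targeted unit tests."""
    n = len(urate)
    df = pd.DataFrame(dosages, index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"))
    df["urate"] = urate
    df["age"] = age if age is not None else np.linspace(40.0, 60.0, n)
    df["sex"] = sex if sex is not None else ["male"] * n
    df["bmi"] = bmi if bmi is not None else np.full(n, 23.0)
    df["status"] = status if status is not None else ["control"] * n
    return df


@pytest.fixture()
def tiny_cohort_builder():
    return make_cohort
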