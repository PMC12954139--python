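import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from omam import Cohort, GeneratorParams, calibrate_sigma, generate_normal_cohort

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calibrated_sigma():
    """Residual SD calibrated to the reference model fit (adj R^2 0.6634)."""
    return calibrate_sigma(GeneratorParams(seed=0))


@pytest.fixture(scope="session")
def reference_cohort(calibrated_sigma):
    """A mid-sized synthetic reference cohort shared across read-only tests."""
    return generate_normal_cohort(
        GeneratorParams(n=2000, seed=42, residual_sd=calibrated_sigma))


@pytest.fixture
def tiny_frame():
    return pd.DataFrame({
        "subject_id": ["a", "b", "c"],
        "sex": ["male", "female", "male"],
        "age_years": [46.0, 30.0, 60.0],
        "height_m": [1.71, 1.60, 1.80],
        "weight_kg": [65.9, 55.1, 80.0],
    })


@pytest.fixture
def tiny_cohort(tiny_frame):
    return Cohort(tiny_frame, provenance="unit test")


@pytest.fixture
def cohort_file(tmp_path):
    """Write a cohort CSV from rows of (id, sex, age, height, weight, ...)."""

    def _write(rows, header="subject_id,sex,age_years,height_m,weight_kg"):
        path = tmp_path / "cohort.csv"
        lines = [header] + [",".join(str(v) for v in r) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
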