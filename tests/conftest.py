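import math
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from marrowdose import (
    PatientContext,
    PhantomReference,
    load_illustrative_phantom,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

FIXTURE_DIR = Path(__file__).resolve().parents[1] / "fixtures" / "published_cohort"


@pytest.fixture(scope="session")
def phantom_male() -> PhantomReference:
    return load_illustrative_phantom("male")


@pytest.fixture(scope="session")
def phantom_female() -> PhantomReference:
    return load_illustrative_phantom("female")


@pytest.fixture(scope="session")
def toy_phantom() -> PhantomReference:
    """Round-number phantom for hand-checkable dose arithmetic."""
    return PhantomReference(
        sex="male",
        m_wb_kg=70.0,
        m_bm_kg=1.0,
        m_organ_kg={"kidneys": 0.3, "liver": 1.8, "spleen": 0.18},
        s_bm_bm=1e-10,
        s_bm_wb=1e-11,
        s_bm_organ={"kidneys": 2e-12, "liver": 1e-12, "spleen": 1.5e-12},
        a=1.0,
        b=1.0,
        c=1.0,
    )


@pytest.fixture
def toy_patient(toy_phantom) -> PatientContext:
    """Patient whose anatomy equals the toy phantom's (all scaling factors 1)."""
    return PatientContext(
        patient_id="T1",
        sex="male",
        therapy="octreotate",
        injected_activity_bq=7.4e9,
        m_wb_kg=toy_phantom.m_wb_kg,
        hct=0.40,
        m_organ_kg=dict(toy_phantom.m_organ_kg),
        m_bm_kg=toy_phantom.m_bm_kg,
    )


@pytest.fixture(scope="session")
def cohort_tables() -> dict[str, pd.DataFrame]:
    return {
        p.stem: pd.read_csv(p) for p in FIXTURE_DIR.glob("*.csv")
    }


def assert_close(a, b, rel=1e-12, abs_=0.0):
    assert math.isclose(a, b, rel_tol=rel, abs_tol=abs_), f"{a} != {b} (rel {rel})"
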