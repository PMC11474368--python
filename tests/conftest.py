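import numpy as np
import pytest

from onhmismatch import (
    CohortConfig,
    SectorGrid,
    apply_qc,
    build_default_bands,
    generate_cohort,
    screen_eye,
)
from onhmismatch.synthetic import EyeRecord


@pytest.fixture(scope="session")
def grid():
    return SectorGrid()


@pytest.fixture(scope="session")
def bands_rnfl():
    return build_default_bands("RNFL")


@pytest.fixture(scope="session")
def bands_mrw():
    return build_default_bands("BMO_MRW")


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-eye synthetic cohort with ground truth, fixed seed."""
    return generate_cohort(CohortConfig(n_eyes=30), seed=123)


@pytest.fixture(scope="session")
def screened_small_cohort(small_cohort, bands_rnfl, bands_mrw, grid):
    eyes, truth = small_cohort
    kept, _ = apply_qc(eyes)
    results = [screen_eye(eye, bands_rnfl, bands_mrw, grid) for eye in kept]
    return kept, truth, results


def make_eye(rnfl_profile, mrw_sectors, eye_id="E1", age=65.0, qf=30.0, missing=0.0):
    return EyeRecord(
        eye_id=eye_id,
        patient_id="P1",
        laterality="right",
        age=age,
        rnfl_profile=np.asarray(rnfl_profile, dtype=float),
        mrw_sectors=np.asarray(mrw_sectors, dtype=float),
        bmo_area=1.9,
        quality_factor=qf,
        missing_fraction=missing,
    )
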