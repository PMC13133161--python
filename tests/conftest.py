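import numpy as np
import pytest

from fedsurv.cohorts import (
    CentreSpec,
    SimulationConfig,
    default_true_model,
    generate_multicentre_cohort,
)
from fedsurv.data_model import PatientRecord
from fedsurv.fedcox import EncodedCentre


@pytest.fixture
def make_record():
    """Factory for valid patient records with overridable fields."""

    def _make(**kwargs) -> PatientRecord:
        defaults = dict(
            patient_id="P001",
            sex="male",
            age_years=60.0,
            t_stage="T1-2",
            n_stage="N0",
            m_stage="M0",
            gtv_cm3=40.0,
            histology="SCC",
            rt_technique="IMRT/VMAT",
            chemo="mitomycin",
            total_dose_gy=54.0,
            dose_per_fraction_gy=1.8,
            followup_months=48.0,
        )
        defaults.update(kwargs)
        return PatientRecord(**defaults)

    return _make


@pytest.fixture
def worked_node() -> EncodedCentre:
    """The hand-solvable 3-patient cohort: (x, t, event) =
    (1,1,1), (0,2,1), (1,3,1). Closed forms: U(0) = -1/6,
    I(0) = 17/36, first Newton step -6/17, MLE beta = -ln(2)/2."""
    return EncodedCentre(
        centre_id="worked",
        x=np.array([[1.0], [0.0], [1.0]]),
        time=np.array([1.0, 2.0, 3.0]),
        event=np.array([1, 1, 1]),
    )


def small_config(seed: int, sizes=(80, 70, 60, 50), n_validation: int = 0):
    centres = [
        CentreSpec(
            centre_id=f"C{i+1:02d}",
            size=s,
            role="training",
            gtv_median_cm3=30.0 + 10.0 * i,
        )
        for i, s in enumerate(sizes)
    ]
    centres += [
        CentreSpec(centre_id=f"V{j+1:02d}", size=60, role="validation")
        for j in range(n_validation)
    ]
    return SimulationConfig(centres=tuple(centres), seed=seed)


@pytest.fixture
def small_cohort():
    """Four modest training centres (n = 260) from the default truth."""
    return generate_multicentre_cohort(small_config(404), default_true_model())


#: Covariate subset with adequate event support at small n: the rare
#: chemotherapy dummies (~1% prevalence) are identifiable only at the
#: full cohort size.
REDUCED_TERMS = (
    "sex_female",
    "t_stage_t34",
    "n_stage_npos",
    "age_per_decade",
    "log10_gtv",
    "eqd2_per_10gy",
)


@pytest.fixture
def reduced_config():
    from fedsurv.data_model import ModelConfig

    return ModelConfig(outcome="OS", covariates=REDUCED_TERMS)
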