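import pytest

from stroketriage import (
    CohortMix,
    DecayCurve,
    TreatmentRates,
    WorkflowTimes,
    default_config,
    generate_region,
    reference_profiles,
)
from stroketriage.config import CurveSpec, ModelConfig


@pytest.fixture(scope="session")
def workflow():
    return WorkflowTimes()


@pytest.fixture(scope="session")
def linear_curves():
    """Linear decay curves; values re-derivable by hand in the oracles.

    Floors equal the untreated outcome probabilities of the default cohort
    mix, so losing IVT eligibility can never raise the expectation.
    """
    return {
        "evt": DecayCurve("linear", p0=0.70, p_floor=0.10, t_max=400.0),
        "ivt_lvo": DecayCurve("linear", p0=0.50, p_floor=0.10, t_max=300.0),
        "ivt_nlvo": DecayCurve("linear", p0=0.65, p_floor=0.35, t_max=300.0),
    }


@pytest.fixture(scope="session")
def mix():
    return CohortMix(p_lvo=0.6, p_nlvo=0.3, p_other=0.1)


@pytest.fixture(scope="session")
def rates():
    return TreatmentRates(evt_rate=0.9, ivt_rate=0.8, ivt_window=270.0)


@pytest.fixture(scope="session")
def linear_config():
    """Model configuration with linear curves for oracle-checkable runs."""
    return ModelConfig(
        curves={
            "evt": CurveSpec(kind="linear", p0=0.70, p_floor=0.10, t_max=400.0),
            "ivt_lvo": CurveSpec(kind="linear", p0=0.50, p_floor=0.10, t_max=300.0),
            "ivt_nlvo": CurveSpec(kind="linear", p0=0.65, p_floor=0.35, t_max=300.0),
        }
    )


@pytest.fixture(scope="session")
def profiles():
    return reference_profiles()


@pytest.fixture(scope="session")
def toy3():
    return generate_region(1, "toy3")


@pytest.fixture(scope="session")
def model_config():
    return default_config()
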