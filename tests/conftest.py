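import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from evidem import WeightVector, core_framework
from evidem.analysis import OrderingConstraint
from evidem.synthetic_data import reference_panel_scores


@pytest.fixture(scope="session")
def framework():
    return core_framework()


@pytest.fixture(scope="session")
def summaries():
    """Published VPZ/TPZ panel score summaries (means and SDs)."""
    return reference_panel_scores()


@pytest.fixture(scope="session")
def uniform_weights(framework):
    return WeightVector.uniform(framework)


@pytest.fixture(scope="session")
def ordering_constraints():
    """The qualitative weight structure the appraisal panel reported:
    unmet needs weighted highest in its domain, effectiveness = safety,
    drug costs > other medical costs > non-medical costs."""
    return (
        OrderingConstraint("gt", "unmet_needs", "disease_severity"),
        OrderingConstraint("gt", "unmet_needs", "population_size"),
        OrderingConstraint("eq", "comparative_effectiveness", "comparative_safety"),
        OrderingConstraint("gt", "intervention_costs", "other_medical_costs"),
        OrderingConstraint("gt", "other_medical_costs", "non_medical_costs"),
    )
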