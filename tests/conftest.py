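import pytest

from pregpk import SubjectSpec, builtin_drug_path, load_drug


@pytest.fixture
def cfx():
    return load_drug(builtin_drug_path("cefuroxime"))


@pytest.fixture
def cz():
    return load_drug(builtin_drug_path("cefazolin"))


@pytest.fixture
def male70():
    """Reference healthy volunteer of the baseline development studies."""
    return SubjectSpec(age=30, prepregnancy_weight=70, height=178, sex="male")


@pytest.fixture
def female_617():
    """The delivery-cohort subject (30 y, 61.7 kg pre-pregnancy)."""
    def make(ga: float = 0.0) -> SubjectSpec:
        return SubjectSpec(age=30, prepregnancy_weight=61.7, height=163,
                           gestational_age=ga)
    return make
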