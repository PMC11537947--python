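import numpy as np
import pytest

from sacfield import InputModelOptions, ModelConstants, TrialTimeline
from sacfield.parameter_space import ParameterAssignment


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def timeline() -> TrialTimeline:
    return TrialTimeline(target_position_mm=2.0)


@pytest.fixture(scope="session")
def options() -> InputModelOptions:
    return InputModelOptions()


#: A frozen mid-grid marmoset step-2 assignment used as the reference trial
#: for the dual-implementation check and for single-trial properties.
REFERENCE_ASSIGNMENT = {
    "vt_onset": 20.0, "vt_ror": 15.0, "vt_maxval": 8.0,
    "am_onset": 45.0, "am_ror": 8.0, "am_maxval": 6.0,
    "af_onset": 60.0, "af_ror": 10.0, "af_maxval": 6.0,
    "internal_onset": 100.0, "vm_ror": 10.0,
    "vf_ror": 10.0, "vf_maxval": 6.0, "vp_maxval": 6.0,
    "ig_ror": 10.0, "ig_maxval": 6.0,
    "pi_ror": 10.0, "pi_maxval": 6.0,
}


@pytest.fixture(scope="session")
def reference_assignment() -> ParameterAssignment:
    return ParameterAssignment(values=dict(REFERENCE_ASSIGNMENT),
                               species="marmoset", step=2)


def make_assignment(**overrides) -> ParameterAssignment:
    values = dict(REFERENCE_ASSIGNMENT)
    for k, v in overrides.items():
        if k not in values:
            raise KeyError(k)
        values[k] = float(v)
    return ParameterAssignment(values=values)
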