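import dataclasses

import pytest

from alvgas import (AlveolusParameters, BindingParameters, LungScale,
                    default_parameters)


@pytest.fixture
def defaults() -> AlveolusParameters:
    return default_parameters()


@pytest.fixture
def binding() -> BindingParameters:
    return BindingParameters()


@pytest.fixture
def lung() -> LungScale:
    return LungScale()


@pytest.fixture
def halftime_scenario(defaults) -> AlveolusParameters:
    """Alveolar pO2 97 mmHg, deoxygenated inflow at 46 mmHg, defaults otherwise."""
    return dataclasses.replace(defaults, alveolar_pO2=97.0, blood_pO2_in=46.0)
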