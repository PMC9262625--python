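import numpy as np
import pytest

from cpmgdisp.exchange import CpmgSchedule, ExchangeParams, FieldContext
from cpmgdisp.simulate import DEFAULT_FIELDS, DEFAULT_SCHEDULE


@pytest.fixture(scope="session")
def fields():
    return dict(DEFAULT_FIELDS)


@pytest.fixture(scope="session")
def schedule():
    return DEFAULT_SCHEDULE


@pytest.fixture(scope="session")
def field_500(fields):
    return fields["11.7T"]


@pytest.fixture(scope="session")
def field_800(fields):
    return fields["18.8T"]


@pytest.fixture
def cluster1_params():
    """Main-cluster exchange parameters of the isolated DNA-binding domain."""
    return ExchangeParams(
        k_ex=1640.0, p_B=0.042, dw_ppm=1.0,
        r20_by_field={"11.7T": 12.0, "18.8T": 15.0},
    )
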