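import io

import pytest
from hypothesis import HealthCheck, settings

from dbprisk.core_data import builtin_registry, impute_censored, read_samples
from dbprisk.risk_model import builtin_exposure_groups

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# One pseudo-sample carrying the published campaign-wide median
# concentrations (mg/L), with the two majority-censored analytes marked ND.
MEDIANS_CSV = """\
sample_id,waterworks_id,season,stage,source,disinfectant,tcm,dbcm,bdcm,tbm,dcaa,tcaa,ph,pi,fc
M1,WW01,dry,terminal,surface,sodium_hypochlorite,0.0110,0.0013,0.00469,ND,0.0044,ND,7.20,0.69,0.26
"""

# Published campaign-wide median concentrations in mg/L (ND medians at the
# LOD/2 substitution value).
MEDIAN_CONC = {
    "tcm": 1.100e-2,
    "dbcm": 0.130e-2,
    "bdcm": 0.469e-2,
    "tbm": 0.041e-3 / 2,
    "dcaa": 0.44e-2,
    "tcaa": 1.000e-3 / 2,
}


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def groups():
    return builtin_exposure_groups()


@pytest.fixture(scope="session")
def group_lookup(groups):
    return {(g.age_group.value, g.gender.value): g for g in groups}


@pytest.fixture()
def median_samples(registry):
    """The single median pseudo-sample, read and imputed."""
    samples = read_samples(io.StringIO(MEDIANS_CSV))
    return impute_censored(samples, registry)
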