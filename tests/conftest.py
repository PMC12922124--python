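import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from toxmix import datasets

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cd_curve():
    return datasets.reconstructed_curve("Cd")


@pytest.fixture(scope="session")
def zn_curve():
    return datasets.reconstructed_curve("Zn")


@pytest.fixture(scope="session")
def zno_curve():
    return datasets.reconstructed_curve("ZnO")


@pytest.fixture(scope="session")
def cd_zn_components():
    return (datasets.tu_component("Cd"), datasets.tu_component("Zn"))


@pytest.fixture(scope="session")
def cd_zno_components():
    return (datasets.tu_component("Cd"), datasets.tu_component("ZnO"))


@pytest.fixture(scope="session")
def cd_zn_surface_data(cd_zn_components):
    """Printed Cd+Zn observed means as (conc_a, conc_b, fraction) rows."""
    comp_a, comp_b = cd_zn_components
    trials = datasets.cd_zn_trials()
    return pd.DataFrame(
        {
            "conc_a": [t.tu_a * comp_a.lc50_ref for t in trials],
            "conc_b": [t.tu_b * comp_b.lc50_ref for t in trials],
            "obs_fraction": [t.observed_mean / 100.0 for t in trials],
        }
    )
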