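import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ddfetal import MaternalContext, builtin_registry, simulate_ntc, simulate_well
from ddfetal.scenarios import SCENARIOS, params_for_scenario


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def cc_ctx(registry):
    """Maternal c/c on the RHCE C/c assay (fetus-specific channel: HEX/C)."""
    return MaternalContext(registry["RHCE_rs676785"], "c/c")


@pytest.fixture(scope="session")
def rhd_ctx(registry):
    return MaternalContext(registry["RHD_ex7"], "RHD-/RHD-")


@pytest.fixture(scope="session")
def kel_ctx(registry):
    return MaternalContext(registry["KEL_rs8176058"], "KEL2/KEL2")


@pytest.fixture(scope="session")
def positive_well():
    """A simulated heterozygous-fetus well (maternal e/e, fetal E/e)."""
    params = params_for_scenario(
        SCENARIOS[1], fetal_fraction=0.10, maternal_positives=950, seed=421
    )
    return params, simulate_well(params)


@pytest.fixture(scope="session")
def clean_ntc():
    return simulate_ntc(n_droplets=15_000, false_positive_rate=2e-5, seed=7)
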