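import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fetalpbk as fp

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rat_phys():
    return fp.build_physiology("rat")


@pytest.fixture(scope="session")
def human20_phys():
    return fp.build_physiology("human", gestational_age=20)


@pytest.fixture(scope="session")
def human40_phys():
    return fp.build_physiology("human", gestational_age=40)


@pytest.fixture(scope="session")
def compound():
    return fp.load_compound()


@pytest.fixture(scope="session")
def rat_met():
    return fp.load_metabolism("rat")


@pytest.fixture(scope="session")
def human_met():
    return fp.load_metabolism("human")


@pytest.fixture(scope="session")
def rat_oral_sim(rat_phys, compound, rat_met):
    """Single 1 mg/kg oral dose in the rat, 4 days, tight tolerances."""
    reg = fp.DosingRegimen(route="oral", dose=1.0)
    model = fp.build_model(rat_phys, compound, rat_met, reg)
    return fp.simulate(model, 4.0, rtol=1e-8, atol=1e-12, points_per_interval=200)


@pytest.fixture(scope="session")
def rat_iv_sim(rat_phys, compound, rat_met):
    """Single 0.5 mg/kg IV dose in the rat, 1 day."""
    reg = fp.DosingRegimen(route="iv", dose=0.5)
    model = fp.build_model(rat_phys, compound, rat_met, reg)
    return fp.simulate(model, 1.0, rtol=1e-8, atol=1e-12, points_per_interval=200)


@pytest.fixture(scope="session")
def human_ss_sim(human20_phys, compound, human_met):
    """60-day daily oral dosing at the acceptable daily intake, week-20 model."""
    reg = fp.DosingRegimen(
        route="oral", dose=0.01, n_doses=60, interval=24.0, formulation_solubility=323.0
    )
    model = fp.build_model(human20_phys, compound, human_met, reg, bpb_ps=1e-3)
    return fp.simulate(model, 60.0, rtol=1e-8, atol=1e-12, points_per_interval=288)


@pytest.fixture(scope="session")
def adi_regimen_60d():
    return fp.DosingRegimen(
        route="oral", dose=0.01, n_doses=60, interval=24.0, formulation_solubility=323.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
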