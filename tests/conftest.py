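import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirswitch import generate_fixtures, get_mirna
from mirswitch import grammar, optimize
from mirswitch.thermo import EnergyModelParams

PANEL_SEED = 20230


@pytest.fixture(scope="session")
def params():
    return EnergyModelParams()


@pytest.fixture(scope="session")
def panel():
    return generate_fixtures(8, PANEL_SEED)


@pytest.fixture(scope="session")
def mir17():
    return get_mirna("miR-17-5p")


@pytest.fixture(scope="session")
def mir16():
    return get_mirna("miR-16-5p")


@pytest.fixture(scope="session")
def mir206():
    return get_mirna("miR-206-3p")


@pytest.fixture(scope="session")
def reference(panel, mir17):
    """The screened reference input set and its construct family."""
    return optimize.design_reference_panel(mir17, panel.spacers)


@pytest.fixture(scope="session")
def default_designs(panel):
    """Default-assembled switchable guides over the first fixture pairs."""
    out = []
    for m, s in panel.pairs()[:2]:
        out.append(grammar.assemble_full_length(m, s))
        out.append(grammar.assemble_seed_only(m, s))
    return out
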