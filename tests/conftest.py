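import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from pestvalid import load_panel
from pestvalid.validate import (bundled_matrix_effect,
                                bundled_printed_loq,
                                bundled_validation_summary)


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def small_panel(panel):
    """Six analytes spanning small and large MRLs, for fast simulations."""
    from pestvalid.panel import Panel
    names = ["Alachlor", "Deltamethrin", "Mirex", "Bromopropylate",
             "Fenpropathrin", "Procymidone"]
    return Panel([panel[n] for n in names])


@pytest.fixture(scope="session")
def summary():
    return bundled_validation_summary()


@pytest.fixture(scope="session")
def matrix_effects():
    return bundled_matrix_effect()


@pytest.fixture(scope="session")
def printed_loq():
    return bundled_printed_loq()
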