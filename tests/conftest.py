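import numpy as np
import pytest

from dentaltopo.kinematics import load_specimen_table, derived_frame


@pytest.fixture(scope="session")
def table1_records():
    return load_specimen_table("table1")


@pytest.fixture(scope="session")
def table1_derived(table1_records):
    """Specimen table with ln/relative measures attached."""
    return derived_frame(table1_records)


@pytest.fixture(scope="session")
def selection_tables(table1_derived):
    """Both fitted five-model selection tables (upper and lower response)."""
    from dentaltopo.model_selection import build_selection_table, candidate_models

    return {resp: build_selection_table(candidate_models(resp), table1_derived)
            for resp in ("ln_upper", "ln_lower")}


@pytest.fixture()
def rng():
    return np.random.default_rng(20120816)
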