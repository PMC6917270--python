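import pytest

from cprlab.cohort import generate_cohort, make_preset
from cprlab.ecosystem import EcosystemParams
from cprlab.metrics import build_panel


@pytest.fixture(scope="session")
def params():
    return EcosystemParams()


@pytest.fixture(scope="session")
def small_cohort(params):
    """A reduced four-arm cohort (3/3/4/4 groups) for pipeline tests."""
    design = [
        make_preset("A", {"n_groups": 3}),
        make_preset("B", {"n_groups": 3}),
        make_preset("C", {"n_groups": 4}),
        make_preset("D", {"n_groups": 4}),
    ]
    return generate_cohort(design, params, master_seed=2024)


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    return build_panel(small_cohort)
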