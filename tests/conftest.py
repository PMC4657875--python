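import numpy as np
import pandas as pd
import pytest

from commrobust.datasets import (
    SPECIES_ORDER,
    full_mix_proportions,
    minus_cg_proportions,
)
from commrobust.designs import build_designs
from commrobust.plating import load_phenotype_matrix
from commrobust.synthetic import (
    default_interaction_matrix,
    generate_default_profiles,
)


@pytest.fixture(scope="session")
def profiles():
    return generate_default_profiles()


@pytest.fixture(scope="session")
def interactions():
    return default_interaction_matrix()


@pytest.fixture(scope="session")
def phenotype_matrix():
    return load_phenotype_matrix()


@pytest.fixture(scope="session")
def designs():
    return build_designs(list(SPECIES_ORDER), per_member_od=0.05)


@pytest.fixture(scope="session")
def mix_design(designs):
    return next(d for d in designs if d.design_id == "Mix")


@pytest.fixture(scope="session")
def minus_cg_design(designs):
    return next(d for d in designs if d.design_id == "-Cg")


@pytest.fixture(scope="session")
def reference_full_mix():
    """Renormalized 72-h full-mix proportions from the packaged table."""
    return full_mix_proportions()


@pytest.fixture(scope="session")
def reference_minus_cg():
    return minus_cg_proportions()
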