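"""Shared fixtures: planted-signal datasets reused across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucsite.model import train
from nucsite.synthetic import FixtureSpec, make_ligand_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Study-condition fixture: 40 proteins x 60 residues, 6 binding each,
# +6 shift on 3 profile dims over unit noise.  The decoy dims carry the
# partner dataset's signal dims without label association, so that
# cross-prediction compares signal transfer, not feature novelty.
SPEC_ATP = FixtureSpec(n_proteins=40, ligand_het="ATP",
                       signal_dims=(0, 1, 2), decoy_dims=(10, 11, 12), seed=11)
SPEC_GTP_SAME = FixtureSpec(n_proteins=40, ligand_het="GTP",
                            signal_dims=(0, 1, 2), decoy_dims=(10, 11, 12), seed=12)
SPEC_GDP_ORTH = FixtureSpec(n_proteins=40, ligand_het="GDP",
                            signal_dims=(10, 11, 12), decoy_dims=(0, 1, 2), seed=13)

SMALL_SPEC = FixtureSpec(n_proteins=8, chain_length=30, n_binding=4, seed=7)


@pytest.fixture(scope="session")
def atp_dataset():
    return make_ligand_dataset(SPEC_ATP)


@pytest.fixture(scope="session")
def gtp_same_dataset():
    return make_ligand_dataset(SPEC_GTP_SAME)


@pytest.fixture(scope="session")
def gdp_orth_dataset():
    return make_ligand_dataset(SPEC_GDP_ORTH)


@pytest.fixture(scope="session")
def atp_model(atp_dataset):
    return train(atp_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    return make_ligand_dataset(SMALL_SPEC)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
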