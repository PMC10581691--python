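import numpy as np
import pytest

from id2phys import synth


@pytest.fixture(scope="session")
def ls_cell():
    """One default late-spiking cell: (sweeps, ground truth)."""
    return synth.gen_intracellular_cell(synth.default_phenotype("LS"), seed=11)


@pytest.fixture(scope="session")
def is_cell():
    return synth.gen_intracellular_cell(synth.default_phenotype("IS"), seed=12)


@pytest.fixture(scope="session")
def bs_cell():
    return synth.gen_intracellular_cell(synth.default_phenotype("BS"), seed=13)


@pytest.fixture(scope="session")
def session_bundle():
    """One default in vivo session shared across read-only analyses."""
    return synth.gen_session(synth.SessionSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
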