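import numpy as np
import pytest

from ahrscreen import GeneratorConfig, MoleculeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """A reduced synthetic campaign that keeps unit tests fast."""
    return GeneratorConfig(
        seed=7, n_candidates=120, n_typical_refs=20, n_atypical_refs=5,
        n_planted_analogs=20, n_excluded_decoys=5,
    )


@pytest.fixture
def aromatic_records():
    return [
        MoleculeRecord(id="benzene", smiles="c1ccccc1"),
        MoleculeRecord(id="naphthalene", smiles="c1ccc2ccccc2c1"),
        MoleculeRecord(id="biphenyl", smiles="c1ccc(-c2ccccc2)cc1"),
        MoleculeRecord(id="chlorobenzene", smiles="Clc1ccccc1"),
        MoleculeRecord(id="toluene", smiles="Cc1ccccc1"),
        MoleculeRecord(id="ethane", smiles="CC"),
    ]
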