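import numpy as np
import pytest

from pfasqsar.chemio import ActivityLabel, MoleculeRecord
from pfasqsar.synthetic_data import FluorinationSpec, SyntheticSpec, generate_dataset


def make_record(mol_id, smiles, label=ActivityLabel.UNLABELED, target="T1"):
    return MoleculeRecord(id=mol_id, smiles=smiles, labels={target: label})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """200 molecules with known fluorination/motif ground truth."""
    spec = SyntheticSpec(
        n_molecules=200,
        labeled_fraction=0.5,
        fluorination=FluorinationSpec(p_cf=0.5, p_c3f6=0.2),
        seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def medium_dataset():
    """500 molecules, default-ish spec, for filter/oracle sweeps."""
    spec = SyntheticSpec(
        n_molecules=500,
        fluorination=FluorinationSpec(p_cf=0.6, p_c3f6=0.25),
        seed=11,
    )
    return generate_dataset(spec)
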