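import pytest
from rdkit import Chem

from molcf import SamplerConfig, parse_molecule
from molcf.fixtures import fixture_molecules


@pytest.fixture(scope="session")
def fixture_smiles() -> list[str]:
    return fixture_molecules()


@pytest.fixture(scope="session")
def aspirin():
    return parse_molecule("CC(=O)OC1=CC=CC=C1C(=O)O")


@pytest.fixture(scope="session")
def acid_base():
    """Hydrocinnamic acid: a carboxylic-acid-bearing base molecule."""
    return parse_molecule("OC(=O)CCc1ccccc1")


def small_config(n=200, seed=7, **kwargs) -> SamplerConfig:
    return SamplerConfig(num_samples=n, seed=seed, **kwargs)


def heavy_atoms(smiles: str) -> int:
    return Chem.MolFromSmiles(smiles).GetNumHeavyAtoms()
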