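import pytest

from mpcscreen.chem_core import (
    deprotonate_acids,
    embed_conformers,
    load_registry,
    parse_structure,
)
from mpcscreen.pharmacophore import build_hypothesis
from mpcscreen.synthetic_data import DeckSpec, generate_deck


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def uk_molecule():
    return parse_structure("UK-5099")


@pytest.fixture(scope="session")
def uk_anion_conformer(uk_molecule):
    return embed_conformers(deprotonate_acids(uk_molecule), 1, seed=7)[0]


@pytest.fixture(scope="session")
def hypothesis(uk_anion_conformer):
    return build_hypothesis(uk_anion_conformer)


@pytest.fixture(scope="session")
def small_deck():
    """20-decoy deck with reference, actives and ester negatives (seed 5)."""
    return generate_deck(DeckSpec(n_decoys=20, seed=5, include_reference=True))
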