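import numpy as np
import pytest

from atommatch.reaction import Reaction, ReactionEdits
from atommatch.molgraph import graph_from_smiles
from atommatch.synthetic import GeneratorConfig, generate_reaction


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def identity_reaction(smiles: str) -> Reaction:
    """Reaction whose product equals its reactant, identity correspondence."""
    reactants = graph_from_smiles(smiles)
    products = graph_from_smiles(smiles)
    return Reaction(reactants=reactants, products=products,
                    edits=ReactionEdits(),
                    gt_matrix=np.eye(reactants.atom_count, dtype=np.int8))


@pytest.fixture(scope="session")
def small_reactions():
    """Forty small synthetic reactions shared across tests."""
    gen = np.random.default_rng(7)
    cfg = GeneratorConfig(atom_range=(5, 10), edit_range=(1, 2),
                          symmetry_fraction=0.4, seed=7)
    return [generate_reaction(cfg, gen)[1] for _ in range(40)]
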