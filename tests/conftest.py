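import copy

import numpy as np
import pytest

from rnpqa.decoygen import make_toy_complex
from rnpqa.features import featurize
from rnpqa.model import ModelConfig, init_model
from rnpqa.structure import Atom, Chain, ComplexStructure, PolymerType, Residue


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(12, 8, seed=1)


@pytest.fixture(scope="session")
def toy_graph(toy_complex):
    return featurize(toy_complex)


@pytest.fixture(scope="session")
def model_config():
    return ModelConfig(hidden_dim=32, attention_heads=4, seed=11)


@pytest.fixture(scope="session")
def model_params(model_config):
    return init_model(model_config)


@pytest.fixture(scope="session")
def two_protein_complex():
    """Complex with two protein chains both contacting one RNA chain."""
    base = make_toy_complex(10, 8, seed=21)
    rna = base.chain("R")
    prot_a = base.chain("A")
    # second protein chain: the first one reflected through the RNA centroid
    centroid = np.mean(
        [a.coord for r in rna.residues for a in r.atoms], axis=0
    )
    residues = []
    for res in prot_a.residues:
        atoms = [
            Atom(a.name, a.element, 2 * centroid - a.coord, a.occupancy) for a in res.atoms
        ]
        residues.append(Residue("B", res.seq_index, res.name, atoms, PolymerType.PROTEIN))
    chain_b = Chain("B", PolymerType.PROTEIN, residues)
    return ComplexStructure(
        chains=[copy.deepcopy(prot_a), chain_b, copy.deepcopy(rna)],
        source_path="<two-protein>",
    )


def permute_graph(graph, perm):
    """Relabel graph nodes by a permutation (test helper)."""
    g = copy.copy(graph)
    inv = np.argsort(perm)
    g.residues = [graph.residues[i] for i in perm]
    g.node_feat = graph.node_feat[perm]
    g.arcs = inv[graph.arcs]
    g.interface_mask = graph.interface_mask[perm]
    g.polymer_flags = graph.polymer_flags[perm]
    return g
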