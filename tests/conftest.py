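import numpy as np
import pytest

from glycrunch.glycans import parse_iupac


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def branch_trisaccharide():
    """Sialylated core: GlcNAc and Neu5Ac on a GalNAc root."""
    return parse_iupac("GlcNAcβ1-3(Neu5Acα2-6)GalNAc")


@pytest.fixture
def linear_trisaccharide():
    return parse_iupac("Neu5Acα2-3Galβ1-3GalNAc")


@pytest.fixture
def core1_reduced():
    return parse_iupac("Galβ1-3GalNAc", reduced=True)


def random_tree(rng: np.random.Generator, n_nodes: int):
    """Uniform random glycan-shaped tree with random labels and linkages."""
    labels = ["GalNAc"] + [
        str(rng.choice(["Gal", "GlcNAc", "Fuc", "Neu5Ac", "Man", "Xyl"]))
        for _ in range(n_nodes - 1)
    ]
    parents = [-1] + [int(rng.integers(i)) for i in range(1, n_nodes)]
    anomeric = ["α", "β", "?"]
    linkages = [""] + [
        f"{rng.choice(anomeric)}{rng.choice([1, 2])}-{rng.choice([2, 3, 4, 6, '?'])}"
        for _ in range(n_nodes - 1)
    ]
    from glycrunch.glycans import GlycanGraph

    return GlycanGraph(labels, parents, linkages)
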