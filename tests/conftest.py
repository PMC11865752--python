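import numpy as np
import pytest

from achescreen.chemclust import MoleculeRecord, SimilarityMatrix
from achescreen.synthdata import GeneratorConfig, gen_library


@pytest.fixture(scope="session")
def small_library():
    """Three scaffold families, ~25 molecules each, with IC50s and MWs."""
    lib, truth = gen_library(GeneratorConfig(seed=11))
    return lib, truth


@pytest.fixture
def one_d_similarity():
    """1-D distance stand-in on points {0, 1, 10}, rescaled into [0,1].

    Distances 1 and 10 map to 0.1 and 1.0 so d(a,b)=0.1, d(a,c)=1.0,
    d(b,c)=0.9 and the average-linkage merge heights are 0.1 and 0.95
    (= 9.5/10 of the hand-traced example).
    """
    d = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 0.9], [1.0, 0.9, 0.0]])
    return SimilarityMatrix(ids=("a", "b", "c"), values=1.0 - d)


@pytest.fixture
def tiny_molecules():
    return [
        MoleculeRecord("m1", "c1ccccc1CCN", ic50_nM=100.0, mw=135.2),
        MoleculeRecord("m2", "c1ccccc1CCCN", ic50_nM=200.0, mw=149.2),
        MoleculeRecord("m3", "C", ic50_nM=300.0, mw=16.0),
    ]
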