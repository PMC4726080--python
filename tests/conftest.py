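import networkx as nx
import pytest

from cofactornet import CofactorTable, SyntheticSpec
from cofactornet.synthetic import generate_cofactor_table


@pytest.fixture
def tiny_catalog() -> CofactorTable:
    return CofactorTable.from_pairs([("P1", "Zn"), ("P1", "Mg"), ("P2", "Zn")])


@pytest.fixture
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        seed=11,
        n_cofactors=15,
        n_proteins=120,
        n_extra_proteins=300,
        n_modules=3,
        module_size=10,
        background_edge_prob=0.01,
        n_background_genes=80,
        n_diseases=8,
        nestedness_shape="perfectly_nested",
    )


@pytest.fixture
def small_catalog(small_spec) -> CofactorTable:
    return generate_cofactor_table(small_spec)
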