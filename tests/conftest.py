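import dendropy
import numpy as np
import pytest

import nirmreg as nr


@pytest.fixture(scope="session")
def nbhd():
    return nr.build_codon_neighborhood()


@pytest.fixture(scope="session")
def table():
    return nr.load_property_table()


@pytest.fixture(scope="session")
def h_table(table):
    return table.select(["h"])


@pytest.fixture()
def toy_tree():
    """Three taxa, labeled internal nodes."""
    return dendropy.Tree.get(
        data="((A:1,B:1)N1:1,C:1)R;", schema="newick",
        suppress_internal_node_taxa=True,
    )


@pytest.fixture()
def toy_sequences():
    """Two codon sites; site 1 has one Met->Ile change on branch N1->A,
    site 2 only a synonymous Lys codon change on branch R->C."""
    return {
        "R": "ATGAAA",
        "N1": "ATGAAA",
        "A": "ATAAAA",
        "B": "ATGAAA",
        "C": "ATGAAG",
    }


@pytest.fixture()
def tiny_dataset():
    """Small, well-behaved regression dataset for sampler unit tests."""
    rng = np.random.default_rng(42)
    I, J = 4, 3
    x = rng.uniform(0.2, 0.9, (I, J))
    y = 1.0 * x + rng.normal(0, 0.05, (I, J))
    return nr.DistanceDataset(
        sites=tuple(range(1, I + 1)),
        properties=("a", "b", "c"),
        y_star=y,
        x_star=x,
        n_obs=np.array([1, 2, 3, 4]),
        zero_mask=(y == 0.0),
        bounded=False,
    )
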