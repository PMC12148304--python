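import numpy as np
import pytest

from fibrilforge import HelixParams, make_fibril, make_template, make_triple_helix
from fibrilforge.pdbio import Structure


@pytest.fixture(scope="session")
def ideal_helix():
    return make_triple_helix(HelixParams(residues_per_chain=30))


@pytest.fixture(scope="session")
def template_text():
    return make_template()


@pytest.fixture()
def fibril20():
    return make_fibril(20, seed=0)


def random_copy_system(rng, n_copies=4, n_atoms=12, box=25.0):
    """Random small multi-copy system for clash-filter tests."""
    copies = []
    elements = np.array(["C", "N", "O", "S"])
    for _ in range(n_copies):
        m = n_atoms
        copies.append(Structure(
            serial=np.arange(1, m + 1, dtype=np.int64),
            name=np.full(m, "CA", dtype="U4"),
            resname=np.full(m, "GLY", dtype="U4"),
            chain_id=np.full(m, "A", dtype="U2"),
            resseq=np.arange(1, m + 1, dtype=np.int64),
            element=rng.choice(elements, size=m).astype("U2"),
            coords=rng.uniform(0, box, size=(m, 3)),
        ))
    return copies
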