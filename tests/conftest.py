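import numpy as np
import pytest

from rcckit.fixtures import make_ideal_helix, make_random_chain
from rcckit.structure_io import Atom, Residue


@pytest.fixture
def helix30():
    return make_ideal_helix(30, "backbone_plus_dummy_sidechain")


@pytest.fixture
def helix30_ca():
    return make_ideal_helix(30, "ca_only")


@pytest.fixture
def random_chain60():
    return make_random_chain(60, 17, "backbone_plus_dummy_sidechain")


def point_residue(chain_id, ordinal, xyz, name="CA"):
    """Single-atom residue helper for geometric micro-tests."""
    return Residue(
        chain_id=chain_id,
        author_seq_id=ordinal + 1,
        ordinal_index=ordinal,
        residue_name="GLY",
        atoms=[Atom(name=name, element="C", coords=np.asarray(xyz, float))],
    )


def multi_atom_residue(chain_id, ordinal, coords, names=None):
    coords = [np.asarray(c, float) for c in coords]
    names = names or [f"C{i}" if i else "CA" for i in range(len(coords))]
    return Residue(
        chain_id=chain_id,
        author_seq_id=ordinal + 1,
        ordinal_index=ordinal,
        residue_name="UNK",
        atoms=[
            Atom(name=n, element="C", coords=c) for n, c in zip(names, coords)
        ],
    )
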