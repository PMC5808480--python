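import numpy as np
import pytest

from enstab.structure_io import Atom, Structure
from enstab.synthetic import ToySpec, make_toy_structure


@pytest.fixture(scope="session")
def helix_dimer() -> Structure:
    """Two-chain helical toy, 12 residues per chain, fixed seed."""
    return make_toy_structure(ToySpec(n_res_per_chain=12, n_chains=2, geometry="helix", seed=7))


@pytest.fixture(scope="session")
def helix_single() -> Structure:
    return make_toy_structure(ToySpec(n_res_per_chain=10, n_chains=1, geometry="helix", seed=3))


@pytest.fixture(scope="session")
def hairpin() -> Structure:
    return make_toy_structure(
        ToySpec(n_res_per_chain=12, n_chains=1, geometry="sheet_hairpin", seed=5)
    )


def make_atoms(coords, names=None, chain="A", start_res=1, element=None, one_per_residue=True):
    """Small helper to build ad-hoc structures from raw coordinates."""
    atoms = []
    for i, c in enumerate(coords):
        name = names[i] if names else "CA"
        atoms.append(
            Atom(
                serial=i + 1,
                name=name,
                element=element or (name[0] if name[0] != "H" else "H"),
                residue_name="GLY",
                residue_number=start_res + (i if one_per_residue else 0),
                chain_id=chain,
                coords=tuple(float(x) for x in c),
            )
        )
    return atoms


def random_connected_toy(rng, n_nodes=8, box=5.0):
    """Random point cloud tight enough to be connected at the 8 A cutoff."""
    coords = rng.uniform(0, box, size=(n_nodes, 3))
    return Structure("toy", make_atoms(coords))
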