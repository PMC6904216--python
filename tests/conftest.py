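import numpy as np
import pytest

from vsdkit.core import ConformationFrame, ResidueSelection, vdw_radius
from vsdkit.synthetic import make_capacitor_grid, make_helix


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue α-helix, axis along z."""
    return make_helix(20)


@pytest.fixture(scope="session")
def helix20_selection():
    return ResidueSelection("A", range(1, 21), role="helix")


@pytest.fixture(scope="session")
def capacitor_pair():
    """Noise-free planar-capacitor grids at ±100 mV, slab z ∈ [15, 45] Å."""
    return (make_capacitor_grid(voltage=100.0),
            make_capacitor_grid(voltage=-100.0))


def point_frame(coords, elements=None, resids=None, chain="A", names=None):
    """Minimal frame of free atoms for geometric fixtures."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    elements = np.array(elements if elements is not None else ["C"] * n)
    resids = np.array(resids if resids is not None else np.arange(1, n + 1))
    names = np.array(names if names is not None else ["X"] * n)
    return ConformationFrame(
        atom_ids=np.arange(1, n + 1),
        coordinates=coords,
        element=elements,
        vdw_radius=np.array([vdw_radius(e) for e in elements]),
        residue_index=resids,
        residue_name=np.array(["UNK"] * n),
        chain_id=np.array([chain] * n),
        atom_name=names,
    )
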