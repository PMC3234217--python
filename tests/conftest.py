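import numpy as np
import pytest

import leverage_coupling as lc


@pytest.fixture(scope="session")
def toy():
    return lc.make_toy_two_mode_system(seed=0)


@pytest.fixture(scope="session")
def pocket():
    return lc.make_pocket_structure(n_residues=100, seed=0)


@pytest.fixture(scope="session")
def chain20():
    return lc.make_random_ca_chain(20, seed=3)


@pytest.fixture(scope="session")
def pocket_locations(pocket):
    """Shared docking run on the pocket fixture (100 sims)."""
    params = lc.DockingParams(probe_size=4, n_sims=100, n_steps=5000, seed=11)
    return lc.generate_probe_locations(pocket.structure, params)


def make_structure(coords):
    """Bare CAStructure from raw coordinates (chain A, numbered from 1)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    return lc.CAStructure(
        residue_ids=[("A", i + 1, "") for i in range(len(coords))],
        coords=coords,
        labels=["GLY"] * len(coords),
    )
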