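import numpy as np
import pytest

from ribomech.structures import CoarseGrainedStructure, Node, map_chains
from ribomech.synthetic import SyntheticSpec, make_allosteric_fixture, make_state_pair


def cg(coords, chain_ids=None, kinds=None, bfactors=None, name="fixture"):
    """Build a CoarseGrainedStructure directly from coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    chain_ids = chain_ids or ["A"] * n
    kinds = kinds or ["CA"] * n
    counters = {}
    nodes = []
    for i in range(n):
        counters[chain_ids[i]] = counters.get(chain_ids[i], 0) + 1
        nodes.append(Node(
            chain_ids[i], counters[chain_ids[i]],
            "GLY" if kinds[i] == "CA" else "U", kinds[i], coords[i].copy(),
            None if bfactors is None else float(bfactors[i]),
        ))
    return CoarseGrainedStructure(nodes, name=name)


def helix_coords(n, spacing=3.8, radius=8.0, rise_fraction=0.71):
    dz = spacing * rise_fraction
    dtheta = np.sqrt(spacing**2 - dz**2) / radius
    k = np.arange(n)
    return np.column_stack(
        [radius * np.cos(k * dtheta), radius * np.sin(k * dtheta), k * dz]
    )


@pytest.fixture(scope="session")
def helix20():
    return cg(helix_coords(20), name="helix20")


@pytest.fixture(scope="session")
def helix30():
    return cg(helix_coords(30), name="helix30")


@pytest.fixture(scope="session")
def state_pair():
    """One shared study-condition synthetic pair (seed 11)."""
    return make_state_pair(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def state_pair_map(state_pair):
    unbound, bound, _ = state_pair
    return map_chains(unbound, bound)


@pytest.fixture(scope="session")
def allosteric():
    return make_allosteric_fixture(seed=5)


@pytest.fixture(scope="session")
def enm_helix30(helix30):
    from ribomech.enm import build_hessian, compute_modes

    return compute_modes(build_hessian(helix30, cutoff=15.0))
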