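"""Synthetic multi-chain complexes with planted ground truth.

The generator emulates the comparison design of an mRNA-unbound vs
mRNA-bound ribonucleoprotein pair: a large "rRNA-like" scaffold chain (P
nodes) with several small compact "protein" chains (Cα nodes) docked along
it.  The bound state differs by a known rigid rotation of one chain,
optional Gaussian coordinate noise, and optionally an appended "mRNA-like"
ligand chain threaded within contact range of designated chains.  A separate
three-chain fixture plants a unique mechanically favoured communication
bridge.

Geometry is idealised (helices, rings, compact self-avoiding globules with
realistic node spacing), not physically realistic folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structures import CoarseGrainedStructure, Node, StructureError

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PlacementError",
    "make_state_pair",
    "make_allosteric_fixture",
    "make_three_state_series",
]

CA_SPACING = 3.8       # Å, consecutive Cα spacing
P_SPACING = 5.9        # Å, consecutive P spacing
MIN_INTERCHAIN = 2.0   # Å, chain-collision threshold


class PlacementError(StructureError):
    """Two chains collide (inter-chain node pair closer than 2 Å)."""


@dataclass
class SyntheticSpec:
    """Recipe for one unbound/bound state pair.

    Defaults give a ~300-node complex: a 120-node scaffold chain ("R") and
    four 45-node globular protein chains, a 12° planted rotation of chain
    "C" about its centroid, 0.2 Å coordinate noise, and an mRNA-like ligand
    threaded past chains "A" and "B" in the bound state — small enough that
    every dense pipeline stage runs in seconds while keeping the multi-chain
    scaffold-plus-proteins architecture of the real comparison.
    """

    seed: int = 0
    n_chains: int = 4
    nodes_per_chain: int = 45
    scaffold_nodes: int = 120
    geometry: str = "globule"          # helix | globule | ring
    planted_rotation: tuple[str, float, tuple[float, float, float]] | None = \
        ("C", 12.0, (0.0, 0.0, 1.0))
    noise_sigma: float = 0.2           # Å
    stiff_path: list[str] | None = None
    added_ligand_chain: bool = True
    ligand_contact_cutoff: float = 8.0  # Å, for the recorded ligand contact set
    noise_stream: int = 0               # substream id for the coordinate noise

    def protein_chain_ids(self) -> list[str]:
        return [chr(ord("A") + k) for k in range(self.n_chains)]


@dataclass
class GroundTruth:
    """Exact planted quantities for a generated state pair."""

    rotated_chain: str | None
    rotation_angle: float
    rotation_axis: np.ndarray | None
    displaced_indices: np.ndarray
    noise_sigma: float
    ligand_chain: str | None
    ligand_contacts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


# ---------------------------------------------------------------------------
# chain geometries


def _helix(n: int, spacing: float = CA_SPACING, radius: float = 8.0,
           rise_fraction: float = 0.71) -> np.ndarray:
    """Helix with uniform consecutive-node spacing."""
    dz = spacing * rise_fraction
    dtheta = np.sqrt(spacing**2 - dz**2) / radius
    k = np.arange(n)
    return np.column_stack(
        [radius * np.cos(k * dtheta), radius * np.sin(k * dtheta), k * dz]
    )


def _ring(n: int, spacing: float = CA_SPACING) -> np.ndarray:
    radius = spacing / (2 * np.sin(np.pi / n))
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])


def _globule(n: int, rng: np.random.Generator, spacing: float = CA_SPACING) -> np.ndarray:
    """Compact self-avoiding chain grown inside a ball (globular-fold surrogate)."""
    pts = [np.zeros(3)]
    r_max = spacing * (n ** (1 / 3)) * 0.8 + spacing
    while len(pts) < n:
        for _ in range(200):
            step = rng.normal(size=3)
            step *= spacing / np.linalg.norm(step)
            cand = pts[-1] + step
            if np.linalg.norm(cand) > r_max:
                continue
            if len(pts) > 1 and cdist([cand], pts[:-1]).min() < spacing * 0.8:
                continue
            pts.append(cand)
            break
        else:  # stuck in a pocket: hop back to a random accepted node
            pts.append(pts[int(rng.integers(len(pts)))] + np.array([0.0, 0.0, spacing]))
    return np.asarray(pts[:n])


def _sphere_spiral(n: int, radius: float) -> np.ndarray:
    """Phyllotaxis (golden-angle) spiral over a sphere: a compact shell with
    near-uniform node spacing, standing in for a folded rRNA core."""
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.arccos(z)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    return radius * np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), z]
    )


def _chain_coords(geometry: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if geometry == "helix":
        return _helix(n)
    if geometry == "ring":
        return _ring(n)
    if geometry == "globule":
        return _globule(n, rng)
    raise StructureError(f"unknown geometry {geometry!r}")


# ---------------------------------------------------------------------------
# assembly helpers


def _check_collisions(groups: dict[str, np.ndarray]) -> None:
    ids = list(groups)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            d = cdist(groups[ids[a]], groups[ids[b]]).min()
            if d < MIN_INTERCHAIN:
                raise PlacementError(
                    f"chains {ids[a]!r} and {ids[b]!r} collide (min distance {d:.2f} Å)"
                )


def _dock(coords: np.ndarray, anchor: np.ndarray, direction: np.ndarray,
          target: float = 5.0) -> np.ndarray:
    """Slide a chain along ``direction`` until its closest approach to
    ``anchor`` equals ``target`` Å (guarantees contact without collision)."""
    direction = direction / np.linalg.norm(direction)
    for _ in range(12):
        dmin = cdist(coords, anchor).min()
        err = dmin - target
        if abs(err) < 0.3:
            break
        coords = coords + direction * err * 0.9
    return coords


def _assemble(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Spherical-shell scaffold with protein chains docked around its equator.

    Docking slots lie in the equatorial band (elevation alternating ±25°) so
    an mRNA-like strand can later be threaded around the outside of the
    complex at cylindrical radius without crossing the scaffold.
    """
    radius = 0.93 * P_SPACING * np.sqrt(spec.scaffold_nodes / (4.0 * np.pi))
    scaffold = _sphere_spiral(spec.scaffold_nodes, radius)
    groups: dict[str, np.ndarray] = {"R": scaffold}
    chain_ids = spec.protein_chain_ids()
    stiff = set(spec.stiff_path or [])
    for k, cid in enumerate(chain_ids):
        n = spec.nodes_per_chain * (2 if cid in stiff else 1)
        local = _chain_coords(spec.geometry, n, rng)
        local = local - local.mean(axis=0)
        rot = Rotation.from_euler("zyx", rng.uniform(0, 2 * np.pi, size=3)).as_matrix()
        local = local @ rot.T
        phi = 2.0 * np.pi * k / len(chain_ids)
        elev = np.radians(25.0 if k % 2 == 0 else -25.0)
        u = np.array([np.cos(elev) * np.cos(phi),
                      np.cos(elev) * np.sin(phi),
                      np.sin(elev)])
        groups[cid] = _dock(local + 120.0 * u, scaffold, -u, target=6.0)
    _check_collisions(groups)
    return groups


def _thread_ligand(groups: dict[str, np.ndarray], through: list[str],
                   n_nodes: int = 16, clearance: float = 5.0) -> np.ndarray:
    """mRNA-like strand skimming the outer surface of the given chains.

    The strand is an arc in cylindrical coordinates about the scaffold axis
    (z), anchored ``clearance`` Å radially outside the outermost node of each
    threaded chain — guaranteed within contact range of those chains and
    clear of everything closer to the axis.
    """
    ends = []
    for c in through:
        coords = groups[c]
        radial = np.hypot(coords[:, 0], coords[:, 1])
        k = int(np.argmax(radial))
        ends.append((radial[k] + clearance,
                     np.arctan2(coords[k, 1], coords[k, 0]),
                     coords[k, 2]))
    (r0, p0, z0) = ends[0]
    (r1, p1, z1) = ends[-1]
    dp = (p1 - p0 + np.pi) % (2 * np.pi) - np.pi  # short way around
    t = np.linspace(0.0, 1.0, n_nodes)
    r = r0 + t * (r1 - r0)
    phi = p0 + t * dp
    z = z0 + t * (z1 - z0)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _make_nodes(chain_id: str, coords: np.ndarray, kind: str = "CA",
                bfactors: np.ndarray | None = None) -> list[Node]:
    name = "GLY" if kind == "CA" else "U"
    return [
        Node(chain_id, i + 1, name, kind, coords[i].copy(),
             None if bfactors is None else float(bfactors[i]))
        for i in range(coords.shape[0])
    ]


# ---------------------------------------------------------------------------
# public generators


def make_state_pair(
    spec: SyntheticSpec,
) -> tuple[CoarseGrainedStructure, CoarseGrainedStructure, GroundTruth]:
    """Generate an (unbound, bound) structure pair with known ground truth.

    The bound state applies, in order: the planted rigid rotation of one
    chain about its own centroid, Gaussian coordinate noise of width
    ``noise_sigma`` on every node, and (optionally) an appended ligand chain
    threaded past the first two protein chains.  Identical specs (including
    the seed) give bit-identical structures.
    """
    rng = np.random.default_rng(spec.seed)
    groups = _assemble(spec, rng)
    order = ["R"] + spec.protein_chain_ids()

    # synthetic B-factors grow with distance from the complex centroid
    # (periphery is floppier), giving a non-constant experimental column
    centroid = np.vstack([groups[c] for c in order]).mean(axis=0)

    def bf(coords: np.ndarray) -> np.ndarray:
        return 10.0 + 1.5 * np.sqrt(np.linalg.norm(coords - centroid, axis=1))

    unbound_nodes: list[Node] = []
    for cid in order:
        kind = "P" if cid == "R" else "CA"
        unbound_nodes.extend(_make_nodes(cid, groups[cid], kind, bf(groups[cid])))
    unbound = CoarseGrainedStructure(unbound_nodes, name="unbound")

    bound_groups = {cid: coords.copy() for cid, coords in groups.items()}
    rot_chain, angle, axis = None, 0.0, None
    if spec.planted_rotation is not None:
        rot_chain, angle, axis_t = spec.planted_rotation
        if rot_chain not in bound_groups:
            raise StructureError(f"planted rotation targets unknown chain {rot_chain!r}")
        axis = np.asarray(axis_t, dtype=float)
        axis /= np.linalg.norm(axis)
        r = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        c = bound_groups[rot_chain].mean(axis=0)
        bound_groups[rot_chain] = (bound_groups[rot_chain] - c) @ r.T + c
    if spec.noise_sigma > 0:
        noise_rng = np.random.default_rng([spec.seed, 7, spec.noise_stream])
        for cid in order:
            bound_groups[cid] = bound_groups[cid] + noise_rng.normal(
                scale=spec.noise_sigma, size=bound_groups[cid].shape
            )

    bound_nodes: list[Node] = []
    for cid in order:
        kind = "P" if cid == "R" else "CA"
        bound_nodes.extend(_make_nodes(cid, bound_groups[cid], kind, bf(groups[cid])))

    ligand_contacts = np.empty(0, dtype=int)
    ligand_chain = None
    if spec.added_ligand_chain:
        through = spec.protein_chain_ids()[: min(2, spec.n_chains)]
        lig = _thread_ligand(bound_groups, through)
        _check_collisions({**bound_groups, "M": lig})
        ligand_chain = "M"
        bound_nodes.extend(_make_nodes("M", lig, "P", bf(lig)))
        # contact set: indices into the non-ligand prefix (index-aligned with
        # the unbound structure) within the cutoff of any ligand node
        non_lig = np.vstack([bound_groups[c] for c in order])
        d = cdist(non_lig, lig)
        ligand_contacts = np.flatnonzero(d.min(axis=1) <= spec.ligand_contact_cutoff)
    bound = CoarseGrainedStructure(bound_nodes, name="bound")

    displaced = (
        unbound.chain_indices(rot_chain) if rot_chain is not None
        else np.empty(0, dtype=int)
    )
    truth = GroundTruth(
        rotated_chain=rot_chain,
        rotation_angle=float(angle),
        rotation_axis=axis,
        displaced_indices=displaced,
        noise_sigma=spec.noise_sigma,
        ligand_chain=ligand_chain,
        ligand_contacts=ligand_contacts,
    )
    return unbound, bound, truth


def make_three_state_series(
    spec: SyntheticSpec,
) -> tuple[list[CoarseGrainedStructure], list[GroundTruth]]:
    """Unbound → intermediate → bound series (a 30S/30S_IC/70S_IC-style design).

    The intermediate carries half the planted rotation and no ligand; the
    bound state carries the full rotation and the ligand.  All three states
    share the same underlying assembly (same seed).
    """
    if spec.planted_rotation is None:
        raise StructureError("three-state series needs a planted rotation")
    chain, angle, axis = spec.planted_rotation
    half = replace(spec, planted_rotation=(chain, angle / 2.0, axis),
                   added_ligand_chain=False, noise_stream=spec.noise_stream + 1)
    unbound, intermediate, truth_half = make_state_pair(half)
    intermediate.name = "intermediate"
    _, bound, truth_full = make_state_pair(spec)
    return [unbound, intermediate, bound], [truth_half, truth_full]


def make_allosteric_fixture(
    seed: int = 0,
    nodes_per_terminal: int = 24,
    bridge_nodes: int = 90,
    span: float = 110.0,
) -> tuple[CoarseGrainedStructure, dict]:
    """Three-chain fixture with a unique communication bridge.

    Chains A and C are compact globules at opposite ends, farther apart than
    any sensible contact cutoff, touching only through the central chain B —
    a long, dense helical bridge whose extra nodes give it higher contact
    degree (higher random-walk affinity).  Every A→C communication path must
    traverse B.
    """
    rng = np.random.default_rng(seed)
    # dense bridge along x
    x = np.linspace(-span / 2.0, span / 2.0, bridge_nodes)
    theta = np.arange(bridge_nodes) * 0.8
    b = np.column_stack([x, 6.0 * np.cos(theta), 6.0 * np.sin(theta)])

    terminals = {}
    for cid, sign in (("A", -1.0), ("C", 1.0)):
        g = _globule(nodes_per_terminal, rng)
        g = g - g.mean(axis=0) + np.array([sign * (span / 2.0 + 40.0), 0.0, 0.0])
        terminals[cid] = _dock(g, b, np.array([-sign, 0.0, 0.0]))
    groups = {"A": terminals["A"], "B": b, "C": terminals["C"]}
    _check_collisions(groups)

    nodes: list[Node] = []
    for cid in ("A", "B", "C"):
        nodes.extend(_make_nodes(cid, groups[cid], "CA"))
    structure = CoarseGrainedStructure(nodes, name=f"allosteric-{seed}")
    expected = {
        "bridge_chain": "B",
        "terminal_chains": ("A", "C"),
        "bridge_indices": structure.chain_indices("B"),
    }
    return structure, expected
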