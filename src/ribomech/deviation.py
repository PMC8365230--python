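"""Structural deviation between two conformational states.

Optimal rigid-body superposition (Kabsch), global and per-chain RMSD,
per-residue deviations with a mean + 2·SD significance rule, and the rotation
angle of individual chains relative to a reference component ("angle of
deviation").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import ChainMap, CoarseGrainedStructure, StructureError

__all__ = [
    "DegenerateFitError",
    "DeviationReport",
    "superpose",
    "apply_transform",
    "per_residue_deviation",
    "local_rmsd",
    "angle_of_deviation",
    "deviation_report",
]


class DegenerateFitError(StructureError):
    """Fewer than 3 paired nodes, or a collinear node set."""


@dataclass
class PerResidueDeviation:
    index_a: int
    index_b: int
    deviation: float
    significant: bool


@dataclass
class PerProteinDeviation:
    chain_id: str
    local_rmsd: float
    angle_of_deviation: float


@dataclass
class DeviationReport:
    """Summary of the structural change between an unbound and a bound state."""

    global_rmsd: float
    per_protein: list[PerProteinDeviation] = field(default_factory=list)
    per_residue: list[PerResidueDeviation] = field(default_factory=list)
    mean_dev: float = 0.0
    sd_dev: float = 0.0

    @property
    def deviations(self) -> np.ndarray:
        return np.asarray([r.deviation for r in self.per_residue], dtype=float)

    @property
    def significant_indices_a(self) -> list[int]:
        return [r.index_a for r in self.per_residue if r.significant]


def _check_fit_points(x: np.ndarray, what: str) -> None:
    if x.shape[0] < 3:
        raise DegenerateFitError(f"{what}: need ≥3 paired nodes, have {x.shape[0]}")
    centred = x - x.mean(axis=0)
    # rank < 2 ⇔ all points collinear (or coincident)
    if np.linalg.matrix_rank(centred, tol=1e-8) < 2:
        raise DegenerateFitError(f"{what}: paired nodes are collinear")


def _resolve_subset(cmap: ChainMap, fit_subset) -> np.ndarray:
    """Positions in ``cmap.pairs`` whose A-side index is in the fit subset."""
    if fit_subset is None or (isinstance(fit_subset, str) and fit_subset == "all"):
        return np.arange(len(cmap.pairs))
    wanted = set(int(i) for i in fit_subset)
    return np.asarray([k for k, (ia, _) in enumerate(cmap.pairs) if ia in wanted], dtype=int)


def superpose(
    a: CoarseGrainedStructure,
    b: CoarseGrainedStructure,
    cmap: ChainMap,
    fit_subset="all",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping B's paired nodes onto A's.

    Returns ``(rotation, translation, rmsd)`` such that
    ``R @ x_b + t ≈ x_a`` for the fit-subset pairs; ``rotation`` is a proper
    rotation (det = +1) and ``rmsd`` is computed over the fit subset after the
    transform.
    """
    rows = _resolve_subset(cmap, fit_subset)
    xa = a.coords[cmap.index_a[rows]]
    xb = b.coords[cmap.index_b[rows]]
    _check_fit_points(xa, "superpose(A)")
    _check_fit_points(xb, "superpose(B)")
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    rot, _ = Rotation.align_vectors(xa - ca, xb - cb)
    r = rot.as_matrix()
    t = ca - r @ cb
    # residual-based RMSD: scipy's reported rssd loses precision near zero
    res = xa - (xb @ r.T + t)
    rmsd = np.sqrt(np.mean(np.sum(res * res, axis=1)))
    return r, t, float(rmsd)


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def per_residue_deviation(
    a: CoarseGrainedStructure,
    b: CoarseGrainedStructure,
    cmap: ChainMap,
    fit_subset="all",
    significance_subset=None,
) -> tuple[list[PerResidueDeviation], float, float]:
    """Per-paired-node Euclidean deviation after global superposition.

    A node is flagged significant when its deviation exceeds
    ``mean + 2·SD`` of the deviation distribution.  ``significance_subset``
    restricts the distribution used for the mean/SD (e.g. one chain) while
    deviations are still reported for all pairs; by default the distribution
    is taken over all reported pairs.  A zero-SD distribution flags nothing.
    """
    r, t, _ = superpose(a, b, cmap, fit_subset)
    xb = apply_transform(b.coords[cmap.index_b], r, t)
    xa = a.coords[cmap.index_a]
    dev = np.linalg.norm(xa - xb, axis=1)

    if significance_subset is None:
        dist = dev
    else:
        rows = _resolve_subset(cmap, significance_subset)
        dist = dev[rows]
    mean, sd = float(dist.mean()), float(dist.std())
    threshold = mean + 2.0 * sd
    # a (near-)degenerate distribution flags nothing: identical structures
    # must not report significant residues off pure floating-point noise
    # (well below the 1e-3 Å coordinate precision of PDB files)
    degenerate = sd < 1e-6
    records = [
        PerResidueDeviation(int(ia), int(ib), float(d),
                            bool(not degenerate and d > threshold))
        for (ia, ib), d in zip(cmap.pairs, dev)
    ]
    return records, mean, sd


def local_rmsd(
    a: CoarseGrainedStructure,
    b: CoarseGrainedStructure,
    cmap: ChainMap,
    chain_id: str,
    fit_mode: str = "fit-on-reference",
    reference_fit_subset="all",
) -> float:
    """RMSD over one chain's paired nodes.

    ``fit-on-self`` superposes on the chain itself and measures internal
    deformation only; ``fit-on-reference`` keeps the complex-level
    superposition (over ``reference_fit_subset``) and therefore measures
    deformation plus rigid displacement of the chain within the complex.
    """
    if fit_mode not in ("fit-on-self", "fit-on-reference"):
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    chain_nodes = a.chain_indices(chain_id)
    rows = _resolve_subset(cmap, chain_nodes)
    if rows.size == 0:
        raise StructureError(f"chain {chain_id!r} has no paired nodes")
    if fit_mode == "fit-on-self":
        _, _, rmsd = superpose(a, b, cmap, fit_subset=chain_nodes)
        return rmsd
    r, t, _ = superpose(a, b, cmap, fit_subset=reference_fit_subset)
    xa = a.coords[cmap.index_a[rows]]
    xb = apply_transform(b.coords[cmap.index_b[rows]], r, t)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def _best_rotation(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    rot, _ = Rotation.align_vectors(xa - xa.mean(axis=0), xb - xb.mean(axis=0))
    return rot.as_matrix()


def angle_of_deviation(
    a: CoarseGrainedStructure,
    b: CoarseGrainedStructure,
    cmap: ChainMap,
    reference_chains,
    chain_id: str,
) -> float:
    """Rotation angle of one chain between two states, in degrees.

    The complexes are first superposed on the reference chains (the rRNA
    scaffold in a ribosomal complex); the optimal rotation R_p between the
    target chain's paired node sets (centroids removed) is then computed and
    its angle θ = arccos((tr R_p − 1)/2) returned.
    """
    ref_nodes = np.concatenate([a.chain_indices(c) for c in reference_chains])
    r, t, _ = superpose(a, b, cmap, fit_subset=ref_nodes)

    chain_nodes = a.chain_indices(chain_id)
    rows = _resolve_subset(cmap, chain_nodes)
    xa = a.coords[cmap.index_a[rows]]
    xb = apply_transform(b.coords[cmap.index_b[rows]], r, t)
    _check_fit_points(xa, f"angle_of_deviation({chain_id})")
    rp = _best_rotation(xa, xb)
    cos_theta = np.clip((np.trace(rp) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))


def deviation_report(
    a: CoarseGrainedStructure,
    b: CoarseGrainedStructure,
    cmap: ChainMap,
    reference_chains=None,
    protein_chains=None,
    fit_mode: str = "fit-on-reference",
) -> DeviationReport:
    """Full deviation report for a state pair.

    ``reference_chains`` default to the largest chain of *a* (the rRNA-like
    scaffold); ``protein_chains`` default to all non-reference chains.
    """
    if reference_chains is None:
        sizes = {c: a.chain_indices(c).size for c in a.chain_ids}
        reference_chains = [max(sizes, key=sizes.get)]
    reference_chains = list(reference_chains)
    if protein_chains is None:
        protein_chains = [c for c in a.chain_ids if c not in reference_chains]

    ref_nodes = np.concatenate([a.chain_indices(c) for c in reference_chains])
    _, _, global_rmsd = superpose(a, b, cmap, fit_subset="all")
    fit_subset = ref_nodes if fit_mode == "fit-on-reference" else "all"
    per_res, mean, sd = per_residue_deviation(a, b, cmap, fit_subset=fit_subset)

    per_protein = []
    for chain in protein_chains:
        rmsd = local_rmsd(a, b, cmap, chain, fit_mode=fit_mode,
                          reference_fit_subset=ref_nodes)
        angle = angle_of_deviation(a, b, cmap, reference_chains, chain)
        per_protein.append(PerProteinDeviation(chain, rmsd, angle))
    return DeviationReport(global_rmsd, per_protein, per_res, mean, sd)
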