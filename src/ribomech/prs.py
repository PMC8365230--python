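"""Perturbation response scanning (PRS).

Each node is perturbed in turn with unit forces; the linear response of every
other node follows from ΔR = H⁺F, with H⁺ the pseudo-inverse of the ANM
Hessian over its nonzero modes.  The N×N response matrix (rows = perturbed
node, columns = responding node) yields per-node effectiveness (row mean) and
sensitivity (column mean) profiles; Z > 2 calls effectors and sensors.  A
chain×chain interaction matrix marks subunit pairs coupled by above-threshold
cross-responses.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .enm import ENMError, ENMModel
from .structures import CoarseGrainedStructure

logger = logging.getLogger(__name__)

__all__ = [
    "PRSResult",
    "SubunitInteractionMatrix",
    "prs_analytic",
    "prs_montecarlo",
    "call_effectors_sensors",
    "subunit_matrix",
]


@dataclass
class PRSResult:
    """N×N PRS response matrix with derived effector/sensor profiles.

    ``response[i, j]`` is the mean squared displacement of node j caused by a
    unit random force at node i.  When ``normalized`` each row has been
    divided by its diagonal self-response, so the diagonal is 1.
    """

    response: np.ndarray
    normalized: bool = False
    effectiveness: np.ndarray | None = None
    sensitivity: np.ndarray | None = None
    eff_z: np.ndarray | None = None
    sens_z: np.ndarray | None = None
    effectors: np.ndarray | None = None
    sensors: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.response.shape[0]

    def normalize(self) -> "PRSResult":
        """Row-normalise by the diagonal self-response (idempotent)."""
        if self.normalized:
            return self
        diag = np.diag(self.response)
        if np.any(diag <= 0):
            raise ENMError("non-positive self-response; cannot normalise")
        return PRSResult(self.response / diag[:, None], normalized=True)


@dataclass
class SubunitInteractionMatrix:
    """Symmetric boolean chain×chain coupling matrix (diagonal undefined)."""

    chains: list[str]
    interacting: np.ndarray


def _profiles(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/column means over off-diagonal entries.

    On a normalised matrix the diagonal is identically 1, a constant that
    would only shift the profiles; it is excluded so the means reflect
    transmitted response only.
    """
    n = p.shape[0]
    off = ~np.eye(n, dtype=bool)
    eff = np.where(off, p, 0.0).sum(axis=1) / (n - 1)
    sens = np.where(off, p, 0.0).sum(axis=0) / (n - 1)
    return eff, sens


def _zscore(x: np.ndarray, what: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ENMError(f"degenerate (constant) {what} profile")
    return (x - x.mean()) / sd


def _finalise(result: PRSResult, threshold: float = 2.0) -> PRSResult:
    r = result.normalize()
    r.effectiveness, r.sensitivity = _profiles(r.response)
    r.eff_z = _zscore(r.effectiveness, "effectiveness")
    r.sens_z = _zscore(r.sensitivity, "sensitivity")
    r.effectors = np.flatnonzero(r.eff_z > threshold)
    r.sensors = np.flatnonzero(r.sens_z > threshold)
    return r


def prs_analytic(m: ENMModel, normalize: bool = True) -> PRSResult:
    """Closed-form PRS matrix from the mode-truncated pseudo-inverse.

    ``P_ij = (1/3)‖B_ji‖_F²`` with B_ji the 3×3 super-element of H⁺ coupling
    responder j to perturbed i — the expectation of the Monte-Carlo estimator
    over force directions uniform on the sphere.  Uses all nonzero modes.
    """
    m._require_modes()
    blocks = m.mode_inverse_blocks(modes=np.arange(m.eigenvalues.size))
    # P[i, j] = (1/3) ||blocks[j, i]||_F^2  (responder-j block of column i)
    p = np.einsum("jiab,jiab->ij", blocks, blocks) / 3.0
    result = PRSResult(p, normalized=False)
    return _finalise(result) if normalize else result


def prs_montecarlo(
    m: ENMModel,
    n_forces: int = 1000,
    seed: int | np.random.Generator = 0,
    normalize: bool = True,
) -> PRSResult:
    """Monte-Carlo PRS: random unit forces applied one node at a time.

    For each perturbed node i, ``n_forces`` force directions are drawn
    uniformly on the sphere; ``P_ij`` is the mean over forces of the squared
    displacement of node j under ΔR = H⁺F.  Deterministic given the seed.
    """
    if n_forces < 1:
        raise ValueError("n_forces must be ≥ 1")
    m._require_modes()
    rng = np.random.default_rng(seed)
    n = m.n_nodes
    hinv = m.pseudo_inverse(modes=np.arange(m.eigenvalues.size))  # (3N, 3N)
    p = np.empty((n, n))
    for i in range(n):
        f = rng.normal(size=(3, n_forces))
        f /= np.linalg.norm(f, axis=0)
        # displacements of all nodes for each force at node i
        d = hinv[:, 3 * i:3 * i + 3] @ f            # (3N, n_forces)
        sq = (d * d).reshape(n, 3, n_forces).sum(axis=1)
        p[i] = sq.mean(axis=1)
    result = PRSResult(p, normalized=False)
    return _finalise(result) if normalize else result


def call_effectors_sensors(
    r: PRSResult, threshold: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Effector/sensor node sets at a Z-score threshold (must be > 0)."""
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    r = _finalise(r, threshold=threshold)
    return r.effectors, r.sensors


def subunit_matrix(
    r: PRSResult,
    s: CoarseGrainedStructure,
    pair_threshold: float = 2.0,
) -> SubunitInteractionMatrix:
    """Chain×chain interaction matrix from standardised cross-responses.

    Chains c ≠ d are marked interacting iff some node pair (i ∈ c, j ∈ d) has
    Z(P_ij) > ``pair_threshold``, where Z standardises the off-diagonal
    entries of the normalised response matrix.  The result is symmetric by
    closure; the diagonal (self-interaction) is undefined and set False.
    """
    r = r.normalize()
    chains = s.chain_ids
    if len(chains) == 1:
        logger.warning("single-chain structure: subunit matrix is trivially 1×1")
        return SubunitInteractionMatrix(chains, np.zeros((1, 1), dtype=bool))
    p = r.response
    n = p.shape[0]
    if n != len(s):
        raise ENMError("PRS matrix size does not match structure")
    off = ~np.eye(n, dtype=bool)
    vals = p[off]
    sd = vals.std()
    if sd == 0:
        raise ENMError("degenerate response matrix")
    z = (p - vals.mean()) / sd

    idx = {c: s.chain_indices(c) for c in chains}
    k = len(chains)
    inter = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for b in range(a + 1, k):
            block = z[np.ix_(idx[chains[a]], idx[chains[b]])]
            block_t = z[np.ix_(idx[chains[b]], idx[chains[a]])]
            hit = bool((block > pair_threshold).any() or (block_t > pair_threshold).any())
            inter[a, b] = inter[b, a] = hit
    return SubunitInteractionMatrix(chains, inter)
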