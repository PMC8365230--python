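"""Anisotropic network model (ANM) normal mode analysis.

The complex is modelled as nodes (Cα/P sites) joined by Hookean springs of
uniform force constant γ for node pairs within a distance cutoff (default
15 Å).  The 3N×3N Hessian is diagonalised; the six zero-eigenvalue rigid-body
modes are discarded and the soft end of the spectrum is kept up to a chosen
fraction of the total 1/λ variance (default 80%).  Per-node mean-square
fluctuations are standardised to Z-scores; |Z| > 2 marks highly flexible
sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .structures import CoarseGrainedStructure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "ENMError",
    "GeometryError",
    "ConnectivityError",
    "ENMModel",
    "FlexibilityProfile",
    "build_hessian",
    "compute_modes",
    "square_fluctuations",
    "cross_correlation",
    "bfactor_agreement",
]

ZERO_MODE_RTOL = 1e-8  # λ < rtol·max(λ) counts as a rigid-body mode
DENSE_LIMIT = 6000     # nodes; above this a sparse partial eigensolver is used


class ENMError(StructureError):
    pass


class GeometryError(ENMError):
    """Coincident nodes within the spring cutoff."""


class ConnectivityError(ENMError):
    """Contact graph is disconnected (rigid-body modes would exceed six)."""


def contact_pairs(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """(n_pairs, 2) array of node pairs with inter-node distance ≤ cutoff."""
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.reshape(-1, 2)


def _connected_components(n: int, pairs: np.ndarray) -> list[np.ndarray]:
    adj = scipy.sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = scipy.sparse.csgraph.connected_components(adj, directed=False)
    return [np.flatnonzero(labels == k) for k in range(n_comp)]


@dataclass
class ENMModel:
    """Anisotropic network model of a coarse-grained structure."""

    structure: CoarseGrainedStructure
    cutoff: float
    gamma: float
    hessian: np.ndarray | scipy.sparse.csr_matrix
    eigenvalues: np.ndarray | None = None     # nonzero modes, ascending
    eigenvectors: np.ndarray | None = None    # (3N, n_modes), orthonormal
    selected_modes: np.ndarray | None = None  # indices into eigenvalues
    variance_fraction: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.structure)

    def _require_modes(self) -> None:
        if self.eigenvalues is None or self.selected_modes is None:
            raise ENMError("modes not computed; call compute_modes() first")

    def mode_inverse_blocks(self, modes: np.ndarray | None = None) -> np.ndarray:
        """Mode-truncated pseudo-inverse of H as an (N, N, 3, 3) block array."""
        self._require_modes()
        idx = self.selected_modes if modes is None else modes
        lam = self.eigenvalues[idx]
        vec = self.eigenvectors[:, idx]          # (3N, k)
        n = self.n_nodes
        v = vec.reshape(n, 3, -1)                # (N, 3, k)
        scaled = v / lam                         # broadcast over k
        # block (i, j) = Σ_k (1/λ_k) v_k,i v_k,jᵀ
        return np.einsum("iak,jbk->ijab", scaled, v)

    def pseudo_inverse(self, modes: np.ndarray | None = None) -> np.ndarray:
        """Mode-truncated pseudo-inverse of H as a dense 3N×3N matrix."""
        blocks = self.mode_inverse_blocks(modes)
        n = self.n_nodes
        return blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


@dataclass
class FlexibilityProfile:
    """Per-node mean-square fluctuation, Z-scores, and the |Z|>2 flexible set."""

    msf: np.ndarray
    zscore: np.ndarray
    flexible: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    threshold: float = 2.0


def build_hessian(
    s: CoarseGrainedStructure,
    cutoff: float = 15.0,
    gamma: float = 1.0,
    sparse: bool | None = None,
) -> ENMModel:
    """Construct the ANM Hessian.

    Off-diagonal super-element for a contacting pair (i, j):
    ``H_ij = −γ d d^T / |d|²`` with ``d = x_j − x_i``; diagonal super-elements
    make every super-row sum to zero (translational invariance).
    """
    coords = np.asarray(s.coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ENMError("need at least 2 nodes")
    if cutoff <= 0:
        raise ENMError("cutoff must be positive")
    pairs = contact_pairs(coords, cutoff)
    if len(pairs):
        d = coords[pairs[:, 1]] - coords[pairs[:, 0]]
        dist2 = np.einsum("ij,ij->i", d, d)
        zero = dist2 < 1e-12
        if np.any(zero):
            i, j = pairs[np.argmax(zero)]
            raise GeometryError(
                f"coincident nodes within cutoff: {s.nodes[i]!r} and {s.nodes[j]!r}"
            )
        # 3×3 super-elements, one per contacting pair
        blocks = -gamma * np.einsum("ka,kb->kab", d, d) / dist2[:, None, None]
    else:
        blocks = np.empty((0, 3, 3))

    use_sparse = (n > DENSE_LIMIT) if sparse is None else sparse
    if use_sparse:
        rows, cols, vals = [], [], []
        diag = np.zeros((n, 3, 3))
        for (i, j), blk in zip(pairs, blocks):
            for a in range(3):
                for b in range(3):
                    rows += [3 * i + a, 3 * j + a]
                    cols += [3 * j + b, 3 * i + b]
                    vals += [blk[a, b], blk[a, b]]
            diag[i] -= blk
            diag[j] -= blk
        for i in range(n):
            for a in range(3):
                for b in range(3):
                    rows.append(3 * i + a)
                    cols.append(3 * i + b)
                    vals.append(diag[i, a, b])
        h = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n))
    else:
        h = np.zeros((3 * n, 3 * n))
        for (i, j), blk in zip(pairs, blocks):
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] += blk
            h[3 * j:3 * j + 3, 3 * i:3 * i + 3] += blk
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= blk
            h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= blk
    return ENMModel(structure=s, cutoff=cutoff, gamma=gamma, hessian=h)


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Sign convention: first component of magnitude > tol is positive."""
    out = vec.copy()
    for k in range(out.shape[1]):
        v = out[:, k]
        nz = np.flatnonzero(np.abs(v) > 1e-10)
        if nz.size and v[nz[0]] < 0:
            out[:, k] = -v
    return out


def compute_modes(m: ENMModel, variance_fraction: float = 0.8) -> ENMModel:
    """Eigendecompose the Hessian and select the soft-mode prefix.

    The six zero modes (five for collinear structures) are discarded.  Each
    nonzero mode k carries a variance share proportional to 1/λ_k; the
    selected set is the smallest prefix of ascending-λ modes whose cumulative
    share reaches ``variance_fraction``.  Requires a connected contact graph.
    """
    if not 0 < variance_fraction <= 1:
        raise ENMError("variance_fraction must be in (0, 1]")
    coords = m.structure.coords
    n = m.n_nodes
    pairs = contact_pairs(coords, m.cutoff)
    comps = _connected_components(n, pairs)
    if len(comps) > 1:
        sizes = sorted((len(c) for c in comps), reverse=True)
        raise ConnectivityError(
            f"contact graph has {len(comps)} components (sizes {sizes}); "
            f"raise the cutoff (currently {m.cutoff} Å)"
        )

    # a connected 3D structure has exactly 6 rigid-body modes (5 if all nodes
    # are collinear); discard exactly that many, verifying they are numerical
    # zeros — very soft *physical* modes can otherwise fall below a relative
    # tolerance on thin elongated structures
    centred = coords - coords.mean(axis=0)
    collinear = np.linalg.matrix_rank(centred, tol=1e-8) < 2
    n_rigid = 5 if collinear else 6

    dense = not scipy.sparse.issparse(m.hessian)
    if dense:
        lam, vec = scipy.linalg.eigh(m.hessian)
    else:
        lam, vec = _sparse_modes(m, variance_fraction, n_rigid)
        if lam is None:  # partial solve could not certify the selection
            lam, vec = scipy.linalg.eigh(m.hessian.toarray())
    order = np.argsort(lam)
    lam, vec = lam[order], vec[:, order]
    tol = ZERO_MODE_RTOL * max(abs(lam).max(), 1.0)
    if abs(lam[n_rigid - 1]) > tol or (len(lam) > n_rigid and lam[n_rigid] < -tol):
        raise ENMError(
            f"expected {n_rigid} zero modes; eigenvalues near zero: "
            f"{lam[:n_rigid + 2]}"
        )
    lam_nz = lam[n_rigid:]
    vec_nz = _fix_sign(vec[:, n_rigid:])
    if np.any(lam_nz < tol):
        logger.warning(
            "%d extremely soft modes below the zero tolerance retained",
            int(np.sum(lam_nz < tol)),
        )
    lam_nz = np.maximum(lam_nz, np.finfo(float).tiny)

    inv = 1.0 / lam_nz
    share = np.cumsum(inv) / inv.sum()
    k = int(np.searchsorted(share, variance_fraction) + 1)
    k = min(k, lam_nz.size)
    m.eigenvalues = lam_nz
    m.eigenvectors = vec_nz
    m.selected_modes = np.arange(k)
    m.variance_fraction = variance_fraction
    return m


def _sparse_modes(
    m: ENMModel, variance_fraction: float, n_rigid: int
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Partial soft-spectrum solve for large models (shift-invert Lanczos).

    Fetches batches of smallest-λ modes until the 1/λ-share selection is
    *certified* identical to the full-spectrum rule: the selected prefix is
    the same whether the unfetched remainder of the spectrum contributes
    nothing or as much as the conservative bound (every remaining mode at
    least as stiff as the stiffest fetched one) allows.  Returns
    ``(None, None)`` when certification would require (nearly) the full
    spectrum — the caller then falls back to a dense solve.
    """
    h = m.hessian.tocsc()
    n3 = h.shape[0]
    if variance_fraction >= 1.0:
        return None, None
    lam_max = float(scipy.sparse.linalg.eigsh(
        h, k=1, which="LA", return_eigenvectors=False)[0])
    sigma = -1e-6 * lam_max  # slightly negative: H − σI is nonsingular
    k = min(max(64, n3 // 50), n3 // 2)
    while True:
        lam, vec = scipy.sparse.linalg.eigsh(h, k=k, sigma=sigma, which="LM")
        order = np.argsort(lam)
        lam, vec = lam[order], vec[:, order]
        lam_nz = lam[n_rigid:]
        if lam_nz.size and lam_nz[0] > 0:
            inv = 1.0 / lam_nz
            cum = np.cumsum(inv)
            n_remaining = n3 - n_rigid - lam_nz.size
            total_lo = cum[-1]
            total_hi = cum[-1] + n_remaining / lam_nz[-1]
            k_lo = int(np.searchsorted(cum / total_lo, variance_fraction) + 1)
            k_hi = int(np.searchsorted(cum / total_hi, variance_fraction) + 1)
            if k_lo == k_hi and k_hi <= lam_nz.size:
                return lam, vec
        if k >= n3 // 2:
            return None, None
        k = min(2 * k, n3 // 2)


def square_fluctuations(m: ENMModel, per_chain_z: bool = False) -> FlexibilityProfile:
    """Mean-square fluctuation per node over the selected modes, Z-scored.

    ``msf_i = Σ_{k∈selected} (1/λ_k) |v_k,i|²`` (the trace of node i's 3×3
    diagonal block of the mode-truncated pseudo-inverse).  Z-scores are over
    all nodes by default; ``per_chain_z`` standardises within each chain.
    """
    m._require_modes()
    idx = m.selected_modes
    lam = m.eigenvalues[idx]
    v = m.eigenvectors[:, idx].reshape(m.n_nodes, 3, -1)
    msf = np.einsum("iak,iak,k->i", v, v, 1.0 / lam)

    if per_chain_z:
        z = np.empty_like(msf)
        for chain in m.structure.chain_ids:
            ci = m.structure.chain_indices(chain)
            sd = msf[ci].std()
            if sd == 0:
                raise ENMError(f"degenerate flexibility profile in chain {chain!r}")
            z[ci] = (msf[ci] - msf[ci].mean()) / sd
    else:
        sd = msf.std()
        if sd == 0:
            raise ENMError("degenerate flexibility profile (zero variance)")
        z = (msf - msf.mean()) / sd
    flexible = np.flatnonzero(np.abs(z) > 2.0)
    return FlexibilityProfile(msf=msf, zscore=z, flexible=flexible)


def cross_correlation(m: ENMModel) -> np.ndarray:
    """Normalised inter-node cross-correlation over the selected modes.

    ``C_ij = cov_ij / sqrt(cov_ii cov_jj)`` with
    ``cov_ij = Σ_k (1/λ_k) v_k,i · v_k,j``; diagonal exactly 1.
    """
    m._require_modes()
    idx = m.selected_modes
    lam = m.eigenvalues[idx]
    v = m.eigenvectors[:, idx].reshape(m.n_nodes, 3, -1)
    cov = np.einsum("iak,jak,k->ij", v, v, 1.0 / lam)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise ENMError(f"zero-variance node {bad} in cross-correlation")
    c = cov / np.sqrt(np.outer(diag, diag))
    np.fill_diagonal(c, 1.0)
    return c


def bfactor_agreement(profile: FlexibilityProfile, s: CoarseGrainedStructure) -> float:
    """Pearson correlation between predicted fluctuations and experimental B-factors."""
    b = s.bfactors
    have = np.isfinite(b)
    if have.sum() < 3:
        raise ENMError("need ≥3 nodes with experimental B-factors")
    x, y = profile.msf[have], b[have]
    if x.std() == 0 or y.std() == 0:
        raise ENMError("constant vector: correlation undefined")
    r, _ = pearsonr(x, y)
    return float(r)
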