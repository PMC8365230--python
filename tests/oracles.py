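"""Independent reference implementations used only to check the package.

Each oracle deliberately uses a different algorithm (or brute force) than
the implementation it validates.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import floyd_warshall


def quaternion_superpose_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion method.

    Independent of the SVD/Kabsch route: builds the 4×4 key matrix from the
    cross-covariance and takes its largest eigenvalue.
    """
    a = xa - xa.mean(axis=0)
    b = xb - xb.mean(axis=0)
    m = b.T @ a  # maps b onto a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, szy - syz, sxz - szx, syx - sxy],
        [szy - syz, sxx - syy - szz, sxy + syx, szx + sxz],
        [sxz - szx, sxy + syx, -sxx + syy - szz, syz + szy],
        [syx - sxy, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam_max = np.linalg.eigvalsh(k)[-1]
    sq = (a * a).sum() + (b * b).sum() - 2.0 * lam_max
    return float(np.sqrt(max(sq, 0.0) / xa.shape[0]))


def brute_hessian(coords: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    """Naive double-loop ANM Hessian."""
    n = coords.shape[0]
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = coords[j] - coords[i]
            dist2 = d @ d
            if np.sqrt(dist2) > cutoff:
                continue
            blk = -gamma * np.outer(d, d) / dist2
            h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = blk
            h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= blk
    return h


def brute_centralities(edges: list[tuple[int, int, float]], n: int):
    """Degree, betweenness and closeness by shortest-path counting.

    Distances via Floyd–Warshall; shortest-path counts σ_st by dynamic
    programming over the predecessor condition d(s,v)+w(v,t)=d(s,t);
    betweenness(v) = Σ_{s≠t≠v} σ_sv σ_vt [on-path] / σ_st, halved for
    undirected graphs and normalised by (n−1)(n−2)/2.
    """
    w = np.full((n, n), np.inf)
    np.fill_diagonal(w, 0.0)
    adj = [[] for _ in range(n)]
    deg = np.zeros(n)
    for i, j, length in edges:
        w[i, j] = w[j, i] = min(w[i, j], length)
        adj[i].append((j, length))
        adj[j].append((i, length))
        deg[i] += 1
        deg[j] += 1
    d = floyd_warshall(scipy.sparse.csr_matrix(np.where(np.isinf(w), 0, w)),
                       directed=False)
    # σ[s, t]: number of shortest s→t paths, by increasing distance from s
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(d[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or np.isinf(d[s, t]):
                continue
            for v, length in adj[t]:
                if np.isclose(d[s, v] + length, d[s, t]):
                    sigma[s, t] += sigma[s, v]
    btw = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if v in (s, t) or s == t or np.isinf(d[s, t]) or sigma[s, t] == 0:
                    continue
                if np.isclose(d[s, v] + d[v, t], d[s, t]):
                    btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    btw /= 2.0  # each unordered pair counted twice
    if n > 2:
        btw /= (n - 1) * (n - 2) / 2.0
    closeness = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(d[v]) & (np.arange(n) != v)
        if reach.any():
            total = d[v, reach].sum()
            closeness[v] = (reach.sum() / total) * (reach.sum() / (n - 1))
    return deg, btw, closeness


def simulate_hitting_time(a: np.ndarray, start: int, target: int,
                          n_walks: int, rng: np.random.Generator,
                          max_steps: int = 100_000) -> tuple[float, float]:
    """Monte-Carlo hitting time estimate (mean, standard error)."""
    n = a.shape[0]
    probs = a / a.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    steps = np.empty(n_walks)
    for w in range(n_walks):
        v = start
        count = 0
        while v != target:
            v = int(np.searchsorted(cum[v], rng.random()))
            count += 1
            if count >= max_steps:  # pragma: no cover - diagnostics only
                raise RuntimeError("walk did not hit the target")
        steps[w] = count
    return float(steps.mean()), float(steps.std(ddof=1) / np.sqrt(n_walks))


def effective_resistance(a: np.ndarray) -> np.ndarray:
    """Pairwise effective resistance from the Laplacian pseudo-inverse."""
    d = np.diag(a.sum(axis=1))
    lap = d - a
    linv = np.linalg.pinv(lap)
    diag = np.diag(linv)
    return diag[:, None] + diag[None, :] - 2.0 * linv


def sphere_quadrature_prs(hinv: np.ndarray, n: int, n_dirs: int = 10_000) -> np.ndarray:
    """PRS matrix by quasi-uniform numerical quadrature over force directions.

    Fibonacci-sphere directions rather than random sampling, so the check is
    deterministic and independent of the closed form.
    """
    k = np.arange(n_dirs)
    z = 1.0 - 2.0 * (k + 0.5) / n_dirs
    theta = np.arccos(z)
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    dirs = np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), z]
    )  # (n_dirs, 3)
    p = np.empty((n, n))
    for i in range(n):
        block = hinv[:, 3 * i:3 * i + 3]          # (3N, 3)
        disp = block @ dirs.T                      # (3N, n_dirs)
        sq = (disp * disp).reshape(n, 3, n_dirs).sum(axis=1)
        p[i] = sq.mean(axis=1)
    return p
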