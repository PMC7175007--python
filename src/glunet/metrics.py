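"""Global architecture and regional centrality of binary undirected graphs.

Conventions: betweenness is unnormalized (raw pair counts, each unordered
pair counted once, with fractional credit for tied shortest paths);
eigenvector centrality is the non-negative principal eigenvector scaled so
its maximum entry is 1 (computed by shifted power iteration, which also
converges on bipartite graphs); clustering of degree-0/1 nodes is 0 and is
included in the mean.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path


class GraphError(ValueError):
    """Raised for graphs outside an operation's domain (disconnected, empty...)."""


@dataclass(frozen=True)
class GlobalMetrics:
    mean_degree: float
    path_length: float
    clustering: float


@dataclass(frozen=True)
class CentralityProfile:
    """Per-region, per-threshold centrality values (arrays of shape (T, R))."""

    thresholds: np.ndarray
    degree: np.ndarray
    betweenness: np.ndarray
    eigenvector: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.degree.shape[1]


def _validate(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise GraphError("adjacency must be square")
    if A.shape[0] == 0:
        raise GraphError("empty graph")
    if not np.array_equal(A, A.T):
        raise GraphError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise GraphError("adjacency diagonal must be zero")
    if not np.isin(A, (0, 1)).all():
        raise GraphError("adjacency must be binary")
    return A.astype(np.uint8)


def degree_centrality(A: np.ndarray) -> np.ndarray:
    return np.asarray(A).sum(axis=1).astype(int)


def path_length_matrix(A: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf between components)."""
    return shortest_path(np.asarray(A, dtype=np.uint8), method="D", unweighted=True)


def clustering_coefficients(A: np.ndarray) -> np.ndarray:
    """C_i = triangles_i / (k_i choose 2); 0 for nodes of degree < 2."""
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=1)
    tri = np.diag(A @ A @ A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def global_metrics(A: np.ndarray) -> GlobalMetrics:
    """Mean degree, average shortest-path length and mean clustering.

    <k> = 2|E|/R; L_p averages over all unordered node pairs (errors on a
    disconnected graph); C_p averages C_i over all nodes.
    """
    A = _validate(A)
    n = A.shape[0]
    n_edges = int(A.sum()) // 2
    if n < 2 or n_edges == 0:
        raise GraphError("global metrics undefined on an empty/edgeless graph")
    D = path_length_matrix(A)
    if not np.all(np.isfinite(D)):
        raise GraphError("graph is disconnected; average path length undefined")
    iu = np.triu_indices(n, k=1)
    lp = float(D[iu].mean())
    cp = float(clustering_coefficients(A).mean())
    return GlobalMetrics(mean_degree=2.0 * n_edges / n, path_length=lp, clustering=cp)


def betweenness_centrality(A: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via Brandes' dependency accumulation.

    Each unordered pair contributes 1 split fractionally over its tied
    shortest paths' interior nodes.
    """
    A = np.asarray(A)
    n = A.shape[0]
    adj = [np.flatnonzero(A[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        stack = []
        preds = [[] for _ in range(n)]
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            dv = dist[v]
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dv + 1
                    queue.append(w)
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in preds[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


def eigenvector_centrality(
    A: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000
) -> np.ndarray:
    """Principal-eigenvector centrality scaled to max 1.

    Power iteration on A + I (the shift leaves eigenvectors unchanged but
    guarantees a dominant eigenvalue even for bipartite graphs), uniform
    deterministic start vector.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.sum() == 0:
        raise GraphError("eigenvector centrality undefined on an edgeless graph")
    M = A + np.eye(n)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = M @ x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise GraphError("power iteration failed to converge")
    x = np.clip(x, 0.0, None)
    return x / x.max()


def centrality(A: np.ndarray, require_connected: bool = True):
    """Degree, betweenness and eigenvector centrality of one adjacency.

    By default requires a connected graph (the threshold grid guarantees
    this for real networks); ``require_connected=False`` lifts the check —
    all three centralities remain well defined on disconnected graphs.
    """
    A = _validate(A)
    if require_connected:
        D = path_length_matrix(A)
        if not np.all(np.isfinite(D)):
            raise GraphError("graph is disconnected")
    return (
        degree_centrality(A),
        betweenness_centrality(A),
        eigenvector_centrality(A),
    )


def centrality_profile(
    adjacency_stack: np.ndarray, thresholds, require_connected: bool = True
) -> CentralityProfile:
    """Centrality of every region at every grid threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    stack = np.asarray(adjacency_stack)
    if stack.shape[0] != len(thresholds):
        raise GraphError("stack depth does not match threshold grid length")
    ks, bs, es = [], [], []
    for A in stack:
        k, b, e = centrality(A, require_connected=require_connected)
        ks.append(k)
        bs.append(b)
        es.append(e)
    return CentralityProfile(
        thresholds=thresholds,
        degree=np.asarray(ks, dtype=float),
        betweenness=np.asarray(bs),
        eigenvector=np.asarray(es),
    )


def global_profile(adjacency_stack: np.ndarray, thresholds) -> "list[GlobalMetrics]":
    """Global metrics at every grid threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    return [global_metrics(A) for A in np.asarray(adjacency_stack)]
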