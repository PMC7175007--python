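"""Null-model inference: hub calling against calibrated Erdős–Rényi ensembles,
group-difference permutation tests, and rich-club core detection.

Calibration choices (documented because the conventions matter):

* ER nulls are G(n, m) — exact edge count matched to the real graph at each
  threshold — and null centrality moments pool across all nodes of all null
  graphs (nodes are exchangeable under ER).
* Across-threshold aggregation of hub evidence is the arithmetic mean of
  per-threshold z-scores; the permutation null pools per-threshold
  differences.  Both are configurable to per-threshold reporting.
* Permutation p-values use the +1 correction and are two-sided via |.|.
* The rich-club routine is a documented stand-in (phi(k) with
  degree-preserving rewiring nulls), flagged ``approximate`` in its output.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import CohortTable, ValidationError
from .metrics import (
    CentralityProfile,
    betweenness_centrality,
    clustering_coefficients,
    degree_centrality,
    eigenvector_centrality,
    path_length_matrix,
)
from .networks import adjacency_at

CENTRALITY_METRICS = ("degree", "betweenness", "eigenvector")
GLOBAL_STATISTICS = ("mean_degree", "path_length", "clustering")
Z_STATISTICS = ("degree_z", "betweenness_z", "eigenvector_z")

HUB_Z = 1.96


def sample_er_adjacency(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """G(n, m) adjacency with exactly m edges drawn uniformly over pairs."""
    n_pairs = n * (n - 1) // 2
    if not (0 <= m <= n_pairs):
        raise ValidationError(f"edge count {m} outside [0, {n_pairs}]")
    chosen = rng.choice(n_pairs, size=m, replace=False)
    iu = np.triu_indices(n, k=1)
    A = np.zeros((n, n), dtype=np.uint8)
    A[iu[0][chosen], iu[1][chosen]] = 1
    A |= A.T
    assert int(A.sum()) // 2 == m  # calibration: exact edge count, every draw
    return A


_CENTRALITY_FUNCS = {
    "degree": degree_centrality,
    "betweenness": betweenness_centrality,
    "eigenvector": eigenvector_centrality,
}


def _null_centrality_moments(
    n: int, m: int, n_null: int, rng: np.random.Generator, metrics=CENTRALITY_METRICS
):
    """Pooled mean/SD of each requested centrality metric over n_null G(n,m)
    graphs.  The rng is advanced identically regardless of ``metrics``."""
    pools = {name: [] for name in metrics}
    for _ in range(n_null):
        A = sample_er_adjacency(n, m, rng)
        for name in metrics:
            pools[name].append(_CENTRALITY_FUNCS[name](A))
    out = {}
    for name, vals in pools.items():
        arr = np.concatenate(vals)
        out[name] = (float(arr.mean()), float(arr.std(ddof=0)))
    return out


@dataclass(frozen=True)
class HubTable:
    """Per-region hub evidence versus edge-count-matched ER graphs.

    ``z`` maps metric name -> (T, R) per-threshold z-scores; ``mean_z`` is
    the across-threshold mean (NaN thresholds excluded); ``hub`` flags
    mean z > 1.96.
    """

    thresholds: np.ndarray
    z: dict
    mean_z: dict
    hub: dict
    n_null_graphs: int
    n_null_per_threshold: int
    seed: int | None


def er_null_z(
    profile: CentralityProfile,
    adjacency_stack: np.ndarray,
    n_null: int = 1000,
    seed: int | None = None,
    metrics=CENTRALITY_METRICS,
) -> HubTable:
    """z-score real centralities against G(n, m) ensembles, threshold by threshold.

    ``metrics`` restricts which centralities get null ensembles (betweenness
    dominates the cost; scaled-down runs often need degree only).
    Degenerate thresholds (null SD 0, e.g. complete graphs) yield NaN z at
    that threshold and are excluded from the across-threshold mean with a
    warning.
    """
    if n_null < 1:
        raise ValidationError("n_null must be >= 1")
    stack = np.asarray(adjacency_stack)
    T = stack.shape[0]
    if profile.degree.shape[0] != T:
        raise ValidationError("profile and adjacency stack disagree on grid length")
    n = stack.shape[1]
    rng = np.random.default_rng(seed)
    real = {
        "degree": profile.degree,
        "betweenness": profile.betweenness,
        "eigenvector": profile.eigenvector,
    }
    z = {name: np.full((T, n), np.nan) for name in metrics}
    n_graphs = 0
    for t in range(T):
        m = int(stack[t].sum()) // 2
        moments = _null_centrality_moments(n, m, n_null, rng, metrics)
        n_graphs += n_null
        for name in metrics:
            mu, sd = moments[name]
            if sd == 0:
                warnings.warn(
                    f"degenerate null (SD=0) for {name} at threshold index {t}; "
                    "z undefined there and excluded from the mean",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            z[name][t] = (real[name][t] - mu) / sd
    mean_z = {}
    hub = {}
    for name in metrics:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mz = np.nanmean(z[name], axis=0)
        mean_z[name] = mz
        hub[name] = mz > HUB_Z
    return HubTable(
        thresholds=np.asarray(profile.thresholds),
        z=z,
        mean_z=mean_z,
        hub=hub,
        n_null_graphs=n_graphs,
        n_null_per_threshold=n_null,
        seed=seed,
    )


def two_sided_pvalue(real: float, null: np.ndarray) -> float:
    """(1 + #{|null| >= |real|}) / (N + 1); never exactly zero."""
    null = np.asarray(null, dtype=float)
    hits = int(np.sum(np.abs(null) >= abs(real) - 1e-12))
    return (1 + hits) / (len(null) + 1)


@dataclass(frozen=True)
class PermutationOutcome:
    statistic: str
    region: int | None
    real: float
    per_threshold_real: np.ndarray
    null: np.ndarray
    p: float
    n_perm_per_threshold: int
    n_evaluated: int
    n_dropped: int
    seed: int | None


class _ZMomentCache:
    """Cache of pooled ER centrality moments keyed by (n, m).

    Shared between the real statistic and all permutations so z-scores are
    comparable; the fill order is deterministic given the seed.
    """

    def __init__(self, n_null: int, rng: np.random.Generator):
        self.n_null = n_null
        self.rng = rng
        self._cache = {}

    def get(self, n: int, m: int):
        key = (n, m)
        if key not in self._cache:
            self._cache[key] = _null_centrality_moments(n, m, self.n_null, self.rng)
        return self._cache[key]


def _stat_per_threshold(X, grid, statistic, region, zcache):
    """Statistic of one pseudo-group's network at each grid threshold.

    Returns a list with None where the statistic is undefined (disconnected
    graph for path-length).
    """
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    out = []
    for t in grid:
        A = adjacency_at(R, t)
        if statistic == "mean_degree":
            out.append(float(A.sum()) / A.shape[0])
        elif statistic == "clustering":
            out.append(float(clustering_coefficients(A).mean()))
        elif statistic == "path_length":
            D = path_length_matrix(A)
            iu = np.triu_indices(A.shape[0], k=1)
            vals = D[iu]
            out.append(float(vals.mean()) if np.all(np.isfinite(vals)) else None)
        elif statistic in Z_STATISTICS:
            name = statistic[: -len("_z")]
            m = int(A.sum()) // 2
            mu, sd = zcache.get(A.shape[0], m)[name]
            if sd == 0:
                out.append(None)
                continue
            if name == "degree":
                val = float(A[region].sum())
            elif name == "betweenness":
                val = float(betweenness_centrality(A)[region])
            else:
                val = float(eigenvector_centrality(A)[region])
            out.append((val - mu) / sd)
        else:
            raise ValidationError(
                f"unknown statistic {statistic!r}; expected one of "
                f"{GLOBAL_STATISTICS + Z_STATISTICS}"
            )
    return out


def permute_groups(
    cohort: CohortTable,
    group_a: tuple,
    group_b: tuple,
    statistic: str,
    grid,
    n_perm_per_threshold: int = 5000,
    seed: int | None = None,
    region: int | None = None,
    er_null_size: int = 200,
) -> PermutationOutcome:
    """Permutation test of the across-threshold mean group difference (a - b).

    Animals are reassigned to pseudo-groups of the original sizes; every
    permutation is evaluated at every grid threshold and the null pools all
    per-threshold differences.  Permuted values undefined at a threshold
    (disconnected graph for path-length; degenerate ER null for z-scores)
    are dropped and counted; a warning is raised if more than 10% drop.
    """
    if statistic in Z_STATISTICS and region is None:
        raise ValidationError(f"statistic {statistic!r} requires a region index")
    grid = np.asarray(grid, dtype=float)
    Xa = cohort.group_uptake(*group_a)
    Xb = cohort.group_uptake(*group_b)
    na, nb = Xa.shape[0], Xb.shape[0]
    if min(na, nb) < 3:
        raise ValidationError("both groups need >= 3 animals")
    rng = np.random.default_rng(seed)
    zcache = _ZMomentCache(er_null_size, np.random.default_rng(rng.integers(2**63)))

    pool = np.vstack([Xa, Xb])

    def diffs(idx_a, idx_b):
        va = _stat_per_threshold(pool[idx_a], grid, statistic, region, zcache)
        vb = _stat_per_threshold(pool[idx_b], grid, statistic, region, zcache)
        return [
            (x - y) if (x is not None and y is not None) else None
            for x, y in zip(va, vb)
        ]

    identity = np.arange(na + nb)
    real_diffs = diffs(identity[:na], identity[na:])
    real_vals = [d for d in real_diffs if d is not None]
    if not real_vals:
        raise ValidationError("real statistic undefined at every grid threshold")
    real = float(np.mean(real_vals))

    null = []
    n_dropped = 0
    for _ in range(n_perm_per_threshold):
        perm = rng.permutation(na + nb)
        for d in diffs(perm[:na], perm[na:]):
            if d is None:
                n_dropped += 1
            else:
                null.append(d)
    total = n_perm_per_threshold * len(grid)
    if total and n_dropped > 0.1 * total:
        warnings.warn(
            f"{n_dropped}/{total} permuted values dropped (undefined statistic)",
            RuntimeWarning,
            stacklevel=2,
        )
    null = np.asarray(null)
    return PermutationOutcome(
        statistic=statistic,
        region=region,
        real=real,
        per_threshold_real=np.asarray(
            [np.nan if d is None else d for d in real_diffs]
        ),
        null=null,
        p=two_sided_pvalue(real, null),
        n_perm_per_threshold=n_perm_per_threshold,
        n_evaluated=len(null) + n_dropped,
        n_dropped=n_dropped,
        seed=seed,
    )


def rich_club_phi(A: np.ndarray, k: int) -> float | None:
    """phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1)) over nodes of degree > k."""
    deg = np.asarray(A).sum(axis=1)
    nodes = np.flatnonzero(deg > k)
    if len(nodes) < 2:
        return None
    sub = np.asarray(A)[np.ix_(nodes, nodes)]
    e = int(sub.sum()) // 2
    return 2.0 * e / (len(nodes) * (len(nodes) - 1))


def _rewired_null(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving null: 10 |E| double-edge swaps (graph unchanged when
    no swap is possible, e.g. complete graphs)."""
    G = nx.from_numpy_array(np.asarray(A, dtype=int))
    m = G.number_of_edges()
    if m < 2 or G.number_of_nodes() < 4:
        return np.asarray(A, dtype=np.uint8)
    nswap = 10 * m
    try:
        nx.double_edge_swap(
            G, nswap=nswap, max_tries=100 * nswap, seed=int(rng.integers(2**31))
        )
    except nx.NetworkXException:
        pass  # saturated graphs admit few/no swaps; use what we got
    return nx.to_numpy_array(G, dtype=np.uint8)


@dataclass(frozen=True)
class RichClubLevel:
    k: int
    n_nodes: int
    phi: float
    phi_rand_mean: float
    phi_norm: float
    p: float


@dataclass(frozen=True)
class RichClubResult:
    """Rich-club coefficients, rewiring-null comparison and the core set.

    ``per_threshold`` holds a list of :class:`RichClubLevel` per grid
    threshold; ``k_star`` the selected degree level (None if no level
    qualifies); ``rcc`` the region indices in the core at a strict majority
    of thresholds.  ``approximate`` flags that this routine is a documented
    stand-in for the externally-cited rich-club algorithm.
    """

    thresholds: np.ndarray
    per_threshold: list
    k_star: list
    rcc: frozenset
    n_null: int
    seed: int | None
    approximate: bool = True


MIN_CLUB_SIZE = 4


def rich_club_core(
    adjacency_stack: np.ndarray,
    thresholds=None,
    n_rewire_null: int = 1000,
    seed: int | None = None,
) -> RichClubResult:
    """Detect the rich-club core across the threshold grid.

    Per threshold: phi(k) for every feasible k, null phi from
    ``n_rewire_null`` degree-preserving rewirings, phi_norm = phi /
    mean(phi_rand) and empirical p = (1 + #{phi_rand >= phi}) / (n + 1).
    k* is the smallest k such that every level k' >= k with at least
    ``MIN_CLUB_SIZE`` qualifying nodes has phi_norm > 1 and p < 0.05; the
    per-threshold core is the node set of degree > k*.  The overall core is
    the set of nodes belonging to the per-threshold core at a strict
    majority of thresholds.  An empty core is a valid outcome.
    """
    stack = np.asarray(adjacency_stack)
    if stack.ndim == 2:
        stack = stack[None]
    T = stack.shape[0]
    if thresholds is None:
        thresholds = np.arange(T, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    rng = np.random.default_rng(seed)
    n = stack.shape[1]
    per_threshold = []
    k_stars = []
    member_counts = np.zeros(n, dtype=int)
    for t in range(T):
        A = stack[t]
        deg = A.sum(axis=1)
        kmax = int(deg.max()) if n else 0
        ks = [k for k in range(kmax) if np.sum(deg > k) >= 2]
        null_phi = {k: [] for k in ks}
        for _ in range(n_rewire_null):
            B = _rewired_null(A, rng)
            for k in ks:
                ph = rich_club_phi(B, k)
                if ph is not None:
                    null_phi[k].append(ph)
        levels = []
        for k in ks:
            phi = rich_club_phi(A, k)
            rand = np.asarray(null_phi[k], dtype=float)
            if phi is None or len(rand) == 0:
                continue
            mean_rand = float(rand.mean())
            norm = phi / mean_rand if mean_rand > 0 else np.inf
            p = (1 + int(np.sum(rand >= phi - 1e-12))) / (len(rand) + 1)
            levels.append(
                RichClubLevel(
                    k=k,
                    n_nodes=int(np.sum(deg > k)),
                    phi=float(phi),
                    phi_rand_mean=mean_rand,
                    phi_norm=float(norm),
                    p=float(p),
                )
            )
        per_threshold.append(levels)
        qualifying = [lv for lv in levels if lv.n_nodes >= MIN_CLUB_SIZE]
        k_star = None
        for lv in qualifying:
            tail = [q for q in qualifying if q.k >= lv.k]
            if tail and all(q.phi_norm > 1.0 and q.p < 0.05 for q in tail):
                k_star = lv.k
                break
        k_stars.append(k_star)
        if k_star is not None:
            member_counts[deg > k_star] += 1
    rcc = frozenset(np.flatnonzero(member_counts > T / 2).tolist())
    return RichClubResult(
        thresholds=thresholds,
        per_threshold=per_threshold,
        k_star=k_stars,
        rcc=rcc,
        n_null=n_rewire_null,
        seed=seed,
    )
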