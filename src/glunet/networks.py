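"""Group-wise correlation networks: Pearson matrices, Fisher z, adjacency stacks.

Thresholding is signed — a negative correlation never creates an edge — and
the boundary is inclusive (r >= T).  Fisher z is carried alongside r for
reporting; the threshold operates on r.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse.csgraph import connected_components

from .io import CohortTable, RegionTable, ValidationError


@dataclass(frozen=True)
class GroupNetwork:
    """One experimental group's correlation structure.

    ``R``: symmetric Pearson matrix with unit diagonal.  ``Z``: Fisher-z
    matrix, NaN on the diagonal and wherever |r| = 1.  ``A`` (once populated)
    is a (T, R, R) stack of binary adjacency matrices over ``thresholds``.
    """

    group_label: tuple
    n_animals: int
    R: np.ndarray
    Z: np.ndarray
    regions: RegionTable
    thresholds: np.ndarray | None = None
    A: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return self.R.shape[0]

    @property
    def n_pairs(self) -> int:
        r = self.n_regions
        return r * (r - 1) // 2


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform atanh(r); NaN where |r| = 1."""
    r = np.asarray(r, dtype=float)
    out = np.full_like(r, np.nan)
    ok = np.abs(r) < 1
    out[ok] = np.arctanh(r[ok])
    return out


def correlation_matrix(cohort: CohortTable, group_label: tuple) -> GroupNetwork:
    """Within-group inter-regional Pearson correlation matrix (+ Fisher z).

    Correlates each pair of regional uptake vectors across the group's
    animals.  Errors on groups of fewer than 3 animals or any zero-variance
    region; off-diagonal |r| = 1 leaves the corresponding z masked (NaN)
    with a warning.
    """
    genotype, treatment = group_label
    X = cohort.group_uptake(genotype, treatment)
    if X.shape[0] < 3:
        raise ValidationError(
            f"group {group_label} has {X.shape[0]} animals; need >= 3 for correlation"
        )
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(
            f"region {cohort.regions.abbreviation[j]!r} has zero variance in group {group_label}"
        )
    R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    off = ~np.eye(R.shape[0], dtype=bool)
    if np.any(np.abs(R[off]) >= 1.0):
        warnings.warn(
            "off-diagonal |r| = 1 encountered; Fisher z masked (atanh diverges)",
            RuntimeWarning,
            stacklevel=2,
        )
    Z = fisher_z(R)
    np.fill_diagonal(Z, np.nan)
    return GroupNetwork(
        group_label=tuple(group_label),
        n_animals=X.shape[0],
        R=R,
        Z=Z,
        regions=cohort.regions,
    )


def adjacency_at(R: np.ndarray, threshold: float) -> np.ndarray:
    """Binary adjacency: edge iff r >= threshold (signed rule), zero diagonal."""
    A = (R >= threshold).astype(np.uint8)
    np.fill_diagonal(A, 0)
    return A


def threshold_adjacency(network: GroupNetwork, thresholds) -> GroupNetwork:
    """Populate the adjacency stack over a strictly increasing threshold grid."""
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim != 1 or len(thresholds) == 0:
        raise ValidationError("threshold grid must be a non-empty 1-D sequence")
    if np.any(np.diff(thresholds) <= 0):
        raise ValidationError("thresholds must be strictly increasing")
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValidationError("thresholds must lie in (0, 1)")
    A = np.stack([adjacency_at(network.R, t) for t in thresholds])
    # edge-set monotonicity across the grid is structural; assert it anyway
    for k in range(1, len(thresholds)):
        assert not np.any(A[k] & ~A[k - 1]), "adjacency stack not monotone"
    return replace(network, thresholds=thresholds, A=A)


def is_connected(A: np.ndarray) -> bool:
    n_comp, _ = connected_components(A, directed=False)
    return bool(n_comp == 1)


def select_threshold_grid(
    networks,
    t_min: float = 0.49,
    step: float = 0.01,
    hard_max: float = 0.95,
) -> np.ndarray:
    """Threshold grid [t_min, t_min+step, ..., t_max].

    t_max is the largest grid value at which every group's adjacency is a
    single connected component, capped at ``hard_max``.  Errors if even
    t_min leaves some group disconnected.
    """
    if not (0 < t_min < 1):
        raise ValidationError("t_min must lie in (0, 1)")
    if step <= 0:
        raise ValidationError("step must be positive")
    grid = []
    k = 0
    while True:
        t = round(t_min + k * step, 10)
        if t > hard_max + 1e-12:
            break
        if all(is_connected(adjacency_at(net.R, t)) for net in networks):
            grid.append(t)
            k += 1
        else:
            break
    if not grid:
        raise ValidationError(
            f"some group is disconnected already at t_min={t_min}; choose a lower t_min"
        )
    return np.asarray(grid)
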