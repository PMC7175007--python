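"""Synthetic cohorts with known ground truth.

Generates a 2-genotype x 3-treatment cohort over R regions from group-wise
multivariate Gaussians whose correlation matrices carry planted structure:
a densely interconnected block ("club"), hub regions attached to that club
at ``hub_corr``, background modules that keep thresholded networks
connected, edges lost in the mutant, and a drug effect that restores a
subset of the lost edges plus the planted mean shifts.

A note on geometry: a node cannot be highly correlated with many mutually
*uncorrelated* partners (the sum of its squared correlations to an
orthogonal set is bounded by 1), so planted hubs gain their edges through
club membership rather than indiscriminate elevation; this keeps the target
matrices (near-)positive semi-definite so the PSD repair step stays a
no-op or a tiny perturbation of the planted entries.

Groups are drawn in fixed lexicographic (genotype, treatment) order from a
single seeded RNG stream, so a seed fully determines the cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CohortTable, RegionTable, ValidationError, default_regions

PSD_EIG_FLOOR = 1e-8


def _default_group_sizes() -> dict:
    return {
        ("WT", "SAL"): 8,
        ("WT", "KET"): 9,
        ("WT", "AMPH"): 9,
        ("HET", "SAL"): 10,
        ("HET", "KET"): 13,
        ("HET", "AMPH"): 11,
    }


def _default_mean_shift() -> dict:
    # mutant hypermetabolism in the interconnected block, normalized by KET
    shift = {}
    for r in range(7):
        shift[r] = {("HET", "SAL"): 0.12, ("HET", "AMPH"): 0.12}
    return shift


def _default_modules(n_regions: int, first: int = 10, size: int = 4) -> tuple:
    """Partition regions [first, n_regions) into background modules."""
    mods = []
    r = first
    while r < n_regions:
        mods.append(frozenset(range(r, min(r + size, n_regions))))
        r += size
    return tuple(mods)


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth recipe for one synthetic cohort.

    ``rcc_regions`` form a mutually correlated block at ``rcc_corr``;
    ``hub_regions`` attach to that block (and to each other) at ``hub_corr``;
    ``modules`` are mutually correlated background blocks at ``module_corr``
    that keep the thresholded networks connected; ``planted_edges`` are
    explicit extra pairwise elevations (the default lost edges live here as
    isolated strongly-correlated pairs, which concentrates seed-region VIP
    on the planted target); everything else sits at ``base_corr``.
    """

    n_regions: int = 59
    n_per_group: dict = field(default_factory=_default_group_sizes)
    base_corr: float = 0.15
    hub_regions: frozenset = frozenset({14, 15, 16})
    hub_corr: float = 0.85
    rcc_regions: frozenset = frozenset(range(14))
    rcc_corr: float = 0.9
    modules: tuple | None = None  # None -> default partition of the remainder
    module_corr: float = 0.8
    planted_edges: dict = field(
        default_factory=lambda: {(17, 18): 0.97, (19, 20): 0.97, (21, 22): 0.97}
    )
    lost_edges_het: frozenset = frozenset({(17, 18), (19, 20), (21, 22)})
    restored_by_ket: frozenset = frozenset({(17, 18), (19, 20)})
    mean_shift: dict = field(default_factory=_default_mean_shift)
    sex_shift: float = 0.0
    noise_sd: float = 0.08
    floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("base_corr", "hub_corr", "rcc_corr", "module_corr"):
            v = getattr(self, name)
            if not (-1.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (-1, 1), got {v}")
        if self.n_regions < 2:
            raise ValidationError("n_regions must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        object.__setattr__(
            self, "hub_regions", frozenset(int(r) for r in self.hub_regions)
        )
        object.__setattr__(
            self, "rcc_regions", frozenset(int(r) for r in self.rcc_regions)
        )
        object.__setattr__(
            self,
            "planted_edges",
            {
                (min(int(i), int(j)), max(int(i), int(j))): float(v)
                for (i, j), v in self.planted_edges.items()
            },
        )
        if self.modules is None:
            planted = (
                self.hub_regions
                | self.rcc_regions
                | {r for e in self.planted_edges for r in e}
            )
            first = (max(planted) + 1) if planted else 0
            object.__setattr__(self, "modules", _default_modules(self.n_regions, first))
        else:
            object.__setattr__(
                self,
                "modules",
                tuple(frozenset(int(r) for r in mod) for mod in self.modules),
            )
        if any(not (0 <= r < self.n_regions) for mod in self.modules for r in mod):
            raise ValidationError("module region index out of range")
        norm_edges = lambda edges: frozenset(
            (min(int(i), int(j)), max(int(i), int(j))) for i, j in edges
        )
        object.__setattr__(self, "lost_edges_het", norm_edges(self.lost_edges_het))
        object.__setattr__(self, "restored_by_ket", norm_edges(self.restored_by_ket))
        all_idx = (
            self.hub_regions
            | self.rcc_regions
            | {r for e in self.lost_edges_het for r in e}
            | {r for e in self.planted_edges for r in e}
        )
        if any(not (0 <= r < self.n_regions) for r in all_idx):
            raise ValidationError("planted region index out of range")
        if not self.restored_by_ket <= self.lost_edges_het:
            raise ValidationError("restored_by_ket must be a subset of lost_edges_het")
        for (g, t), n in self.n_per_group.items():
            if n < 3:
                raise ValidationError(
                    f"group ({g}, {t}) has n={n}; need >= 3 for correlation estimation"
                )

    def groups(self):
        return sorted(self.n_per_group)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        """Build a spec from YAML-friendly plain types.

        Group keys may be written ``"WT/SAL"`` (or ``"WT,SAL"``); edges as
        2-lists; ``planted_edges`` as a mapping ``"i,j" -> corr``;
        ``mean_shift`` as ``{region: {"G/T": shift}}``.
        """
        d = dict(d)

        def group_key(k):
            if isinstance(k, str):
                parts = [p for p in k.replace("/", ",").split(",") if p]
                if len(parts) != 2:
                    raise ValidationError(f"bad group key {k!r}")
                return tuple(parts)
            return tuple(k)

        if "n_per_group" in d:
            d["n_per_group"] = {
                group_key(k): int(v) for k, v in d["n_per_group"].items()
            }
        for key in ("lost_edges_het", "restored_by_ket"):
            if key in d:
                d[key] = frozenset(tuple(int(r) for r in e) for e in d[key])
        for key in ("hub_regions", "rcc_regions"):
            if key in d:
                d[key] = frozenset(int(r) for r in d[key])
        if "modules" in d and d["modules"] is not None:
            d["modules"] = tuple(frozenset(int(r) for r in m) for m in d["modules"])
        if "planted_edges" in d:
            edges = {}
            for k, v in d["planted_edges"].items():
                if isinstance(k, str):
                    i, j = (int(x) for x in k.split(","))
                else:
                    i, j = (int(x) for x in k)
                edges[(i, j)] = float(v)
            d["planted_edges"] = edges
        if "mean_shift" in d:
            d["mean_shift"] = {
                int(r): {group_key(k): float(v) for k, v in shifts.items()}
                for r, shifts in d["mean_shift"].items()
            }
        return cls(**d)


def _repair_psd(C: np.ndarray) -> tuple:
    """Clip eigenvalues at a small positive floor and renormalize to unit
    diagonal.  Returns (repaired matrix, was_repaired)."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= PSD_EIG_FLOOR:
        return C, False
    vals = np.clip(vals, PSD_EIG_FLOOR, None)
    C2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    C2 = (C2 + C2.T) / 2.0
    np.fill_diagonal(C2, 1.0)
    return C2, True


def build_group_correlation(
    spec: SyntheticSpec, genotype: str, treatment: str
) -> tuple:
    """Target correlation matrix for one group; returns (matrix, repaired).

    Planted order: base everywhere, module blocks to ``module_corr``, the
    club block to ``rcc_corr``, hub-to-club (and hub-to-hub) edges to
    ``hub_corr``, then explicit ``planted_edges``; for HET/SAL and HET/AMPH
    the ``lost_edges_het`` drop back to base, and for HET/KET only those
    outside ``restored_by_ket`` do.  A lost edge that was never elevated is
    a contradiction and errors.
    """
    R = spec.n_regions
    C = np.full((R, R), spec.base_corr)
    for mod in spec.modules:
        members = sorted(mod)
        for i in members:
            for j in members:
                if i != j:
                    C[i, j] = spec.module_corr
    block = sorted(spec.rcc_regions)
    for i in block:
        for j in block:
            if i != j:
                C[i, j] = spec.rcc_corr
    club = sorted(spec.rcc_regions | spec.hub_regions)
    for h in sorted(spec.hub_regions):
        for j in club:
            if j != h:
                C[h, j] = C[j, h] = spec.hub_corr
    for (i, j), v in sorted(spec.planted_edges.items()):
        C[i, j] = C[j, i] = v
    np.fill_diagonal(C, 1.0)

    for i, j in sorted(spec.lost_edges_het):
        if C[i, j] <= spec.base_corr:
            raise ValidationError(
                f"edge ({i}, {j}) is listed as lost but carries no planted elevation"
            )
    if genotype == "HET":
        if treatment in ("SAL", "AMPH"):
            removed = spec.lost_edges_het
        elif treatment == "KET":
            removed = spec.lost_edges_het - spec.restored_by_ket
        else:
            raise ValidationError(f"unknown treatment {treatment!r}")
        for i, j in removed:
            C[i, j] = C[j, i] = spec.base_corr
    return _repair_psd(C)


def _mean_vector(spec: SyntheticSpec, genotype: str, treatment: str) -> np.ndarray:
    mu = np.ones(spec.n_regions)
    for region, shifts in spec.mean_shift.items():
        mu[int(region)] += shifts.get((genotype, treatment), 0.0)
    return mu


def generate_cohort(
    spec: SyntheticSpec, regions: RegionTable | None = None
) -> CohortTable:
    """Draw the full cohort described by ``spec``; identical seed, identical
    output (bit for bit).

    Each group's animals are drawn from N(1 + mean_shift,
    noise_sd^2 * C_group), truncated below at ``spec.floor``; sex alternates
    M/F within each group (plus the optional ``sex_shift`` hook for F).
    """
    if regions is None:
        regions = default_regions(spec.n_regions)
    if regions.n_regions != spec.n_regions:
        raise ValidationError("region table size does not match spec.n_regions")
    rng = np.random.default_rng(spec.seed)
    uptake_rows = []
    ids, genos, treats, sexes = [], [], [], []
    for genotype, treatment in spec.groups():
        n = spec.n_per_group[(genotype, treatment)]
        C, _ = build_group_correlation(spec, genotype, treatment)
        vals = np.linalg.eigvalsh(C)
        if vals.min() < -1e-10:
            raise ValidationError(
                f"group ({genotype}, {treatment}) covariance is not PSD after repair"
            )
        mu = _mean_vector(spec, genotype, treatment)
        cov = spec.noise_sd**2 * C
        X = rng.multivariate_normal(mu, cov, size=n, method="eigh")
        sex = np.array(["M" if i % 2 == 0 else "F" for i in range(n)])
        if spec.sex_shift:
            X[sex == "F"] += spec.sex_shift
        X = np.clip(X, spec.floor, None)
        uptake_rows.append(X)
        ids.extend(f"{genotype}-{treatment}-{i:02d}" for i in range(n))
        genos.extend([genotype] * n)
        treats.extend([treatment] * n)
        sexes.extend(sex.tolist())
    return CohortTable(
        uptake=np.vstack(uptake_rows),
        animal_id=tuple(ids),
        genotype=tuple(genos),
        treatment=tuple(treats),
        sex=tuple(sexes),
        regions=regions,
    )


def ground_truth(spec: SyntheticSpec) -> dict:
    """Planted structure as a plain dict (YAML-serializable)."""
    return {
        "n_regions": spec.n_regions,
        "hub_regions": sorted(spec.hub_regions),
        "rcc_regions": sorted(spec.rcc_regions),
        "lost_edges_het": sorted(list(e) for e in spec.lost_edges_het),
        "restored_by_ket": sorted(list(e) for e in spec.restored_by_ket),
        "mean_shift": {
            int(r): {f"{g}/{t}": float(v) for (g, t), v in shifts.items()}
            for r, shifts in spec.mean_shift.items()
        },
        "modules": [sorted(mod) for mod in spec.modules],
        "planted_edges": {f"{i},{j}": float(v) for (i, j), v in sorted(spec.planted_edges.items())},
        "base_corr": spec.base_corr,
        "hub_corr": spec.hub_corr,
        "rcc_corr": spec.rcc_corr,
        "module_corr": spec.module_corr,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
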