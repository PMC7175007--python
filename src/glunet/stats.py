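"""Regional metabolism statistics: uptake ratios, factorial ANOVA and
Benjamini–Hochberg-corrected post hoc contrasts.

The factorial ANOVA uses Type II (marginal) sums of squares by default —
the conventional choice for unbalanced designs — computed by model
comparison with treatment-coded design matrices, so the result is invariant
to the contrast coding.  Type III (via effects coding) is available.
Post hoc pairwise tests default to Welch (unequal variances).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import CohortTable, ValidationError


def uptake_ratio(region_value: float, whole_brain_value: float) -> float:
    """Regional isotope concentration relative to the whole-brain value."""
    if whole_brain_value <= 0:
        raise ValidationError("whole-brain value must be positive")
    if region_value == 0:
        warnings.warn(
            "zero regional value gives uptake ratio 0 (biologically implausible)",
            RuntimeWarning,
            stacklevel=2,
        )
    return region_value / whole_brain_value


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    """Factorial ANOVA for one region: effect name -> :class:`EffectResult`.

    Effect names are ':'-joined factor names (e.g. ``genotype:treatment``).
    ``main_effect_accepted`` mirrors the reporting rule that a genotype main
    effect stands when no genotype interaction is significant — it is a flag,
    not a refit.
    """

    effects: dict
    residual_df: int
    ss_type: int
    main_effect_accepted: dict

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]


def _contrast_columns(levels_idx: np.ndarray, n_levels: int, coding: str) -> np.ndarray:
    """(n, n_levels-1) contrast columns; 'treatment' drops the first level,
    'effects' is sum-to-zero."""
    n = len(levels_idx)
    cols = np.zeros((n, n_levels - 1))
    for j in range(1, n_levels):
        cols[:, j - 1] = (levels_idx == j).astype(float)
    if coding == "effects":
        first = levels_idx == 0
        cols[first, :] = -1.0
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> tuple:
    """Residual sum of squares and rank for the least-squares fit of y on X."""
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return float(np.sum((y - fitted) ** 2)), int(rank)


def anova_table(y: np.ndarray, factors: dict, ss_type: int = 2) -> AnovaResult:
    """Full-factorial ANOVA of ``y`` on the ordered ``factors`` mapping
    (name -> per-observation level labels).

    Type II compares, for each term, the model of all terms not containing
    it against that model plus the term; the denominator is the full-model
    residual mean square.  Empty cells for any interaction term are an error
    naming the missing cell.
    """
    y = np.asarray(y, dtype=float)
    if ss_type not in (2, 3):
        raise ValidationError("ss_type must be 2 or 3")
    names = list(factors)
    levels = {}
    idx = {}
    for name in names:
        labels = np.asarray(factors[name])
        uniq = list(dict.fromkeys(labels.tolist()))  # first-appearance order
        if len(uniq) < 2:
            raise ValidationError(f"factor {name!r} needs >= 2 observed levels")
        levels[name] = uniq
        idx[name] = np.array([uniq.index(v) for v in labels])

    terms = []
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            terms.append(combo)

    # empty-cell check for every interaction term
    for combo in terms:
        if len(combo) < 2:
            continue
        for cell in itertools.product(*(range(len(levels[f])) for f in combo)):
            present = np.ones(len(y), dtype=bool)
            for f, li in zip(combo, cell):
                present &= idx[f] == li
            if not present.any():
                label = ", ".join(
                    f"{f}={levels[f][li]}" for f, li in zip(combo, cell)
                )
                raise ValidationError(f"empty cell for interaction {':'.join(combo)}: ({label})")

    coding = "treatment" if ss_type == 2 else "effects"
    base_cols = {
        name: _contrast_columns(idx[name], len(levels[name]), coding) for name in names
    }

    def term_matrix(combo):
        cols = base_cols[combo[0]]
        for f in combo[1:]:
            other = base_cols[f]
            cols = np.einsum("ni,nj->nij", cols, other).reshape(len(y), -1)
        return cols

    X_term = {combo: term_matrix(combo) for combo in terms}
    intercept = np.ones((len(y), 1))
    X_full = np.hstack([intercept] + [X_term[c] for c in terms])
    rss_full, rank_full = _rss(X_full, y)
    df_res = len(y) - rank_full
    if df_res < 1:
        raise ValidationError("residual degrees of freedom < 1; model is saturated")
    ms_res = rss_full / df_res

    effects = {}
    for combo in terms:
        if ss_type == 2:
            base_terms = [c for c in terms if not set(combo).issubset(set(c))]
        else:
            base_terms = [c for c in terms if c != combo]
        X0 = np.hstack([intercept] + [X_term[c] for c in base_terms]) if base_terms else intercept
        X1 = np.hstack([X0, X_term[combo]])
        rss0, rank0 = _rss(X0, y)
        rss1, rank1 = _rss(X1, y)
        df_num = rank1 - rank0
        if df_num < 1:
            raise ValidationError(f"term {':'.join(combo)} adds no estimable contrast")
        F = ((rss0 - rss1) / df_num) / ms_res
        F = max(F, 0.0)
        p = float(sps.f.sf(F, df_num, df_res))
        effects[":".join(combo)] = EffectResult(F=float(F), df_num=df_num, df_den=df_res, p=p)

    # reporting rule: a factor's main effect "stands" when none of its
    # interactions is significant at 0.05
    accepted = {}
    for name in names:
        inter_ps = [
            res.p
            for key, res in effects.items()
            if ":" in key and name in key.split(":")
        ]
        accepted[name] = all(p >= 0.05 for p in inter_ps)
    return AnovaResult(
        effects=effects, residual_df=df_res, ss_type=ss_type, main_effect_accepted=accepted
    )


def factorial_anova(
    cohort: CohortTable,
    region: int,
    factors=("sex", "genotype", "treatment"),
    ss_type: int = 2,
    treatments: tuple | None = None,
) -> AnovaResult:
    """Factorial ANOVA of one region's uptake ratios on animal factors.

    ``treatments`` optionally restricts the cohort to a treatment subset
    (e.g. ``("SAL", "KET")`` for the saline-vs-drug design).
    """
    data = cohort
    if treatments is not None:
        data = cohort.subset(np.isin(cohort.treatment, treatments))
    y = data.uptake[:, region]
    fac = {}
    for name in factors:
        if name not in ("sex", "genotype", "treatment"):
            raise ValidationError(f"unknown factor {name!r}")
        fac[name] = np.asarray(getattr(data, name))
    return anova_table(y, fac, ss_type=ss_type)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass(frozen=True)
class Contrast:
    cell_a: tuple
    cell_b: tuple
    t: float
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class PosthocTable:
    region: int
    contrasts: list
    equal_var: bool


def _welch_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def posthoc_pairwise(
    cohort: CohortTable,
    region: int,
    cells,
    equal_var: bool = False,
    alpha: float = 0.05,
) -> PosthocTable:
    """Pairwise t-tests for every pair of the requested (genotype, treatment)
    cells, BH-corrected within this family only."""
    groups = {}
    for cell in cells:
        g, t = cell
        mask = cohort.group_mask(g, t)
        if mask.sum() < 2:
            raise ValidationError(f"cell {cell} has {int(mask.sum())} animals; need >= 2")
        groups[tuple(cell)] = cohort.uptake[mask, region]
    pairs = list(itertools.combinations(groups, 2))
    raw = []
    ts = []
    for a, b in pairs:
        t, p = _welch_t(groups[a], groups[b], equal_var)
        ts.append(t)
        raw.append(p)
    adj = bh_adjust(raw) if raw else np.array([])
    contrasts = [
        Contrast(
            cell_a=a,
            cell_b=b,
            t=t,
            p_raw=p,
            p_adjusted=float(q),
            significant=bool(q < alpha),
        )
        for (a, b), t, p, q in zip(pairs, ts, raw, adj)
    ]
    return PosthocTable(region=region, contrasts=contrasts, equal_var=equal_var)
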