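import numpy as np
import pytest

from glunet import io, synthetic


def make_cohort(uptake, genotype, treatment, sex=None, regions=None):
    """Build a validated CohortTable from plain arrays (animals x regions)."""
    uptake = np.asarray(uptake, dtype=float)
    n, r = uptake.shape
    if sex is None:
        sex = tuple("M" if i % 2 == 0 else "F" for i in range(n))
    if regions is None:
        regions = io.default_regions(r)
    return io.CohortTable(
        uptake=uptake,
        animal_id=tuple(f"a{i:03d}" for i in range(n)),
        genotype=tuple(genotype),
        treatment=tuple(treatment),
        sex=tuple(sex),
        regions=regions,
    )


def plain_spec(**overrides):
    """SyntheticSpec with no planted structure unless overridden."""
    defaults = dict(
        hub_regions=frozenset(),
        rcc_regions=frozenset(),
        modules=(),
        planted_edges={},
        lost_edges_het=frozenset(),
        restored_by_ket=frozenset(),
        mean_shift={},
    )
    defaults.update(overrides)
    return synthetic.SyntheticSpec(**defaults)


@pytest.fixture
def tiny_cohort():
    """4 animals x 5 regions, two groups, deterministic values."""
    rng = np.random.default_rng(42)
    uptake = 1.0 + 0.1 * rng.standard_normal((4, 5))
    return make_cohort(
        uptake,
        genotype=("WT", "WT", "HET", "HET"),
        treatment=("SAL", "SAL", "SAL", "SAL"),
    )


@pytest.fixture
def group_cohort():
    """One 10-animal WT/SAL group over 6 regions with correlated structure."""
    rng = np.random.default_rng(7)
    base = rng.standard_normal((10, 1))
    uptake = 1.0 + 0.05 * (0.6 * base + 0.8 * rng.standard_normal((10, 6)))
    return make_cohort(uptake, genotype=["WT"] * 10, treatment=["SAL"] * 10)
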