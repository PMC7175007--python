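"""Tabular I/O for regional-uptake cohorts, region catalogues and group networks.

All files are plain UTF-8 CSV with "." as the decimal separator.  The uptake
table is stored regions-as-rows on disk (the way densitometry tables are
transcribed) and transposed to animals x regions in memory.  Validation is
strict: missing cells, duplicated identifiers or animals present in only one
of the two input tables are hard errors — nothing is imputed or dropped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "HET")
TREATMENTS = ("SAL", "KET", "AMPH")
SEXES = ("M", "F")


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


@dataclass(frozen=True)
class RegionTable:
    """Catalogue of brain regions of interest.

    Region ids are implicit row positions (0..R-1); the on-disk format is a
    CSV with columns ``abbreviation,name,system``.
    """

    abbreviation: tuple
    name: tuple
    system: tuple

    def __post_init__(self):
        if not (len(self.abbreviation) == len(self.name) == len(self.system)):
            raise ValidationError("region table columns have unequal lengths")
        abbrs = list(self.abbreviation)
        if any((not a) or (not str(a).strip()) for a in abbrs):
            raise ValidationError("region abbreviations must be non-empty")
        if len(set(abbrs)) != len(abbrs):
            dupes = sorted({a for a in abbrs if abbrs.count(a) > 1})
            raise ValidationError(f"duplicate region abbreviations: {dupes}")

    @property
    def n_regions(self) -> int:
        return len(self.abbreviation)

    def index_of(self, abbreviation: str) -> int:
        try:
            return self.abbreviation.index(abbreviation)
        except ValueError:
            raise KeyError(f"unknown region abbreviation {abbreviation!r}") from None

    @classmethod
    def from_csv(cls, path) -> "RegionTable":
        df = pd.read_csv(path, dtype=str)
        required = {"abbreviation", "name", "system"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"region CSV must have columns {sorted(required)}, got {list(df.columns)}"
            )
        return cls(
            abbreviation=tuple(df["abbreviation"]),
            name=tuple(df["name"]),
            system=tuple(df["system"]),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "abbreviation": self.abbreviation,
                "name": self.name,
                "system": self.system,
            }
        ).to_csv(path, index=False)


# Default 59-region catalogue.  The first seven rows are thalamic nuclei and
# prefrontal subfields so that the synthetic generator's planted hub /
# densely-interconnected block defaults land on anatomically sensible labels.
_DEFAULT_REGIONS = [
    ("dRT", "dorsal reticular thalamus", "Thalamus"),
    ("vRT", "ventral reticular thalamus", "Thalamus"),
    ("Re", "nucleus reuniens", "Thalamus"),
    ("CM", "centromedial thalamus", "Thalamus"),
    ("CL", "centrolateral thalamus", "Thalamus"),
    ("aPrL", "anterior prelimbic cortex", "PFC"),
    ("Cg1", "anterior cingulate cortex area 1", "PFC"),
    ("MD", "mediodorsal thalamus", "Thalamus"),
    ("AM", "anteromedial thalamus", "Thalamus"),
    ("VL", "ventrolateral thalamus", "Thalamus"),
    ("VPL", "ventral posterolateral thalamus", "Thalamus"),
    ("LD", "laterodorsal thalamus", "Thalamus"),
    ("pPrL", "posterior prelimbic cortex", "PFC"),
    ("IL", "infralimbic cortex", "PFC"),
    ("VO", "ventral orbital cortex", "PFC"),
    ("LO", "lateral orbital cortex", "PFC"),
    ("DLO", "dorsolateral orbital cortex", "PFC"),
    ("Cg2", "anterior cingulate cortex area 2", "PFC"),
    ("M2", "secondary motor cortex", "PFC"),
    ("NAcC", "nucleus accumbens core", "Mesolimbic"),
    ("NAcSh", "nucleus accumbens shell", "Mesolimbic"),
    ("VTA", "ventral tegmental area", "Mesolimbic"),
    ("OT", "olfactory tubercle", "Mesolimbic"),
    ("CPu", "caudate putamen", "BG"),
    ("GP", "globus pallidus", "BG"),
    ("SNC", "substantia nigra pars compacta", "BG"),
    ("SNR", "substantia nigra pars reticulata", "BG"),
    ("STN", "subthalamic nucleus", "BG"),
    ("EP", "entopeduncular nucleus", "BG"),
    ("dCA1", "dorsal hippocampus CA1", "Hipp"),
    ("dCA2", "dorsal hippocampus CA2", "Hipp"),
    ("dCA3", "dorsal hippocampus CA3", "Hipp"),
    ("DG", "dentate gyrus", "Hipp"),
    ("VHCA1", "ventral hippocampus CA1", "Hipp"),
    ("VHCA2", "ventral hippocampus CA2", "Hipp"),
    ("VHCA3", "ventral hippocampus CA3", "Hipp"),
    ("Sub", "subiculum", "Hipp"),
    ("MS", "medial septum", "Sept/DB"),
    ("LS", "lateral septum", "Sept/DB"),
    ("VDB", "vertical limb of the diagonal band", "Sept/DB"),
    ("HDB", "horizontal limb of the diagonal band", "Sept/DB"),
    ("DRN", "dorsal raphe nucleus", "5-HT"),
    ("MRN", "median raphe nucleus", "5-HT"),
    ("BLA", "basolateral amygdala", "Amg"),
    ("CeA", "central amygdala", "Amg"),
    ("MeA", "medial amygdala", "Amg"),
    ("LaA", "lateral amygdala", "Amg"),
    ("AC", "auditory cortex", "Aud"),
    ("MG", "medial geniculate nucleus", "Aud"),
    ("IC", "inferior colliculus", "Aud"),
    ("LL", "lateral lemniscus", "Aud"),
    ("V1", "primary visual cortex", "Other"),
    ("SC", "superior colliculus", "Other"),
    ("S1BF", "somatosensory barrel field", "Other"),
    ("M1", "primary motor cortex", "Other"),
    ("LH", "lateral hypothalamus", "Other"),
    ("MB", "mammillary body", "Other"),
    ("PAG", "periaqueductal gray", "Other"),
    ("Cb", "cerebellar cortex", "Other"),
]


def default_regions(n_regions: int = 59) -> RegionTable:
    """Default region catalogue.

    For ``n_regions`` <= 59 a prefix of the built-in catalogue is used;
    beyond that, numbered placeholder regions are appended.  The table is
    user-replaceable via any CSV with the same columns.
    """
    rows = list(_DEFAULT_REGIONS[:n_regions])
    for i in range(len(rows), n_regions):
        rows.append((f"RoI{i:02d}", f"placeholder region {i}", "Other"))
    return RegionTable(
        abbreviation=tuple(r[0] for r in rows),
        name=tuple(r[1] for r in rows),
        system=tuple(r[2] for r in rows),
    )


assert len(_DEFAULT_REGIONS) == 59


@dataclass(frozen=True)
class CohortTable:
    """Per-animal uptake ratios plus genotype/treatment/sex metadata.

    ``uptake`` is animals x regions; column order matches ``regions``.
    """

    uptake: np.ndarray
    animal_id: tuple
    genotype: tuple
    treatment: tuple
    sex: tuple
    regions: RegionTable

    def __post_init__(self):
        up = np.asarray(self.uptake, dtype=float)
        object.__setattr__(self, "uptake", up)
        n, r = up.shape
        if r != self.regions.n_regions:
            raise ValidationError(
                f"uptake has {r} regions but region table has {self.regions.n_regions}"
            )
        for name, col in (
            ("animal_id", self.animal_id),
            ("genotype", self.genotype),
            ("treatment", self.treatment),
            ("sex", self.sex),
        ):
            if len(col) != n:
                raise ValidationError(f"{name} has length {len(col)}, expected {n}")
        ids = list(self.animal_id)
        if len(set(ids)) != len(ids):
            dupes = sorted({a for a in ids if ids.count(a) > 1})
            raise ValidationError(f"duplicate animal_id: {dupes}")
        for name, col, levels in (
            ("genotype", self.genotype, GENOTYPES),
            ("treatment", self.treatment, TREATMENTS),
            ("sex", self.sex, SEXES),
        ):
            bad = sorted({v for v in col if v not in levels})
            if bad:
                raise ValidationError(f"unknown {name} level(s) {bad}; allowed {levels}")
        if not np.all(np.isfinite(up)):
            i, j = (int(x) for x in np.argwhere(~np.isfinite(up))[0])
            raise ValidationError(
                f"missing or non-finite uptake for animal {self.animal_id[i]!r}, "
                f"region {self.regions.abbreviation[j]!r}"
            )
        if np.any(up <= 0):
            i, j = (int(x) for x in np.argwhere(up <= 0)[0])
            raise ValidationError(
                f"non-positive uptake for animal {self.animal_id[i]!r}, "
                f"region {self.regions.abbreviation[j]!r}"
            )

    @property
    def n_animals(self) -> int:
        return self.uptake.shape[0]

    @property
    def n_regions(self) -> int:
        return self.uptake.shape[1]

    def group_mask(self, genotype: str, treatment: str) -> np.ndarray:
        return np.array(
            [g == genotype and t == treatment for g, t in zip(self.genotype, self.treatment)]
        )

    def group_uptake(self, genotype: str, treatment: str) -> np.ndarray:
        return self.uptake[self.group_mask(genotype, treatment)]

    def subset(self, mask: np.ndarray) -> "CohortTable":
        mask = np.asarray(mask, dtype=bool)
        pick = lambda col: tuple(v for v, m in zip(col, mask) if m)
        return CohortTable(
            uptake=self.uptake[mask],
            animal_id=pick(self.animal_id),
            genotype=pick(self.genotype),
            treatment=pick(self.treatment),
            sex=pick(self.sex),
            regions=self.regions,
        )


def read_cohort(uptake_path, metadata_path, regions_path) -> CohortTable:
    """Read and validate the three input CSVs into a :class:`CohortTable`.

    The uptake CSV has a first column ``region`` (abbreviations, one row per
    region, in region-table order) and one column per animal.  The metadata
    CSV has columns ``animal_id,genotype,treatment,sex``.
    """
    regions = RegionTable.from_csv(regions_path)
    up = pd.read_csv(uptake_path, dtype=str)
    if up.columns[0] != "region":
        raise ValidationError("uptake CSV must have 'region' as its first column")
    meta = pd.read_csv(metadata_path, dtype=str)
    required = {"animal_id", "genotype", "treatment", "sex"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata CSV must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    disk_regions = tuple(up["region"])
    if disk_regions != regions.abbreviation:
        raise ValidationError(
            "uptake CSV region order does not match the region table "
            f"(first mismatch at row "
            f"{next(i for i, (a, b) in enumerate(zip(disk_regions, regions.abbreviation)) if a != b) if len(disk_regions) == regions.n_regions else 'n/a'})"
        )
    uptake_animals = list(up.columns[1:])
    if len(set(uptake_animals)) != len(uptake_animals):
        raise ValidationError("duplicate animal columns in uptake CSV")
    meta_animals = list(meta["animal_id"])
    if len(set(meta_animals)) != len(meta_animals):
        raise ValidationError("duplicate animal_id in metadata CSV")
    only_meta = sorted(set(meta_animals) - set(uptake_animals))
    only_uptake = sorted(set(uptake_animals) - set(meta_animals))
    if only_meta or only_uptake:
        raise ValidationError(
            f"animal mismatch between metadata and uptake: metadata-only={only_meta}, "
            f"uptake-only={only_uptake}"
        )
    # uptake column order is canonical; align metadata to it
    meta = meta.set_index("animal_id").loc[uptake_animals]
    def parse(value):
        # exact round-trip parsing (pandas' fast parser is not correctly
        # rounded); blanks and junk count as missing
        try:
            return float(value)
        except (TypeError, ValueError):
            return float("nan")

    values = np.empty((len(uptake_animals), regions.n_regions))
    for ai, animal in enumerate(uptake_animals):
        col = np.array([parse(v) for v in up[animal]])
        if np.any(~np.isfinite(col)):
            j = int(np.flatnonzero(~np.isfinite(col))[0])
            raise ValidationError(
                f"missing uptake cell for animal {animal!r}, region "
                f"{regions.abbreviation[j]!r}"
            )
        values[ai] = col
    return CohortTable(
        uptake=values,
        animal_id=tuple(uptake_animals),
        genotype=tuple(meta["genotype"]),
        treatment=tuple(meta["treatment"]),
        sex=tuple(meta["sex"]),
        regions=regions,
    )


def write_cohort(cohort: CohortTable, uptake_path, metadata_path, regions_path) -> None:
    """Write a cohort to the three-CSV on-disk layout (regions as rows)."""
    cohort.regions.to_csv(regions_path)
    df = pd.DataFrame(
        cohort.uptake.T, columns=list(cohort.animal_id)
    )
    df.insert(0, "region", list(cohort.regions.abbreviation))
    df.to_csv(uptake_path, index=False, float_format="%.17g")
    pd.DataFrame(
        {
            "animal_id": cohort.animal_id,
            "genotype": cohort.genotype,
            "treatment": cohort.treatment,
            "sex": cohort.sex,
        }
    ).to_csv(metadata_path, index=False)


def write_edge_list(network, threshold_index: int, path) -> None:
    """Write one CSV row per edge (i<j) of the adjacency at a grid threshold.

    Columns: ``region_a,region_b,r,z``.  Re-thresholding the written ``r``
    values at the same threshold reproduces the adjacency exactly.
    """
    if network.A is None or network.thresholds is None:
        raise ValidationError("network has no adjacency stack; run threshold_adjacency first")
    if not (0 <= threshold_index < len(network.thresholds)):
        raise IndexError(
            f"threshold_index {threshold_index} out of range "
            f"[0, {len(network.thresholds) - 1}]"
        )
    A = network.A[threshold_index]
    abbr = network.regions.abbreviation
    rows = []
    ii, jj = np.triu_indices(A.shape[0], k=1)
    for i, j in zip(ii, jj):
        if A[i, j]:
            rows.append(
                (abbr[i], abbr[j], network.R[i, j], network.Z[i, j])
            )
    pd.DataFrame(rows, columns=["region_a", "region_b", "r", "z"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_adjacency(network, threshold_index: int, path) -> None:
    """Square 0/1 adjacency CSV with abbreviation header row/column."""
    if network.A is None:
        raise ValidationError("network has no adjacency stack")
    if not (0 <= threshold_index < len(network.thresholds)):
        raise IndexError("threshold_index out of range")
    abbr = list(network.regions.abbreviation)
    pd.DataFrame(
        network.A[threshold_index].astype(int), index=abbr, columns=abbr
    ).to_csv(path)


def read_adjacency(path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.uint8)
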