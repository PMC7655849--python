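"""Core in-memory containers shared by every stage of the pipeline.

Coordinates are 0-based half-open everywhere inside the package; formats that
use other conventions (VCF, GFF3) are converted on read and write.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "allele_ref", "allele_alt",
                  "ancestral_state"]
ANCESTRAL_STATES = ("ref", "alt", "unresolved")
#: ancestry-group labels used by the study design (three reference groups
#: contrasted against the focal North African group)
DEFAULT_GROUPS = ("AFT", "EUT", "IND", "NorthAFT")
RELATEDNESS_CLASSES = ("commercial", "north_african")
TESTS = ("iHS", "Rsb", "XPEHH")


def validate_marker_table(markers: pd.DataFrame) -> None:
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table lacks columns {missing}")
    if (markers["pos_bp"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based physical bp)")
    bad = ~markers["ancestral_state"].isin(ANCESTRAL_STATES)
    if bad.any():
        raise ValueError(f"invalid ancestral_state values: "
                         f"{sorted(markers.loc[bad, 'ancestral_state'].unique())}")
    key = markers[["chrom", "pos_bp"]]
    # strict sort within chromosome, no duplicate positions
    for chrom, sub in key.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if not (np.diff(pos) > 0).all():
            raise ValueError(f"markers on {chrom} not strictly sorted by position")


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 allele matrix: rows are haplotypes, columns are markers.

    Two consecutive rows per diploid sample (hap A then hap B, sample order
    fixed). After polarization, 0 is the ancestral and 1 the derived allele at
    every marker.
    """

    markers: pd.DataFrame
    haplotypes: np.ndarray
    sample_ids: list[str]
    pop_labels: list[str]

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.markers = self.markers.reset_index(drop=True)

    # -- shape ------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def validate(self) -> None:
        validate_marker_table(self.markers)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must equal 2 x sample count")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype columns must equal marker count")
        if len(self.pop_labels) != len(self.sample_ids):
            raise ValueError("one population label per sample required")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1 with no missing data")

    # -- views ------------------------------------------------------------
    def positions(self) -> np.ndarray:
        return self.markers["pos_bp"].to_numpy(dtype=np.int64)

    def dosage(self) -> np.ndarray:
        """Diploid derived-allele dosage (samples x markers, values 0/1/2)."""
        h = self.haplotypes.astype(np.int16)
        return h[0::2] + h[1::2]

    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def subset_markers(self, index: np.ndarray | Sequence[int]) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return HaplotypeMatrix(self.markers.iloc[index].reset_index(drop=True),
                               self.haplotypes[:, index],
                               list(self.sample_ids), list(self.pop_labels))

    def subset_samples(self, keep: Sequence[str]) -> "HaplotypeMatrix":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep_set]
        rows = np.array([[2 * i, 2 * i + 1] for i in idx], dtype=int).ravel()
        return HaplotypeMatrix(self.markers.copy(),
                               self.haplotypes[rows] if len(rows) else
                               self.haplotypes[:0],
                               [self.sample_ids[i] for i in idx],
                               [self.pop_labels[i] for i in idx])

    def for_populations(self, pops: Iterable[str]) -> "HaplotypeMatrix":
        pops = set(pops)
        keep = [s for s, p in zip(self.sample_ids, self.pop_labels) if p in pops]
        return self.subset_samples(keep)


@dataclass
class PopulationMap:
    """sample -> (population, group, relatedness class) assignment."""

    table: pd.DataFrame  # columns sample_id, population, group, relatedness_class

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in set(self.table["sample_id"])

    def population_of(self, sample_id: str) -> str:
        return self._lookup(sample_id, "population")

    def group_of_population(self, population: str) -> str:
        sub = self.table[self.table["population"] == population]
        if sub.empty:
            raise KeyError(f"unknown population {population!r}")
        return sub["group"].iloc[0]

    def relatedness_class_of(self, sample_id: str) -> str:
        return self._lookup(sample_id, "relatedness_class")

    def populations_in_group(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        return sorted(sub["population"].unique())

    def _lookup(self, sample_id: str, column: str) -> str:
        sub = self.table[self.table["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"sample {sample_id!r} not in population map")
        return sub[column].iloc[0]

    def check_covers(self, sample_ids: Sequence[str]) -> None:
        known = set(self.table["sample_id"])
        absent = [s for s in sample_ids if s not in known]
        if absent:
            raise ValueError(f"samples missing from population map: {absent}")


@dataclass(frozen=True)
class Feature:
    chrom: str
    start_bp: int  # 0-based half-open
    end_bp: int
    name: str
    kind: str  # gene | QTL | SV
    sv_length_bp: Optional[int] = None

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError(f"feature {self.name}: start {self.start_bp} > end {self.end_bp}")


@dataclass
class FeatureSet:
    features: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def of_kind(self, kind: str) -> "FeatureSet":
        return FeatureSet([f for f in self.features if f.kind == kind])


@dataclass
class ScoreTrack:
    """Per-marker scores for one test/contrast.

    ``raw`` is the unstandardized ln-ratio, ``score`` the standardized value
    and ``mlog10p`` the two-sided -log10 p under a standard-normal null.
    """

    test: str
    contrast: Optional[str]  # group pair "A/B" or None for within-population iHS
    table: pd.DataFrame  # chrom, pos_bp, marker_id, raw, score, mlog10p
    standardization: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.test not in TESTS:
            raise ValueError(f"unknown test {self.test!r}; expected one of {TESTS}")
        self.table = self.table.reset_index(drop=True)


@dataclass(frozen=True)
class Region:
    chrom: str
    start_bp: int
    end_bp: int
    methods: frozenset  # of (test, contrast) tags

    @property
    def n_support_methods(self) -> int:
        """Number of distinct tests supporting the region."""
        return len({t for t, _ in self.methods})

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.regions,
                                key=lambda r: (_chrom_key(r.chrom), r.start_bp, r.end_bp)))


def _chrom_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


@dataclass
class AlleleCountMatrix:
    """Derived-allele counts per locus (rows) and population (columns)."""

    derived: np.ndarray  # (n_loci, n_pops) ints
    total: np.ndarray  # chromosomes sampled, same shape
    locus_ids: list[str]
    pop_ids: list[str]

    def __post_init__(self):
        self.derived = np.asarray(self.derived, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.derived.shape != self.total.shape:
            raise ValueError("derived and total count shapes differ")
        if (self.total <= 0).any():
            raise ValueError("every cell needs total chromosomes > 0")
        if ((self.derived < 0) | (self.derived > self.total)).any():
            raise ValueError("derived counts must lie in [0, total]")

    @property
    def n_loci(self) -> int:
        return self.derived.shape[0]

    @property
    def n_pops(self) -> int:
        return self.derived.shape[1]

    def permuted(self, order: np.ndarray) -> "AlleleCountMatrix":
        order = np.asarray(order)
        return AlleleCountMatrix(self.derived[order], self.total[order],
                                 [self.locus_ids[i] for i in order], list(self.pop_ids))
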