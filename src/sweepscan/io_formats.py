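"""Readers and writers for every external format the pipeline touches.

Internal convention: marker positions are 1-based physical bp (as in VCF);
interval features and regions are 0-based half-open. BED passes through
unchanged, GFF3 is shifted on read, VCF genotypes are transcribed as written.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (DEFAULT_GROUPS, RELATEDNESS_CLASSES, Feature,
                        FeatureSet, HaplotypeMatrix, PopulationMap, Region,
                        RegionSet, ScoreTrack, validate_marker_table)

#: sha256 of the packaged transcription of the published region table
_REGION_TABLE_SHA256 = "3bb7474612d8eacba1edbcea8393f22627d57a92cdcc9d7261220e5a840086fe"


# ---------------------------------------------------------------------------
# phased genotypes
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | Path, pop_labels: Optional[dict[str, str]] = None
                    ) -> HaplotypeMatrix:
    """Read a phased, biallelic-SNP VCF into a haplotype matrix.

    Every GT must be phased ("|") and complete; unphased or missing genotypes
    and multiallelic records are hard errors — the pipeline assumes input
    haplotypes were already estimated (e.g. by fastPHASE) and does not impute.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[dict] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        where = f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            raise ValueError(f"multiallelic record at {where}: ALT={variant.ALT}")
        gts = variant.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(gts):
            if len(gt) != 3:
                raise ValueError(f"non-diploid genotype at {where} for {samples[i]}")
            a, b, phased = gt
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {where} for {samples[i]}")
            if not phased:
                raise ValueError(f"unphased genotype at {where} for {samples[i]}")
            col[2 * i], col[2 * i + 1] = a, b
        rows.append(dict(marker_id=variant.ID or where, chrom=variant.CHROM,
                         pos_bp=variant.POS, allele_ref=variant.REF,
                         allele_alt=variant.ALT[0], ancestral_state="unresolved"))
        columns.append(col)
    markers = pd.DataFrame(rows)
    haps = (np.stack(columns, axis=1) if columns
            else np.empty((2 * len(samples), 0), dtype=np.uint8))
    pop_labels = pop_labels or {}
    matrix = HaplotypeMatrix(markers, haps, samples,
                             [pop_labels.get(s, "unknown") for s in samples])
    matrix.validate()
    return matrix


def write_phased_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a minimal phased VCF 4.2 that read_phased_vcf round-trips."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(matrix.markers["chrom"]):
            sub = matrix.markers[matrix.markers["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos_bp'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        h = matrix.haplotypes
        for j, row in matrix.markers.iterrows():
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}"
                            for i in range(matrix.n_samples))
            fh.write(f"{row.chrom}\t{row.pos_bp}\t{row.marker_id}\t{row.allele_ref}"
                     f"\t{row.allele_alt}\t.\t.\t.\tGT\t{gts}\n")


def read_haps(haps_path: str | Path, sample_path: str | Path) -> HaplotypeMatrix:
    """Two-file HAPS/SAMPLE-style text dialect (simulator convenience).

    haps: one marker per line: chrom marker_id pos_bp ref alt hap1 hap2 ...
    sample: header then one line per sample: sample_id population
    """
    sample_df = pd.read_csv(sample_path, sep="\t")
    rows, cols = [], []
    with open(haps_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 5 + 2 * len(sample_df):
                raise ValueError(f"{haps_path}: line {lineno}: too few fields")
            rows.append(dict(marker_id=parts[1], chrom=parts[0], pos_bp=int(parts[2]),
                             allele_ref=parts[3], allele_alt=parts[4],
                             ancestral_state="unresolved"))
            cols.append(np.array(parts[5:], dtype=np.uint8))
    matrix = HaplotypeMatrix(pd.DataFrame(rows), np.stack(cols, axis=1),
                             list(sample_df["sample_id"].astype(str)),
                             list(sample_df["population"].astype(str)))
    matrix.validate()
    return matrix


def write_haps(matrix: HaplotypeMatrix, haps_path: str | Path,
               sample_path: str | Path) -> None:
    with open(haps_path, "w") as fh:
        for j, row in matrix.markers.iterrows():
            alleles = " ".join(str(a) for a in matrix.haplotypes[:, j])
            fh.write(f"{row.chrom} {row.marker_id} {row.pos_bp} "
                     f"{row.allele_ref} {row.allele_alt} {alleles}\n")
    pd.DataFrame({"sample_id": matrix.sample_ids,
                  "population": matrix.pop_labels}
                 ).to_csv(sample_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path,
                        allowed_groups: Optional[tuple] = DEFAULT_GROUPS
                        ) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "population", "group", "relatedness_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"population map lacks columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated sample_id in population map: {sorted(dup)}")
    if allowed_groups is not None:
        bad = sorted(set(df["group"]) - set(allowed_groups))
        if bad:
            raise ValueError(f"unknown group token(s) {bad}; "
                             f"allowed groups: {sorted(allowed_groups)}")
    bad_cls = sorted(set(df["relatedness_class"]) - set(RELATEDNESS_CLASSES))
    if bad_cls:
        raise ValueError(f"unknown relatedness_class {bad_cls}; "
                         f"allowed: {list(RELATEDNESS_CLASSES)}")
    return PopulationMap(df[required])


def read_outgroup_alleles(path: str | Path) -> pd.DataFrame:
    """Outgroup calls TSV: marker_id, then one allele column per outgroup.

    Missing calls are '.' or empty; alleles are nucleotide letters matching
    the marker's ref/alt.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    if "marker_id" not in df.columns or df.shape[1] < 2:
        raise ValueError("outgroup table needs marker_id plus >=1 outgroup column")
    return df


def write_outgroup_alleles(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval features
# ---------------------------------------------------------------------------

def read_features(path: str | Path, kind: str = "gene") -> FeatureSet:
    """Read BED (0-based half-open, as-is) or GFF3 (1-based inclusive, shifted).

    Format is autodetected from the extension (.bed vs .gff/.gff3). For SV
    features the interval length is recorded as sv_length_bp.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return _read_bed(path, kind)
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path, kind)
    raise ValueError(f"cannot autodetect format of {path} (expected .bed/.gff3)")


def _read_bed(path: Path, kind: str) -> FeatureSet:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start > end:
                raise ValueError(f"{path}: line {lineno}: start {start} > end {end}")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            feats.append(Feature(parts[0], start, end, name, kind,
                                 end - start if kind == "SV" else None))
    return FeatureSet(feats)


def _read_gff3(path: Path, kind: str) -> FeatureSet:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}: line {lineno}: fewer than 9 GFF3 fields")
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start1 > end1:
                raise ValueError(f"{path}: line {lineno}: start {start1} > end {end1}")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            name = attrs.get("Name") or attrs.get("ID") or f"{parts[0]}:{start1}-{end1}"
            start, end = start1 - 1, end1  # 1-based inclusive -> half-open
            feats.append(Feature(parts[0], start, end, name, kind,
                                 end - start if kind == "SV" else None))
    return FeatureSet(feats)


# ---------------------------------------------------------------------------
# regions and score tracks
# ---------------------------------------------------------------------------

def _method_tag(test: str, contrast: Optional[str]) -> str:
    return test if contrast in (None, "none") else f"{test}:{contrast}"


def _parse_method_tag(tag: str) -> tuple[str, Optional[str]]:
    if ":" in tag:
        test, contrast = tag.split(":", 1)
        return test, contrast
    return tag, None


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """BED4 with the supporting methods comma-joined in the name field."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tmethods\n")
        for r in regions.sorted():
            tags = ",".join(sorted(_method_tag(t, c) for t, c in r.methods))
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{tags}\n")


def read_regions(path: str | Path) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 BED fields")
            methods = frozenset(_parse_method_tag(t) for t in parts[3].split(","))
            regions.append(Region(parts[0], int(parts[1]), int(parts[2]), methods))
    return RegionSet(regions).sorted()


SCORE_COLUMNS = ["chrom", "pos_bp", "marker_id", "raw", "score", "mlog10p"]


def write_scores(track: ScoreTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# test={track.test} contrast={track.contrast or 'none'}\n")
        track.table[SCORE_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_scores(path: str | Path) -> ScoreTrack:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# test="):
            raise ValueError(f"{path}: missing score-track header line")
        fields = dict(kv.split("=", 1) for kv in header[2:].split())
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "marker_id": str})
    contrast = None if fields.get("contrast") == "none" else fields.get("contrast")
    return ScoreTrack(fields["test"], contrast, df[SCORE_COLUMNS])


# ---------------------------------------------------------------------------
# packaged fixtures of the published region table
# ---------------------------------------------------------------------------

@dataclass
class RegionTableFixture:
    """The published table of candidate sweep regions (48 intervals).

    Columns: test (iHS/Rsb/XPEHH), contrast (reference group or none), chrom,
    start_bp, end_bp, length_mb, genes (list of identifiers as printed).
    """

    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)

    def region_sets(self) -> dict[tuple[str, str], RegionSet]:
        """One RegionSet per (test, contrast)."""
        out = {}
        for (test, contrast), sub in self.rows.groupby(["test", "contrast"], sort=False):
            regs = [Region(str(r.chrom), int(r.start_bp), int(r.end_bp),
                           frozenset({(test, contrast)}))
                    for r in sub.itertuples()]
            out[(test, contrast)] = RegionSet(regs)
        return out

    def all_intervals(self) -> RegionSet:
        return RegionSet([r for rs in self.region_sets().values() for r in rs])


def load_region_table_fixture() -> RegionTableFixture:
    data = resources.files("sweepscan.data").joinpath("table1_regions.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _REGION_TABLE_SHA256:
        raise ValueError("packaged region-table fixture is corrupted "
                         f"(sha256 {digest} != {_REGION_TABLE_SHA256})")
    df = pd.read_csv(pd.io.common.BytesIO(data), sep="\t",
                     dtype={"chrom": str})
    df["genes"] = df["genes"].map(lambda s: s.split(","))
    for r in df.itertuples():
        if round(r.length_mb * 1e6) != r.end_bp - r.start_bp:
            raise ValueError(f"fixture row {r.Index}: length/interval mismatch")
    return RegionTableFixture(df)


def load_bayescan_support_fixture() -> RegionSet:
    """The two published regions whose support comes from the FST outlier arm."""
    data = resources.files("sweepscan.data").joinpath("table1_bayescan_support.tsv")
    df = pd.read_csv(data.open("r"), sep="\t", dtype={"chrom": str})
    return RegionSet([Region(str(r.chrom), int(r.start_bp), int(r.end_bp),
                             frozenset({(r.test, r.contrast)}))
                      for r in df.itertuples()])
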