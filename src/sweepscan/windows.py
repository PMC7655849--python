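"""Sliding-window region calling and multi-method consensus.

Per-marker -log10 p tracks are summarized over 1-Mb windows advancing on a
10-kb grid; a window is significant when it holds at least the per-test
minimum number of markers at -log10 p >= 3 (3 for iHS, 4 for Rsb and XP-EHH).
Overlapping significant windows merge into regions, whose bounds therefore
fall on the 10-kb grid with lengths of 1 Mb + k x 10 kb — the granularity of
the published region table. Consensus across methods is a transitive >= 1 bp
overlap merge keeping regions supported by at least ``min_methods`` distinct
tests.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .datatypes import (Feature, FeatureSet, Region, RegionSet, ScoreTrack,
                        _chrom_key)
from .io_formats import RegionTableFixture

WINDOW_SIZE_BP = 1_000_000
WINDOW_STEP_BP = 10_000
SIGNIFICANCE_THRESHOLD = 3.0
#: minimum markers over the threshold for a window to be called, per test
MIN_MARKERS = {"iHS": 3, "Rsb": 4, "XPEHH": 4}
MAX_SV_LENGTH_BP = 8_000_000  # SVs at or above this are ignored in annotation


@dataclass
class Window:
    chrom: str
    start_bp: int  # multiple of the window step
    end_bp: int  # start + window size
    n_significant: int = 0
    significant: bool = False


def make_windows(chrom_lengths: dict[str, int], size: int = WINDOW_SIZE_BP,
                 step: int = WINDOW_STEP_BP) -> list[Window]:
    """All fully on-chromosome windows [k*step, k*step + size)."""
    if size % step != 0:
        raise ValueError("window size must be a multiple of the step")
    out = []
    for chrom in sorted(chrom_lengths, key=_chrom_key):
        length = chrom_lengths[chrom]
        k = 0
        while k * step + size <= length:
            out.append(Window(chrom, k * step, k * step + size))
            k += 1
    return out


def classify_windows(windows: Sequence[Window], track: ScoreTrack,
                     threshold: float = SIGNIFICANCE_THRESHOLD,
                     min_markers: Optional[dict] = None) -> list[Window]:
    """Mark windows significant by the per-test marker-count rule.

    A marker counts when its -log10 p is >= threshold (inclusive); a window
    is significant when it holds at least min_markers[test] such markers.
    """
    min_markers = min_markers or MIN_MARKERS
    if track.test not in min_markers:
        raise ValueError(f"unknown test label {track.test!r}")
    need = min_markers[track.test]
    hits = track.table[track.table["mlog10p"] >= threshold]
    by_chrom = {chrom: np.sort(sub["pos_bp"].to_numpy())
                for chrom, sub in hits.groupby("chrom")}
    out = []
    for w in windows:
        pos = by_chrom.get(w.chrom)
        if pos is None:
            n = 0
        else:
            # marker at 1-based position p lies in half-open window [s, e)
            n = int(np.searchsorted(pos, w.end_bp, "right")
                    - np.searchsorted(pos, w.start_bp + 1, "left"))
        out.append(Window(w.chrom, w.start_bp, w.end_bp, n, n >= need))
    return out


def merge_windows_to_regions(windows: Iterable[Window], test: str,
                             contrast: Optional[str] = None) -> RegionSet:
    """Union overlapping/adjacent significant windows into regions."""
    tag = frozenset({(test, contrast if contrast is not None else "none")})
    sig = sorted((w for w in windows if w.significant),
                 key=lambda w: (_chrom_key(w.chrom), w.start_bp))
    regions: list[Region] = []
    for w in sig:
        if regions and regions[-1].chrom == w.chrom \
                and w.start_bp <= regions[-1].end_bp:
            last = regions.pop()
            regions.append(Region(last.chrom, last.start_bp,
                                  max(last.end_bp, w.end_bp), tag))
        else:
            regions.append(Region(w.chrom, w.start_bp, w.end_bp, tag))
    return RegionSet(regions)


def consensus_regions(region_sets: Sequence[RegionSet], min_methods: int = 2
                      ) -> RegionSet:
    """Transitive >= 1 bp overlap merge across methods.

    Merged regions carry the union of supporting (test, contrast) tags; only
    regions supported by >= min_methods distinct tests are kept. min_methods=1
    reduces to a plain interval union.
    """
    pool = sorted((r for rs in region_sets for r in rs),
                  key=lambda r: (_chrom_key(r.chrom), r.start_bp, r.end_bp))
    merged: list[Region] = []
    for r in pool:
        if merged and merged[-1].chrom == r.chrom \
                and r.start_bp < merged[-1].end_bp:  # >= 1 bp overlap
            last = merged.pop()
            merged.append(Region(last.chrom, last.start_bp,
                                 max(last.end_bp, r.end_bp),
                                 last.methods | r.methods))
        else:
            merged.append(r)
    return RegionSet([r for r in merged if r.n_support_methods >= min_methods])


def annotate_regions(regions: RegionSet, features: FeatureSet,
                     max_sv_length_bp: int = MAX_SV_LENGTH_BP
                     ) -> dict[Region, list[Feature]]:
    """Assign features overlapping each region by >= 1 bp (half-open).

    SV features as long as max_sv_length_bp or longer are excluded first —
    intervals that large are beyond what short-read SV callers resolve and
    would blanket every region.
    """
    usable = [f for f in features
              if not (f.kind == "SV" and f.sv_length_bp is not None
                      and f.sv_length_bp >= max_sv_length_bp)]
    trees: dict[str, IntervalTree] = {}
    for f in usable:
        if f.end_bp > f.start_bp:  # zero-length features can overlap nothing
            trees.setdefault(f.chrom, IntervalTree()).addi(f.start_bp, f.end_bp, f)
    out: dict[Region, list[Feature]] = {}
    for r in regions:
        hits = trees[r.chrom].overlap(r.start_bp, r.end_bp) if r.chrom in trees else ()
        out[r] = sorted((iv.data for iv in hits),
                        key=lambda f: (f.start_bp, f.end_bp, f.name))
    return out


def count_region_genes(fixture: RegionTableFixture, test: str) -> int:
    """Unique gene identifiers across the fixture rows of one test."""
    rows = fixture.rows[fixture.rows["test"] == test]
    if rows.empty:
        raise ValueError(f"unknown test {test!r}; fixture has "
                         f"{sorted(fixture.rows['test'].unique())}")
    return len({g for genes in rows["genes"] for g in genes if g})
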