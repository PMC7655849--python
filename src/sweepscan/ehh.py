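"""Extended haplotype homozygosity (EHH) statistics.

EHH at distance x from a core marker is the probability that two randomly
chosen haplotypes carrying the core allele are identical over the whole
interval between core and x. We use the unbiased pairwise form

    EHH = sum_h C(n_h, 2) / C(n_a, 2)

over the distinct extended haplotypes h among the n_a allele carriers.
Integrating EHH over physical distance gives iHH (per core allele) and iES
(allele-agnostic, per population); the three scan statistics are

    iHS    = ln(iHH_ancestral / iHH_derived), standardized within
             derived-allele-frequency bins;
    Rsb    = ln(iES_pop1 / iES_pop2), median-centred, sd-scaled;
    XP-EHH = ln(iES_pop1 / iES_pop2), mean-centred, sd-scaled;

each reported with the two-sided normal p-transform
-log10(1 - 2|Phi(score) - 0.5|).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .datatypes import HaplotypeMatrix, ScoreTrack

DEFAULT_MAX_GAP_BP = 500_000
DEFAULT_EHH_CUTOFF = 0.05


@dataclass
class EHHProfile:
    """EHH decay around one core marker, for one core allele.

    Each side starts at the core (EHH = 1) and extends outward marker by
    marker until the EHH cutoff, the chromosome end, or an inter-marker gap
    larger than the maximum allowed.
    """

    core_index: int
    core_pos: int
    allele: str  # ancestral | derived | all
    left_pos: np.ndarray  # absolute bp, core first, then outward (decreasing)
    left_ehh: np.ndarray
    right_pos: np.ndarray  # core first, then outward (increasing)
    right_ehh: np.ndarray
    truncation_left: str  # cutoff | chrom_end | maxgap
    truncation_right: str
    n_carriers: int

    @property
    def defined(self) -> bool:
        return self.n_carriers >= 2


def _pairwise_homozygosity(class_counts: np.ndarray, n: int) -> float:
    return float((class_counts * (class_counts - 1)).sum() / (n * (n - 1)))


def _extend(haps: np.ndarray, positions: np.ndarray, core: int, step: int,
            stop: int, max_gap_bp: int, ehh_cutoff: float):
    """Walk outward from the core refining haplotype classes."""
    n = haps.shape[0]
    pos_out = [int(positions[core])]
    ehh_out = [1.0]
    codes = np.zeros(n, dtype=np.int64)
    j = core
    reason = "chrom_end"
    while True:
        nxt = j + step
        if nxt == stop:
            break
        if abs(int(positions[nxt]) - int(positions[j])) > max_gap_bp:
            reason = "maxgap"
            break
        codes = np.unique(codes * 2 + haps[:, nxt], return_inverse=True)[1]
        counts = np.bincount(codes)
        ehh = _pairwise_homozygosity(counts, n)
        pos_out.append(int(positions[nxt]))
        ehh_out.append(ehh)
        j = nxt
        if ehh < ehh_cutoff:
            reason = "cutoff"
            break
    return np.array(pos_out), np.array(ehh_out), reason


def ehh_decay(matrix: HaplotypeMatrix, core_index: int, allele: str = "derived",
              max_gap_bp: int = DEFAULT_MAX_GAP_BP,
              ehh_cutoff: float = DEFAULT_EHH_CUTOFF) -> EHHProfile:
    """EHH profile around ``core_index`` for one core allele.

    The matrix must be polarized (0 = ancestral) for allele= ancestral/derived;
    allele="all" pools every haplotype, the building block of iES. With fewer
    than two carriers the profile is flagged undefined rather than raising.
    """
    if allele not in ("ancestral", "derived", "all"):
        raise ValueError(f"unknown allele selector {allele!r}")
    chrom = matrix.markers["chrom"].iloc[core_index]
    on_chrom = np.flatnonzero((matrix.markers["chrom"] == chrom).to_numpy())
    lo, hi = on_chrom[0], on_chrom[-1] + 1
    positions = matrix.positions()
    core_col = matrix.haplotypes[:, core_index]
    if allele == "all":
        carriers = np.arange(matrix.n_haplotypes)
    else:
        want = 1 if allele == "derived" else 0
        carriers = np.flatnonzero(core_col == want)
    core_pos = int(positions[core_index])
    if len(carriers) < 2:
        empty = np.array([core_pos]), np.array([1.0])
        return EHHProfile(core_index, core_pos, allele, empty[0], empty[1],
                          empty[0].copy(), empty[1].copy(),
                          "chrom_end", "chrom_end", len(carriers))
    haps = matrix.haplotypes[carriers]
    lpos, lehh, lreason = _extend(haps, positions, core_index, -1, lo - 1,
                                  max_gap_bp, ehh_cutoff)
    rpos, rehh, rreason = _extend(haps, positions, core_index, +1, hi,
                                  max_gap_bp, ehh_cutoff)
    return EHHProfile(core_index, core_pos, allele, lpos, lehh, rpos, rehh,
                      lreason, rreason, len(carriers))


def integrate_ihh(profile: EHHProfile) -> float:
    """Trapezoidal integral of EHH over physical distance, both sides summed.

    Returns NaN for undefined profiles (fewer than two allele carriers).
    """
    if not profile.defined:
        return float("nan")
    total = 0.0
    for pos, ehh in ((profile.left_pos, profile.left_ehh),
                     (profile.right_pos, profile.right_ehh)):
        if len(pos) > 1:
            dist = np.abs(pos.astype(np.int64) - profile.core_pos)
            total += float(np.trapezoid(ehh, dist))
    return total


# ---------------------------------------------------------------------------
# standardization and the p transform
# ---------------------------------------------------------------------------

def p_transform(score) -> np.ndarray | float:
    """-log10 of the two-sided normal tail, numerically stable.

    -log10(1 - 2|Phi(x) - 0.5|) = -log10(2 (1 - Phi(|x|))); computed via
    log_ndtr so very large |x| maps to large finite values.
    """
    x = np.abs(np.asarray(score, dtype=float))
    out = -(np.log(2.0) + log_ndtr(-x)) / np.log(10.0)
    out = np.maximum(out, 0.0)  # clip -0.0 from rounding at x = 0
    return out if out.ndim else float(out)


def _frequency_bins(freq: np.ndarray, n_bins: int, min_count: int) -> np.ndarray:
    """Assign derived-frequency bins, merging sparse bins with their right
    neighbour (left for the last bin) until every bin holds >= min_count."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(freq, edges[1:-1]), 0, n_bins - 1)
    labels = list(range(n_bins))
    while True:
        present = [b for b in labels if (idx == b).sum() > 0]
        small = [b for b in present if (idx == b).sum() < min_count]
        if not small or len(present) <= 1:
            break
        b = small[0]
        right = [c for c in present if c > b]
        target = min(right) if right else max(c for c in present if c < b)
        idx[idx == b] = target
    return idx


def ihs_scan(matrix: HaplotypeMatrix, max_gap_bp: int = DEFAULT_MAX_GAP_BP,
             ehh_cutoff: float = DEFAULT_EHH_CUTOFF, n_bins: int = 20,
             min_bin_count: int = 10) -> ScoreTrack:
    """Within-population iHS scan over every marker of a polarized matrix.

    raw = ln(iHH_ancestral / iHH_derived); markers where either iHH is zero
    or undefined are skipped. Standardization is to mean 0 / sd 1 within
    derived-allele-frequency bins.
    """
    raws, freqs, kept = [], [], []
    freq_all = matrix.derived_freq()
    for m in range(matrix.n_markers):
        ihh_a = integrate_ihh(ehh_decay(matrix, m, "ancestral", max_gap_bp, ehh_cutoff))
        ihh_d = integrate_ihh(ehh_decay(matrix, m, "derived", max_gap_bp, ehh_cutoff))
        if not np.isfinite(ihh_a) or not np.isfinite(ihh_d) \
                or ihh_a <= 0 or ihh_d <= 0:
            continue
        raws.append(np.log(ihh_a / ihh_d))
        freqs.append(freq_all[m])
        kept.append(m)
    raws = np.asarray(raws)
    freqs = np.asarray(freqs)
    scores = np.full_like(raws, np.nan)
    bins = _frequency_bins(freqs, n_bins, min_bin_count) if len(raws) else np.array([])
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = raws[sel].mean(), raws[sel].std()
        scores[sel] = (raws[sel] - mu) / sd if sd > 0 else 0.0
    sub = matrix.markers.iloc[kept]
    table = pd.DataFrame({"chrom": sub["chrom"].to_numpy(),
                          "pos_bp": sub["pos_bp"].to_numpy(),
                          "marker_id": sub["marker_id"].to_numpy(),
                          "raw": raws, "score": scores,
                          "mlog10p": p_transform(scores) if len(raws) else raws})
    return ScoreTrack("iHS", None, table,
                      standardization={"kind": "freq_bins", "n_bins": n_bins,
                                       "min_bin_count": min_bin_count})


def ies_scan(matrix: HaplotypeMatrix, max_gap_bp: int = DEFAULT_MAX_GAP_BP,
             ehh_cutoff: float = DEFAULT_EHH_CUTOFF) -> pd.DataFrame:
    """Allele-agnostic integrated EHH (iES) at every marker of one group."""
    ies = np.empty(matrix.n_markers)
    for m in range(matrix.n_markers):
        ies[m] = integrate_ihh(ehh_decay(matrix, m, "all", max_gap_bp, ehh_cutoff))
    return pd.DataFrame({"chrom": matrix.markers["chrom"].to_numpy(),
                         "pos_bp": matrix.markers["pos_bp"].to_numpy(),
                         "marker_id": matrix.markers["marker_id"].to_numpy(),
                         "ies": ies})


def _ies_log_ratio(ies_pop1: pd.DataFrame, ies_pop2: pd.DataFrame) -> pd.DataFrame:
    merged = ies_pop1.merge(ies_pop2, on=["chrom", "pos_bp", "marker_id"],
                            suffixes=("_1", "_2"), validate="one_to_one")
    ok = np.isfinite(merged["ies_1"]) & np.isfinite(merged["ies_2"]) \
        & (merged["ies_1"] > 0) & (merged["ies_2"] > 0)
    merged = merged[ok].reset_index(drop=True)
    merged["raw"] = np.log(merged["ies_1"] / merged["ies_2"])
    return merged


def _between_pop_track(test: str, center: str, ies_pop1: pd.DataFrame,
                       ies_pop2: pd.DataFrame, contrast: Optional[str]) -> ScoreTrack:
    merged = _ies_log_ratio(ies_pop1, ies_pop2)
    raw = merged["raw"].to_numpy()
    loc = np.median(raw) if center == "median" else raw.mean()
    sd = raw.std()
    score = (raw - loc) / sd if sd > 0 else np.zeros_like(raw)
    table = pd.DataFrame({"chrom": merged["chrom"], "pos_bp": merged["pos_bp"],
                          "marker_id": merged["marker_id"], "raw": raw,
                          "score": score, "mlog10p": p_transform(score)})
    return ScoreTrack(test, contrast, table,
                      standardization={"center": center, "location": float(loc),
                                       "sd": float(sd)})


def rsb_scan(ies_pop1: pd.DataFrame, ies_pop2: pd.DataFrame,
             contrast: Optional[str] = None, center: str = "median") -> ScoreTrack:
    """Rsb: standardized ln(iES_pop1 / iES_pop2), centred on the genome-wide
    median (the statistic's original description) and scaled by the sd."""
    return _between_pop_track("Rsb", center, ies_pop1, ies_pop2, contrast)


def xpehh_scan(ies_pop1: pd.DataFrame, ies_pop2: pd.DataFrame,
               contrast: Optional[str] = None, center: str = "mean") -> ScoreTrack:
    """XP-EHH: standardized ln(iES_pop1 / iES_pop2), mean/sd standardization."""
    return _between_pop_track("XPEHH", center, ies_pop1, ies_pop2, contrast)
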