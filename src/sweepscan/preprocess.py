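"""Marker and sample filters applied ahead of the haplotype scans.

The chain mirrors standard SNP-chip practice: relatedness removal (PI-HAT),
MAF filter, windowed-r2 LD pruning, ancestral-allele polarization by outgroup
majority, and haplotype pooling by ancestry group. A Weir-Cockerham theta
estimator is included to validate the synthetic allele-count generator.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import AlleleCountMatrix, HaplotypeMatrix, PopulationMap

#: PI-HAT removal thresholds per relatedness class. Commercial breeds use the
#: conventional 0.25 (closer than grandparent-grandchild); populations bred by
#: natural service are generally less inbred, hence the stricter 0.1.
PI_HAT_THRESHOLDS = {"commercial": 0.25, "north_african": 0.1}


@dataclass
class FilterReport:
    stage: str
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed_markers: list = field(default_factory=list)  # (marker_id, reason)
    removed_samples: list = field(default_factory=list)  # dicts
    notes: list = field(default_factory=list)

    def reconciles(self) -> bool:
        return (self.n_markers_in == self.n_markers_out + len(self.removed_markers)
                and self.n_samples_in == self.n_samples_out + len(self.removed_samples))

    def to_dict(self) -> dict:
        return {"stage": self.stage,
                "n_markers_in": self.n_markers_in, "n_markers_out": self.n_markers_out,
                "n_samples_in": self.n_samples_in, "n_samples_out": self.n_samples_out,
                "removed_markers": [list(t) for t in self.removed_markers],
                "removed_samples": self.removed_samples,
                "notes": list(self.notes)}


# ---------------------------------------------------------------------------
# marker filters
# ---------------------------------------------------------------------------

def maf_filter(matrix: HaplotypeMatrix, threshold: float = 0.05
               ) -> tuple[HaplotypeMatrix, FilterReport]:
    """Remove markers with minor-allele frequency strictly below ``threshold``
    (a marker at exactly the threshold is retained)."""
    freq = matrix.derived_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= threshold
    report = FilterReport("maf", n_markers_in=matrix.n_markers,
                          n_markers_out=int(keep.sum()),
                          n_samples_in=matrix.n_samples,
                          n_samples_out=matrix.n_samples)
    ids = matrix.markers["marker_id"]
    report.removed_markers = [(ids.iloc[i], "maf") for i in np.flatnonzero(~keep)]
    return matrix.subset_markers(np.flatnonzero(keep)), report


def _dosage_r2(dosage: np.ndarray, i: int, j: int) -> float:
    """Squared Pearson correlation of diploid dosages; 0 if either is constant."""
    x, y = dosage[:, i].astype(float), dosage[:, j].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(((x - x.mean()) @ (y - y.mean()) / (len(x) * sx * sy)) ** 2)


def ld_prune(matrix: HaplotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.5) -> tuple[HaplotypeMatrix, FilterReport]:
    """Windowed LD pruning on diploid dosages.

    Windows of ``window`` consecutive retained markers start at multiples of
    ``step``. Whenever a window holds a pair with dosage r2 > r2_max, the
    lower-MAF member is removed (tie: the later position); scanning restarts
    at the first window that could be affected and repeats to a fixpoint, so
    the result contains no violating pair in any window. Marker order is
    preserved.
    """
    if window < 2:
        raise ValueError("window must cover at least 2 markers")
    dosage = matrix.dosage()
    freq = matrix.derived_freq()
    maf = np.minimum(freq, 1.0 - freq)
    kept = list(range(matrix.n_markers))
    removed: list[int] = []

    w = 0  # window start within the kept list
    while w < max(len(kept) - 1, 1):
        members = kept[w:w + window]
        dropped = None
        for a, b in itertools.combinations(range(len(members)), 2):
            i, j = members[a], members[b]
            if _dosage_r2(dosage, i, j) > r2_max:
                if maf[i] < maf[j]:
                    dropped = i
                elif maf[j] < maf[i]:
                    dropped = j
                else:  # tie -> later position removed
                    dropped = j
                break
        if dropped is None:
            w += step
            continue
        kept.remove(dropped)
        removed.append(dropped)
        # removal only disturbs windows overlapping the removal point
        w = max(0, w - window)
        w -= w % step
    removed.sort()
    report = FilterReport("ld", n_markers_in=matrix.n_markers,
                          n_markers_out=len(kept),
                          n_samples_in=matrix.n_samples,
                          n_samples_out=matrix.n_samples)
    ids = matrix.markers["marker_id"]
    report.removed_markers = [(ids.iloc[i], "ld") for i in removed]
    return matrix.subset_markers(np.array(kept, dtype=int)), report


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

@dataclass
class KinshipEstimate:
    sample_a: str
    sample_b: str
    ibs_counts: tuple  # (IBS0, IBS1, IBS2)
    p_ibd: tuple  # (P0, P1, P2) on the simplex
    pi_hat: float
    low_information: bool = False  # fewer than 50 informative markers


def estimate_pi_hat(matrix: HaplotypeMatrix,
                    allele_freqs: Optional[np.ndarray] = None,
                    pairs: Optional[Sequence[tuple[str, str]]] = None
                    ) -> list[KinshipEstimate]:
    """Method-of-moments IBD sharing (PI-HAT) for sample pairs.

    Observed IBS0/1/2 counts are equated to their expectations given the IBD
    state and the allele frequencies; the resulting probabilities are
    truncated to the simplex and PI-HAT = P(IBD=1)/2 + P(IBD=2).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dosage = matrix.dosage()
    p = matrix.derived_freq() if allele_freqs is None else np.asarray(allele_freqs)
    informative = (p > 0) & (p < 1)
    p = p[informative]
    q = 1.0 - p
    dosage = dosage[:, informative]
    low_info = informative.sum() < 50

    # per-marker IBS-state expectations given IBD state, summed over markers
    e0_ibd0 = float((2 * p**2 * q**2).sum())
    e1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e2_ibd0 = informative.sum() - e0_ibd0 - e1_ibd0
    e1_ibd1 = float((2 * p**2 * q + 2 * p * q**2).sum())
    e2_ibd1 = informative.sum() - e1_ibd1
    n_mark = int(informative.sum())

    index = {s: i for i, s in enumerate(matrix.sample_ids)}
    if pairs is None:
        pairs = list(itertools.combinations(matrix.sample_ids, 2))
    out = []
    for sa, sb in pairs:
        d = np.abs(dosage[index[sa]] - dosage[index[sb]])
        n0, n1, n2 = int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())
        p0 = n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
        p1 = (n1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
        p2 = (n2 - p0 * e2_ibd0 - p1 * e2_ibd1) / n_mark if n_mark else 0.0
        probs = np.clip([p0, p1, p2], 0.0, 1.0)
        total = probs.sum()
        probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
        pi_hat = float(np.clip(probs[1] / 2 + probs[2], 0.0, 1.0))
        out.append(KinshipEstimate(sa, sb, (n0, n1, n2), tuple(probs), pi_hat,
                                   low_information=low_info))
    return out


def relatedness_filter(estimates: Sequence[KinshipEstimate],
                       population_map: PopulationMap,
                       thresholds: Optional[dict] = None
                       ) -> tuple[list[str], FilterReport]:
    """Drop one member of every within-population pair over its PI-HAT limit.

    The limit is the relatedness class's threshold (commercial 0.25, local
    0.1). Iteratively the sample with the most over-threshold partners is
    removed (tie: the later sample id), maximizing retained samples.
    """
    thresholds = thresholds or PI_HAT_THRESHOLDS
    samples = sorted({s for e in estimates for s in (e.sample_a, e.sample_b)})

    def limit(sample: str) -> float:
        return thresholds[population_map.relatedness_class_of(sample)]

    over = []
    for e in estimates:
        if population_map.population_of(e.sample_a) != \
                population_map.population_of(e.sample_b):
            continue
        if e.pi_hat > min(limit(e.sample_a), limit(e.sample_b)):
            over.append(e)

    removed: list[dict] = []
    active = set(samples)
    while True:
        live = [e for e in over
                if e.sample_a in active and e.sample_b in active]
        if not live:
            break
        degree: dict[str, int] = {}
        for e in live:
            degree[e.sample_a] = degree.get(e.sample_a, 0) + 1
            degree[e.sample_b] = degree.get(e.sample_b, 0) + 1
        top = max(degree.values())
        victim = max(s for s, d in degree.items() if d == top)  # tie: later id
        active.discard(victim)
        partners = [e for e in live if victim in (e.sample_a, e.sample_b)]
        removed.append({"sample_id": victim,
                        "max_pi_hat": max(e.pi_hat for e in partners),
                        "n_partners": len(partners)})
    kept = [s for s in samples if s in active]
    report = FilterReport("relatedness", n_samples_in=len(samples),
                          n_samples_out=len(kept), removed_samples=removed)
    return kept, report


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

def infer_ancestral(matrix: HaplotypeMatrix, outgroup_alleles: pd.DataFrame
                    ) -> tuple[HaplotypeMatrix, FilterReport]:
    """Polarize by strict outgroup majority.

    The ancestral allele is the most common call among the non-missing
    outgroup calls, requiring at least two concordant calls and a strict
    majority; otherwise the marker is removed (reason unresolved_ancestral).
    Calls matching neither marker allele are treated as missing and logged.
    After polarization haplotype code 0 is the ancestral allele everywhere.
    """
    og = outgroup_alleles.set_index("marker_id")
    call_cols = [c for c in og.columns]
    report = FilterReport("polarize", n_markers_in=matrix.n_markers,
                          n_samples_in=matrix.n_samples,
                          n_samples_out=matrix.n_samples)
    keep_idx, flip_idx = [], []
    states = []
    for m, row in enumerate(matrix.markers.itertuples()):
        ref, alt = row.allele_ref, row.allele_alt
        calls = []
        if row.marker_id in og.index:
            for c in call_cols:
                call = str(og.loc[row.marker_id, c])
                if call in (ref, alt):
                    calls.append(call)
                elif call not in (".", "nan", ""):
                    report.notes.append(
                        f"{row.marker_id}: outgroup call {call!r} matches "
                        f"neither allele; treated as missing")
        n_ref = sum(c == ref for c in calls)
        n_alt = len(calls) - n_ref
        if len(calls) >= 2 and n_ref != n_alt:
            ancestral = "ref" if n_ref > n_alt else "alt"
            keep_idx.append(m)
            states.append(ancestral)
            if ancestral == "alt":
                flip_idx.append(m)
        else:
            report.removed_markers.append((row.marker_id, "unresolved_ancestral"))
    haps = matrix.haplotypes.copy()
    if flip_idx:
        haps[:, flip_idx] = 1 - haps[:, flip_idx]
    markers = matrix.markers.copy()
    markers.loc[keep_idx, "ancestral_state"] = states
    polarized = HaplotypeMatrix(markers, haps, list(matrix.sample_ids),
                                list(matrix.pop_labels)).subset_markers(
                                    np.array(keep_idx, dtype=int))
    report.n_markers_out = polarized.n_markers
    return polarized, report


def pool_haplotypes(matrix: HaplotypeMatrix, population_map: PopulationMap,
                    group: str) -> HaplotypeMatrix:
    """Concatenate the haplotypes of every population in an ancestry group."""
    pops = population_map.populations_in_group(group)
    pooled = matrix.for_populations(pops)
    if pooled.n_samples == 0:
        raise ValueError(f"group {group!r} has no samples in the matrix")
    return pooled


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    theta: np.ndarray  # per locus; NaN where monomorphic across populations
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    multi_locus: float  # ratio of sums over informative loci


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir-Cockerham variance components for one biallelic locus.

    n: individuals sampled per population; p: allele frequency per population;
    h: observed heterozygote proportion per population (zeros for haploid
    chromosome counts, where n counts chromosomes).
    """
    r = len(n)
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def weir_cockerham_fst(data: AlleleCountMatrix | HaplotypeMatrix,
                       pops: Optional[Sequence[str]] = None) -> FstResult:
    """Weir-Cockerham theta per locus and as a multi-locus ratio of sums.

    Accepts either per-population chromosome counts (haploid components,
    heterozygosity term zero) or a haplotype matrix, in which case diploid
    genotypes are reconstituted from consecutive haplotype pairs and the
    heterozygosity term enters the components. Loci monomorphic across the
    chosen populations are excluded from the sums.
    """
    if isinstance(data, AlleleCountMatrix):
        cols = (list(range(data.n_pops)) if pops is None
                else [data.pop_ids.index(p) for p in pops])
        if len(cols) < 2:
            raise ValueError("need at least two populations")
        derived = data.derived[:, cols].astype(float)
        total = data.total[:, cols].astype(float)
        if (total < 2).any():
            raise ValueError("need >= 2 sampled chromosomes per population")
        n_loci = data.n_loci
        ns = total
        ps = derived / total
        hs = np.zeros_like(ps)
    else:
        labels = np.asarray(data.pop_labels)
        pops = sorted(set(labels)) if pops is None else list(pops)
        if len(pops) < 2:
            raise ValueError("need at least two populations")
        dosage = data.dosage()
        n_loci = data.n_markers
        ns = np.empty((n_loci, len(pops)))
        ps = np.empty_like(ns)
        hs = np.empty_like(ns)
        for k, pop in enumerate(pops):
            sel = labels == pop
            if sel.sum() < 1:
                raise ValueError(f"population {pop!r} absent from matrix")
            d = dosage[sel]
            ns[:, k] = sel.sum()
            ps[:, k] = d.mean(axis=0) / 2.0
            hs[:, k] = (d == 1).mean(axis=0)

    a = np.full(n_loci, np.nan)
    b = np.full(n_loci, np.nan)
    c = np.full(n_loci, np.nan)
    theta = np.full(n_loci, np.nan)
    for i in range(n_loci):
        pbar_raw = (ns[i] * ps[i]).sum() / ns[i].sum()
        if pbar_raw in (0.0, 1.0):
            continue  # monomorphic across populations
        ai, bi, ci = _wc_components(ns[i], ps[i], hs[i])
        a[i], b[i], c[i] = ai, bi, ci
        denom = ai + bi + ci
        theta[i] = ai / denom if denom != 0 else np.nan
    ok = np.isfinite(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    multi = float(a[ok].sum() / denom) if ok.any() and denom != 0 else float("nan")
    return FstResult(theta, a, b, c, multi)
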