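"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's class-refinement / sweep-line code
paths: EHH is computed by direct pairwise haplotype comparison, integrals by
explicit trapezoid sums, window classification by a double loop, and interval
consensus by union-find over the pairwise overlap graph.
"""
from __future__ import annotations

import numpy as np


def brute_ehh_profile(haps: np.ndarray, positions: np.ndarray, core: int,
                      carriers: np.ndarray, max_gap_bp: int, cutoff: float):
    """EHH outward from core by explicit pair enumeration.

    Returns (left_pos, left_ehh, right_pos, right_ehh) with the core first in
    each direction, mirroring the package profile layout.
    """
    n = len(carriers)
    sub = haps[carriers]

    def side(step, stop):
        pos_out = [int(positions[core])]
        ehh_out = [1.0]
        j = core
        while True:
            nxt = j + step
            if nxt == stop:
                break
            if abs(int(positions[nxt]) - int(positions[j])) > max_gap_bp:
                break
            # identity over the extension excluding the core column itself
            # (for single-allele carriers the core column is constant anyway)
            lo, hi = (nxt, core - 1) if step < 0 else (core + 1, nxt)
            same = 0
            for a in range(n):
                for b in range(a + 1, n):
                    if np.array_equal(sub[a, lo:hi + 1], sub[b, lo:hi + 1]):
                        same += 1
            ehh = same / (n * (n - 1) / 2)
            pos_out.append(int(positions[nxt]))
            ehh_out.append(ehh)
            j = nxt
            if ehh < cutoff:
                break
        return np.array(pos_out), np.array(ehh_out)

    lp, le = side(-1, -1)
    rp, re_ = side(+1, haps.shape[1])
    return lp, le, rp, re_


def brute_integrate(pos: np.ndarray, ehh: np.ndarray, core_pos: int) -> float:
    """Explicit trapezoid sum over one side of a profile."""
    total = 0.0
    for i in range(1, len(pos)):
        d0 = abs(int(pos[i - 1]) - core_pos)
        d1 = abs(int(pos[i]) - core_pos)
        total += 0.5 * (ehh[i - 1] + ehh[i]) * (d1 - d0)
    return total


def brute_classify(positions: np.ndarray, mlog10p: np.ndarray,
                   win_start: int, win_end: int, threshold: float,
                   min_markers: int) -> tuple[int, bool]:
    n = 0
    for p, v in zip(positions, mlog10p):
        if win_start + 1 <= p <= win_end and v >= threshold:
            n += 1
    return n, n >= min_markers


def brute_consensus(intervals, min_methods: int):
    """Union-find transitive merge of (chrom, start, end, test) intervals.

    Returns a sorted list of (chrom, start, end, frozenset_of_tests) for
    components supported by >= min_methods distinct tests.
    """
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            ci, si, ei, _ = intervals[i]
            cj, sj, ej, _ = intervals[j]
            if ci == cj and si < ej and sj < ei:
                union(i, j)
    comps: dict[int, list] = {}
    for i in range(len(intervals)):
        comps.setdefault(find(i), []).append(intervals[i])
    out = []
    for members in comps.values():
        chrom = members[0][0]
        start = min(m[1] for m in members)
        end = max(m[2] for m in members)
        tests = frozenset(m[3] for m in members)
        if len(tests) >= min_methods:
            out.append((chrom, start, end, tests))
    return sorted(out)


def wc_theta_two_pops(n1, n2, p1, p2, h1, h2):
    """Weir-Cockerham components for one locus, two populations, written out
    term by term from the published component formulas."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                     / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c
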