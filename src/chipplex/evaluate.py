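"""Peak-set comparison statistics and gene-level annotation.

Percent overlap of X in Y is |{x in X : x touches some y}| / |X| — at least
one shared base under half-open interval arithmetic, and asymmetric by
definition.  Peaks annotate to a gene when they come within ``flank`` bases
(default 1 kb) of its transcription start or end site.  Gene recovery and the
lost-peak report quantify what a shallower (more multiplexed) library retains
of the deep reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import AnnotationParams, GeneModel, Peak


@dataclass(frozen=True)
class OverlapResult:
    n_x: int
    n_y: int
    n_x_overlapping: int
    percent_overlap_of_x: float  # NaN when X is empty


def _check_sorted_disjoint(peaks: Sequence[Peak], label: str) -> None:
    prev: Peak | None = None
    for p in peaks:
        if prev is not None and prev.chrom == p.chrom:
            if p.start < prev.start or p.start < prev.end:
                raise ValueError(f"{label} peaks must be sorted and non-overlapping")
        prev = p


def _by_chrom(peaks: Sequence[Peak]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, list[list[int]]] = {}
    for p in peaks:
        out.setdefault(p.chrom, [[], []])
        out[p.chrom][0].append(p.start)
        out[p.chrom][1].append(p.end)
    return {
        c: (np.array(s, dtype=np.int64), np.array(e, dtype=np.int64))
        for c, (s, e) in out.items()
    }


def percent_overlap(x: Sequence[Peak], y: Sequence[Peak]) -> OverlapResult:
    """Fraction of X's peaks with >= 1 base of overlap in Y.

    [a, b) and [c, d) intersect iff a < d and c < b; a peak of X counts once
    no matter how many Y peaks it touches.  Both sets must be sorted and
    internally non-overlapping.
    """
    _check_sorted_disjoint(x, "X")
    _check_sorted_disjoint(y, "Y")
    ychrom = _by_chrom(y)
    hit = 0
    for p in x:
        if p.chrom not in ychrom:
            continue
        ys, ye = ychrom[p.chrom]
        # first Y interval ending after p.start; overlap iff it starts before p.end
        j = int(np.searchsorted(ye, p.start, side="right"))
        if j < len(ys) and ys[j] < p.end:
            hit += 1
    pct = 100.0 * hit / len(x) if x else math.nan
    return OverlapResult(len(x), len(y), hit, pct)


def pairwise_overlap_matrix(peak_sets: Mapping[str, Sequence[Peak]]) -> pd.DataFrame:
    """Entry (i, j) = percent overlap of set i in set j; diagonal 100."""
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    names = list(peak_sets)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            if a == b:
                mat.loc[a, b] = 100.0
            else:
                mat.loc[a, b] = percent_overlap(peak_sets[a], peak_sets[b]).percent_overlap_of_x
    return mat


@dataclass(frozen=True)
class ApexShift:
    """Signed apex displacements of matched query peaks vs their reference."""

    shifts: np.ndarray  # query apex - reference apex, one per matched pair
    threshold: float
    fraction_within: float | None  # None when nothing matched

    @property
    def n_matched(self) -> int:
        return len(self.shifts)


def apex_shift_distribution(
    reference: Sequence[Peak],
    query: Sequence[Peak],
    threshold: float | None = None,
) -> ApexShift:
    """Match each query peak to the reference peak it overlaps most.

    The default concordance threshold is the reference median peak width (the
    natural "within one peak size" yardstick); ties in overlap break to the
    leftmost reference peak.
    """
    if threshold is None:
        if not reference:
            raise ValueError("cannot derive threshold from an empty reference")
        threshold = float(np.median([p.width for p in reference]))
    ref_by_chrom: dict[str, list[Peak]] = {}
    for p in reference:
        ref_by_chrom.setdefault(p.chrom, []).append(p)
    shifts: list[int] = []
    for q in query:
        best: Peak | None = None
        best_ov = 0
        for r in ref_by_chrom.get(q.chrom, ()):
            ov = min(q.end, r.end) - max(q.start, r.start)
            if ov > best_ov:  # strict: ties keep the leftmost (earlier) peak
                best_ov, best = ov, r
        if best is not None:
            shifts.append(q.apex - best.apex)
    arr = np.array(shifts, dtype=np.int64)
    frac = float(np.mean(np.abs(arr) <= threshold)) if len(arr) else None
    return ApexShift(arr, float(threshold), frac)


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
) -> tuple[dict[str, list[Peak]], set[str]]:
    """Assign peaks to genes within ``flank`` bases of a TSS or TES.

    The flank window is the closed interval [site − flank, site + flank],
    clipped at zero; a peak intersecting either window annotates the gene.  A
    peak may annotate several genes; a gene counts once however many peaks
    hit it.  Returns (gene_id → peaks, annotated gene id set).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        t = trees.setdefault(g.chrom, IntervalTree())
        for site in {g.tss, g.tes}:
            lo = max(0, site - params.flank)
            hi = site + params.flank + 1  # closed window in half-open coordinates
            t.addi(lo, hi, g.gene_id)
    assignment: dict[str, list[Peak]] = {}
    for p in peaks:
        t = trees.get(p.chrom)
        if t is None:
            continue
        for gid in {iv.data for iv in t.overlap(p.start, p.end)}:
            assignment.setdefault(gid, []).append(p)
    return assignment, set(assignment)


def interval_recovery(
    regions: Sequence[tuple[str, int, int]], peaks: Sequence[Peak]
) -> float:
    """Percent of arbitrary regions touched (>= 1 bp) by any called peak.

    Unlike :func:`percent_overlap` the regions need not be disjoint — handy
    for scoring called peaks against simulator ground truth.
    """
    if not regions:
        return math.nan
    bychrom = _by_chrom(sorted(peaks, key=lambda p: (p.chrom, p.start)))
    hit = 0
    for chrom, start, end in regions:
        if chrom not in bychrom:
            continue
        ys, ye = bychrom[chrom]
        j = int(np.searchsorted(ye, start, side="right"))
        if j < len(ys) and ys[j] < end:
            hit += 1
    return 100.0 * hit / len(regions)


def gene_recovery(reference_genes: Iterable[str], query_genes: Iterable[str]) -> float | None:
    """Percent of the reference gene set present in the query; None if empty."""
    ref = set(reference_genes)
    if not ref:
        return None
    return 100.0 * len(ref & set(query_genes)) / len(ref)


@dataclass(frozen=True)
class LostPeakReport:
    """Per lost gene: its best reference peak and that peak's quartiles.

    Quartile placement uses the empirical CDF of the best-peak distribution
    across all reference genes: quartile = ceil(4 * ecdf) in {1, .., 4}.
    Low p-value quartile 1 = most significant peaks.
    """

    table: pd.DataFrame  # gene_id, p_value, width, p_quartile, width_quartile
    n_reference_genes: int

    @property
    def lost_genes(self) -> set[str]:
        return set(self.table["gene_id"])


def _quartile(values: np.ndarray, pool: np.ndarray) -> np.ndarray:
    ecdf = np.searchsorted(np.sort(pool), values, side="right") / len(pool)
    return np.ceil(4.0 * ecdf).astype(int).clip(1, 4)


def lost_peak_characteristics(
    reference_annotation: Mapping[str, Sequence[Peak]],
    query_genes: Iterable[str],
) -> LostPeakReport:
    """Characterise the reference genes a shallower library failed to recover.

    For each lost gene, take its most significant (minimum p) reference peak
    and place that peak's p-value and width within the reference-wide
    best-peak distributions.  P-value ranking uses the exact −log10(p) so
    peaks whose p underflowed double precision are still discriminated; the
    p-quartile is the quartile of p itself (quartile 4 = least significant).
    """
    query = set(query_genes)
    best = {
        gid: min(pks, key=lambda p: (-p.neg_log10_p, p.start))
        for gid, pks in reference_annotation.items()
    }
    # -neg_log10_p orders identically to p but never saturates.
    pool_p = np.array([-p.neg_log10_p for p in best.values()])
    pool_w = np.array([p.width for p in best.values()])
    lost = sorted(set(best) - query)
    rows = []
    if lost:
        pvals = np.array([best[g].p_value for g in lost])
        widths = np.array([best[g].width for g in lost])
        pq = _quartile(np.array([-best[g].neg_log10_p for g in lost]), pool_p)
        wq = _quartile(widths, pool_w)
        rows = [
            {
                "gene_id": g,
                "p_value": float(pv),
                "width": int(w),
                "p_quartile": int(q1),
                "width_quartile": int(q2),
            }
            for g, pv, w, q1, q2 in zip(lost, pvals, widths, pq, wq)
        ]
    table = pd.DataFrame(rows, columns=["gene_id", "p_value", "width", "p_quartile", "width_quartile"])
    return LostPeakReport(table=table, n_reference_genes=len(best))
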