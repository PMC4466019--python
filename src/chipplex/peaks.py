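"""Window-scan Poisson peak caller with an input control, plus swap FDR.

The model: extend every usable read to the expected fragment length from its
5' end, tile each chromosome into fixed windows, and test the number of IP
fragments overlapping each window against a Poisson null whose mean is the
depth-scaled input count in the same window, floored by the genome-wide IP
fragment rate (a pseudo-background that guards sparse-input windows).
Significant windows within ``merge_gap`` of each other merge into candidate
regions; each region is re-tested on its total counts and kept only if it
passes the significance threshold (default 1e-15), the minimum IP/input fold
(default 2), and a minimum width.  The apex is the leftmost position of
maximal IP fragment coverage inside the region.

The empirical false discovery rate swaps the roles of IP and input: peaks
"called" from the input against the IP are enriched in the control and are
counted as false calls relative to the forward peak count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import CallerParams, Genome, Peak, ReadSet


class CoverageTrack:
    """Per-chromosome fragment coverage (count per base)."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self.cov: dict[str, np.ndarray] = {
            name: np.zeros(length, dtype=np.int32) for name, length in genome.chroms
        }

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.cov[chrom]

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.cov.values()))


def fragment_intervals(
    reads: ReadSet, genome: Genome, fragment_length: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Clipped fragment [start, end) per chromosome, each array sorted.

    A '+' read extends to [start, start + L); a '−' read extends back from
    its 5' end to [end − L, end); both clipped at chromosome bounds.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    fstart_all = np.where(reads.strand_plus, reads.start, reads.end - fragment_length)
    fend_all = np.where(reads.strand_plus, reads.start + fragment_length, reads.end)
    for ci, (name, length) in enumerate(genome.chroms):
        m = reads.chrom_code == ci
        s = np.clip(fstart_all[m], 0, length)
        e = np.clip(fend_all[m], 0, length)
        out[name] = (np.sort(s), np.sort(e))
    return out


def extend_and_cover(reads: ReadSet, genome: Genome, fragment_length: int) -> CoverageTrack:
    """Fragment-extension coverage; total mass equals the clipped fragment bases."""
    track = CoverageTrack(genome)
    frags = fragment_intervals(reads, genome, fragment_length)
    for name, length in genome.chroms:
        s, e = frags[name]
        if len(s) == 0:
            continue
        diff = np.bincount(s, minlength=length + 1).astype(np.int32)
        diff -= np.bincount(e, minlength=length + 1).astype(np.int32)
        track.cov[name] = np.cumsum(diff[:length], dtype=np.int32)
    return track


def _count_overlapping(
    sorted_starts: np.ndarray, sorted_ends: np.ndarray, lo, hi
) -> np.ndarray:
    """Fragments [s, e) intersecting [lo, hi): s < hi and e > lo."""
    return np.searchsorted(sorted_starts, hi, side="left") - np.searchsorted(
        sorted_ends, lo, side="right"
    )


def poisson_upper_tail(k, lam) -> np.ndarray:
    """P(X >= k) for X ~ Poisson(lam); 1 when k <= 0 (vectorised)."""
    k = np.asarray(k)
    lam = np.asarray(lam, dtype=float)
    p = stats.poisson.sf(k - 1, lam)
    return np.where(k <= 0, 1.0, p)


def poisson_log_tail(k: int, lam: float) -> float:
    """Natural log of P(X >= k); stays finite far past double underflow.

    In the moderate regime this is log(sf).  Deep in the upper tail (where
    sf underflows, necessarily k >> lam) the tail is summed as
    pmf(k) * (1 + lam/(k+1) + lam^2/((k+1)(k+2)) + ...) on the log scale;
    the ratio series converges geometrically since lam/(k+1) < 1 there.
    """
    if k <= 0:
        return 0.0
    s = float(stats.poisson.sf(k - 1, lam))
    if s > 1e-280:
        return float(np.log(s))
    total, term, j = 1.0, 1.0, k + 1
    while True:
        term *= lam / j
        total += term
        j += 1
        if term < 1e-17 * total:
            break
    return float(stats.poisson.logpmf(k, lam) + np.log(total))


def window_test(
    ip_count: int,
    input_count: int,
    depth_ratio: float,
    genome_rate: float,
    span: int,
) -> float:
    """Poisson upper-tail test of an IP count against scaled input.

    lambda = max(input_count * depth_ratio, genome_rate * span) where
    ``genome_rate`` is the genome-wide IP fragment rate per base and ``span``
    the tested width (window plus fragment allowance).  Returns 1 when
    ip_count = 0.
    """
    if depth_ratio <= 0:
        raise ValueError("depth_ratio must be positive")
    if ip_count == 0:
        return 1.0
    lam = max(input_count * depth_ratio, genome_rate * span)
    if lam <= 0:
        return 0.0
    p = float(stats.poisson.sf(ip_count - 1, lam))
    if p < 1e-280:  # sf loses the deep tail; recover it on the log scale
        p = float(np.exp(poisson_log_tail(ip_count, lam)))
    return p


def _merge_windows(win_start: np.ndarray, win_end: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Merge sorted significant windows separated by <= gap."""
    regions: list[tuple[int, int]] = []
    cs, ce = int(win_start[0]), int(win_end[0])
    for s, e in zip(win_start[1:], win_end[1:]):
        if s - ce <= gap:
            ce = int(e)
        else:
            regions.append((cs, ce))
            cs, ce = int(s), int(e)
    regions.append((cs, ce))
    return regions


def call_peaks(
    ip_reads: ReadSet,
    input_reads: ReadSet,
    genome: Genome,
    params: CallerParams = CallerParams(),
) -> list[Peak]:
    """Call enriched intervals in IP relative to input.

    Deterministic: no randomness anywhere in the scan.  Returned peaks are
    sorted in genome order and mutually non-overlapping, each containing at
    least one window that passed the per-window test.
    """
    if len(ip_reads) == 0 or len(input_reads) == 0:
        raise ValueError(
            "peak calling requires both IP and input reads; input-free mode is unsupported"
        )
    depth_ratio = len(ip_reads) / len(input_reads)
    genome_rate = len(ip_reads) / genome.total_length  # fragments per base
    lf = params.fragment_length
    ip_frags = fragment_intervals(ip_reads, genome, lf)
    input_frags = fragment_intervals(input_reads, genome, lf)

    peaks: list[Peak] = []
    for name, length in genome.chroms:
        ips, ipe = ip_frags[name]
        if len(ips) == 0:
            continue
        ins, ine = input_frags[name]
        w_lo = np.arange(0, length, params.window, dtype=np.int64)
        w_hi = np.minimum(w_lo + params.window, length)
        ip_n = _count_overlapping(ips, ipe, w_lo, w_hi)
        in_n = _count_overlapping(ins, ine, w_lo, w_hi)
        lam = np.maximum(in_n * depth_ratio, genome_rate * (w_hi - w_lo + lf))
        pvals = poisson_upper_tail(ip_n, lam)
        sig = (pvals <= params.p_threshold) & (ip_n > 0)
        if not sig.any():
            continue
        regions = _merge_windows(w_lo[sig], w_hi[sig], params.merge_gap)

        cov = None  # built lazily, only for chromosomes with candidates
        for rs, re in regions:
            width = re - rs
            if width < params.min_width:
                continue
            ip_r = int(_count_overlapping(ips, ipe, rs, re))
            in_r = int(_count_overlapping(ins, ine, rs, re))
            lam_r = max(in_r * depth_ratio, genome_rate * (width + lf))
            # Region test on the log scale: exact even where sf underflows.
            log_p = poisson_log_tail(ip_r, lam_r)
            if log_p > np.log(params.p_threshold):
                continue
            # Pseudocount 1 keeps the fold gate defined at zero input.
            fold = ip_r / max(in_r * depth_ratio, 1.0)
            if fold < params.min_fold:
                continue
            if cov is None:
                chrom_reads = ip_reads.take(
                    ip_reads.chrom_code == genome.names.index(name)
                )
                cov = extend_and_cover(chrom_reads, genome, lf)[name]
            apex = rs + int(np.argmax(cov[rs:re]))  # argmax ties break leftmost
            peaks.append(
                Peak(
                    chrom=name,
                    start=rs,
                    end=re,
                    apex=apex,
                    p_value=max(float(np.exp(log_p)), 5e-324),
                    fold=fold,
                    neg_log10_p=float(-log_p / np.log(10.0)),
                )
            )
    return peaks


@dataclass(frozen=True)
class FdrResult:
    """Swap-based empirical FDR: reverse calls as a fraction of forward calls."""

    n_forward: int
    n_reverse: int
    fdr_percent: float | None  # None when no forward peaks exist (undefined)

    @property
    def defined(self) -> bool:
        return self.fdr_percent is not None


def empirical_fdr_swap(
    ip_reads: ReadSet,
    input_reads: ReadSet,
    genome: Genome,
    params: CallerParams = CallerParams(),
) -> FdrResult:
    """Empirical FDR by inverting the caller (input tested against IP).

    Peaks found with the roles swapped are enriched in the control and are
    counted as false calls; fdr_percent = 100 * n_reverse / n_forward,
    0 when n_reverse = 0, undefined (None) when n_forward = 0.
    """
    n_fwd = len(call_peaks(ip_reads, input_reads, genome, params))
    n_rev = len(call_peaks(input_reads, ip_reads, genome, params))
    if n_fwd == 0:
        return FdrResult(0, n_rev, None)
    return FdrResult(n_fwd, n_rev, 100.0 * n_rev / n_fwd)
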