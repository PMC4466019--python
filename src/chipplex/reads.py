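"""Clonal-read removal, library subsampling, and read accounting.

Clonal (duplicate) reads — identical mapped 5' position and strand, presumed
PCR artifacts — are collapsed to a single representative before any peak
calling.  Subsampling emulates the shallower coverage a library receives when
multiplexed into a shared lane: a fraction f of the usable reads drawn
uniformly without replacement.
"""

from __future__ import annotations

import numpy as np

from .model import ReadSet, ReadStats


def deduplicate(reads: ReadSet) -> tuple[ReadSet, int]:
    """Collapse reads sharing (chrom, 5'-start, strand) to one representative.

    Returns the unique reads sorted by (chrom, start, strand) and the number
    of clonal reads removed.  With a constant read length the 5'-start key is
    equivalent to keying on start, but stays correct for variable lengths.
    Idempotent by construction.
    """
    n = len(reads)
    if n == 0:
        return reads, 0
    key_chrom = reads.chrom_code.astype(np.int64)
    key_pos = reads.five_prime
    key_strand = reads.strand_plus.astype(np.int64)
    order = np.lexsort((key_strand, key_pos, key_chrom))
    kc, kp, ks = key_chrom[order], key_pos[order], key_strand[order]
    first = np.ones(n, dtype=bool)
    first[1:] = (kc[1:] != kc[:-1]) | (kp[1:] != kp[:-1]) | (ks[1:] != ks[:-1])
    keep = order[first]
    # Output order: sorted by (chrom, start, strand).
    out = reads.take(keep)
    out_order = np.lexsort((out.strand_plus, out.start, out.chrom_code))
    return out.take(out_order), int(n - len(keep))


def subsample(
    reads: ReadSet,
    fraction: float | None = None,
    target_count: int | None = None,
    seed: int = 0,
) -> ReadSet:
    """Draw reads uniformly without replacement.

    Exactly ``round(fraction * n)`` reads (banker's rounding) or
    ``target_count`` reads are kept, via a seeded permutation of indices and a
    prefix take; the kept reads are returned in their original order.
    ``fraction=1.0`` returns the full set.
    """
    n = len(reads)
    if (fraction is None) == (target_count is None):
        raise ValueError("give exactly one of fraction or target_count")
    if fraction is not None:
        if not (0.0 < fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        k = int(round(fraction * n))
    else:
        if not (0 < target_count <= n):
            raise ValueError(f"target_count must be in (0, {n}], got {target_count}")
        k = int(target_count)
    if k >= n:
        return reads
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.permutation(n)[:k])
    return reads.take(idx)


def compute_read_stats(total: int, mapped: int, unique_after_dedup: int) -> ReadStats:
    """Library accounting in lane-report form.

    usable = mapped − clonal; the two percentages (usable over mapped, usable
    over total) are rounded to 0.1.
    """
    if not (0 <= unique_after_dedup <= mapped <= total):
        raise ValueError(
            f"require unique <= mapped <= total, got {unique_after_dedup}, {mapped}, {total}"
        )
    clonal = mapped - unique_after_dedup
    return ReadStats(
        total=total,
        mapped=mapped,
        clonal=clonal,
        usable=unique_after_dedup,
        usable_over_mapped=round(100.0 * unique_after_dedup / mapped, 1) if mapped else 0.0,
        usable_over_total=round(100.0 * unique_after_dedup / total, 1) if total else 0.0,
    )
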