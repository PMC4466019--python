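"""Domain types shared by every pipeline stage.

All genomic intervals are 0-based, half-open ``[start, end)`` — the BED
convention.  The only place 1-based inclusive coordinates appear is the GFF3
reader, which converts on input.  A mapped single-end read ("tag") is a
(chrom, start, length, strand) tuple; its 5' end is ``start`` on the + strand
and ``start + length - 1`` on the − strand, which is what fragment extension
and duplicate removal key on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

SCORE_CAP = 323.0  # -log10 of the smallest positive double; avoids underflow sentinels


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome sizes (name, length in bases)."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in self.chroms):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "Genome":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None


@dataclass(frozen=True)
class Read:
    """A mapped single-end tag."""

    chrom: str
    start: int
    length: int = 50
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("read length must be positive")
        if self.start < 0:
            raise ValueError("read start must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class ReadSet:
    """Columnar container for a read collection.

    Stores chrom as an integer code into ``chrom_names`` plus numpy arrays for
    start, length and strand (True = '+').  Library-scale operations (dedup,
    subsampling, coverage) work on the arrays; iteration yields ``Read``
    objects for small-scale use.
    """

    __slots__ = ("chrom_names", "chrom_code", "start", "length", "strand_plus")

    def __init__(
        self,
        chrom_names: Sequence[str],
        chrom_code: np.ndarray,
        start: np.ndarray,
        length: np.ndarray,
        strand_plus: np.ndarray,
    ) -> None:
        n = len(start)
        if not (len(chrom_code) == len(length) == len(strand_plus) == n):
            raise ValueError("column length mismatch")
        self.chrom_names = list(chrom_names)
        self.chrom_code = np.asarray(chrom_code, dtype=np.int32)
        self.start = np.asarray(start, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.int32)
        self.strand_plus = np.asarray(strand_plus, dtype=bool)

    @classmethod
    def from_reads(cls, reads: Iterable[Read], chrom_names: Sequence[str]) -> "ReadSet":
        code_of = {n: i for i, n in enumerate(chrom_names)}
        rows = [(code_of[r.chrom], r.start, r.length, r.strand == "+") for r in reads]
        if not rows:
            return cls.empty(chrom_names)
        code, start, length, plus = map(np.array, zip(*rows))
        return cls(chrom_names, code, start, length, plus)

    @classmethod
    def empty(cls, chrom_names: Sequence[str]) -> "ReadSet":
        z = np.zeros(0)
        return cls(chrom_names, z, z, z, z.astype(bool))

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[Read]:
        for c, s, l, p in zip(self.chrom_code, self.start, self.length, self.strand_plus):
            yield Read(self.chrom_names[c], int(s), int(l), "+" if p else "-")

    @property
    def end(self) -> np.ndarray:
        return self.start + self.length

    @property
    def five_prime(self) -> np.ndarray:
        return np.where(self.strand_plus, self.start, self.end - 1)

    def take(self, idx: np.ndarray) -> "ReadSet":
        return ReadSet(
            self.chrom_names,
            self.chrom_code[idx],
            self.start[idx],
            self.length[idx],
            self.strand_plus[idx],
        )

    def concat(self, other: "ReadSet") -> "ReadSet":
        if self.chrom_names != other.chrom_names:
            raise ValueError("cannot concatenate read sets over different genomes")
        return ReadSet(
            self.chrom_names,
            np.concatenate([self.chrom_code, other.chrom_code]),
            np.concatenate([self.start, other.start]),
            np.concatenate([self.length, other.length]),
            np.concatenate([self.strand_plus, other.strand_plus]),
        )

    def validate(self, genome: Genome) -> None:
        lengths = np.array([genome.length_of(n) for n in self.chrom_names], dtype=np.int64)
        if np.any(self.start < 0) or np.any(self.end > lengths[self.chrom_code]):
            raise ValueError("read outside chromosome bounds")


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS (5' end) and TES (3' end)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: '+' gene requires tss <= tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: '-' gene requires tss >= tes")


@dataclass(frozen=True)
class Peak:
    """An enriched interval called against input.

    ``p_value`` is the Poisson tail probability of the region's IP count,
    floored at the smallest positive double when it underflows;
    ``neg_log10_p`` carries the exact −log10(p) (computed on the log scale by
    the caller, so it never saturates) and defaults to −log10(p_value) when
    not supplied.
    """

    chrom: str
    start: int
    end: int
    apex: int
    p_value: float
    fold: float
    neg_log10_p: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("peak requires start < end")
        if not (self.start <= self.apex < self.end):
            raise ValueError("apex must lie inside the peak")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")
        if self.fold < 0:
            raise ValueError("fold must be >= 0")
        if self.neg_log10_p is None:
            object.__setattr__(self, "neg_log10_p", float(-np.log10(self.p_value)))
        elif self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        """Detection score: −log10(p), capped to avoid underflow sentinels."""
        return min(self.neg_log10_p, SCORE_CAP)


@dataclass(frozen=True)
class CallerParams:
    """Window-scan Poisson caller parameters.

    The significance threshold (1e-15) and minimum IP/input fold (2) are the
    two published gates; window, merge_gap, min_width and fragment_length are
    this caller's transparent defaults.
    """

    p_threshold: float = 1e-15
    min_fold: float = 2.0
    fragment_length: int = 200
    window: int = 100
    merge_gap: int = 200
    min_width: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1")
        for f in ("fragment_length", "window", "merge_gap", "min_width"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class AnnotationParams:
    """Peak-to-gene assignment window: distance <= flank of TSS or TES."""

    flank: int = 1000

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass(frozen=True)
class ReadStats:
    """Read accounting: usable = mapped − clonal."""

    total: int
    mapped: int
    clonal: int
    usable: int
    usable_over_mapped: float
    usable_over_total: float


@dataclass(frozen=True)
class TruePeak:
    """Simulator ground truth: an enriched region and its expected fold."""

    chrom: str
    start: int
    end: int
    enrichment: float
    anchor_gene: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 200:
            raise ValueError("true peak width must be >= 200")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimParams:
    """Simulation settings for one IP + input library pair."""

    n_ip_reads: int = 2_000_000
    n_input_reads: int = 1_000_000
    fragment_length: int = 200
    read_length: int = 50
    duplicate_rate: float = 0.2
    tss_fraction: float = 0.9
    enrichment_log_mean: float = field(default=float(np.log(10.0)))
    enrichment_log_sd: float = 0.5
    background_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ip_reads <= 0 or self.n_input_reads <= 0:
            raise ValueError("read counts must be positive")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError("duplicate_rate must be in [0, 1)")
        for f in ("tss_fraction", "background_fraction"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValueError(f"{f} must be in [0, 1]")
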