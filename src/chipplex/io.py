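"""Readers and writers for the plain-text formats the pipeline speaks.

Reads come in as BED6 (chrom, start, end, name, score, strand) or a 4-column
tagAlign-like dialect (chrom, start, end, strand).  Peaks go out as BED6+3
(name, score, strand='.', then apex, p_value, fold) and round-trip losslessly.
Genes load from BED12 or a minimal GFF3 subset; GFF3's 1-based inclusive
coordinates are converted to 0-based half-open on read, the only place that
conversion happens.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .model import (
    AnnotationParams,
    CallerParams,
    Genome,
    GeneModel,
    Peak,
    ReadSet,
    ReadStats,
)


class ParseError(ValueError):
    """Malformed record; message carries the file and line number."""


def read_chrom_sizes(path: str | Path) -> Genome:
    """Load a 2-column TSV of chromosome name and length."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        try:
            pairs.append((fields[0], int(fields[1])))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
    return Genome.from_pairs(pairs)


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    Path(path).write_text("".join(f"{n}\t{l}\n" for n, l in genome.chroms))


def read_reads(path: str | Path, genome: Genome) -> ReadSet:
    """Load mapped tags from BED6 or 4-column (chrom start end strand) text.

    Every record is bounds-checked against the genome; order is preserved.
    """
    code_of = {n: i for i, n in enumerate(genome.names)}
    lengths = genome.lengths
    codes: list[int] = []
    starts: list[int] = []
    lens: list[int] = []
    plus: list[bool] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) >= 6:
            chrom, s, e, strand = f[0], f[1], f[2], f[5]
        elif len(f) == 4:
            chrom, s, e, strand = f
        else:
            raise ParseError(f"{path}:{lineno}: expected 4 or >=6 columns, got {len(f)}")
        if chrom not in code_of:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
        try:
            start, end = int(s), int(e)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or end <= start:
            raise ParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        if end > lengths[chrom]:
            raise ParseError(
                f"{path}:{lineno}: read end {end} exceeds {chrom} length {lengths[chrom]}"
            )
        codes.append(code_of[chrom])
        starts.append(start)
        lens.append(end - start)
        plus.append(strand == "+")
    if not codes:
        return ReadSet.empty(genome.names)
    return ReadSet(
        genome.names,
        np.array(codes, dtype=np.int32),
        np.array(starts, dtype=np.int64),
        np.array(lens, dtype=np.int32),
        np.array(plus, dtype=bool),
    )


def write_reads(reads: ReadSet, path: str | Path) -> None:
    """Write tags as BED6 with name '.' and score 0."""
    names = reads.chrom_names
    with open(path, "w") as fh:
        for c, s, e, p in zip(reads.chrom_code, reads.start, reads.end, reads.strand_plus):
            fh.write(f"{names[c]}\t{s}\t{e}\t.\t0\t{'+' if p else '-'}\n")


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6+3: name, score, strand '.', then apex, p, fold.

    The score column is the uncapped −log10(p), written with full float
    precision so write-then-read is the identity on valid peaks.
    """
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks, 1):
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\tpeak_{i}\t{float(pk.neg_log10_p)!r}\t.\t"
                f"{pk.apex}\t{float(pk.p_value)!r}\t{float(pk.fold)!r}\n"
            )


def read_peaks(path: str | Path) -> list[Peak]:
    peaks = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ParseError(f"{path}:{lineno}: expected BED6+3 (9 columns), got {len(f)}")
        peaks.append(
            Peak(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                apex=int(f[6]),
                p_value=float(f[7]),
                fold=float(f[8]),
                neg_log10_p=float(f[4]),
            )
        )
    return peaks


def _genes_from_bed12(path: Path) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(f"{path}:{lineno}: BED gene record needs >= 6 columns")
        chrom, start, end, gene_id, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        genes.append(GeneModel(gene_id, chrom, strand, tss, tes))
    return genes


def _genes_from_gff3(path: Path) -> list[GeneModel]:
    genes = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9:
            raise ParseError(f"{path}:{lineno}: GFF3 record needs 9 columns")
        chrom, _, ftype, start1, end1, _, strand, _, attrs = f[:9]
        if ftype != "gene":
            continue
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
        gene_id = None
        for kv in attrs.split(";"):
            k, _, v = kv.partition("=")
            if k.strip() == "ID":
                gene_id = v.strip()
        if gene_id is None:
            raise ParseError(f"{path}:{lineno}: gene record lacks ID attribute")
        # GFF3 is 1-based inclusive; convert to 0-based half-open here.
        start, end = int(start1) - 1, int(end1)
        tss, tes = (start, end - 1) if strand == "+" else (end - 1, start)
        genes.append(GeneModel(gene_id, chrom, strand, tss, tes))
    return genes


def read_genes(path: str | Path) -> list[GeneModel]:
    """Load gene models from BED12 (or BED6) or a minimal GFF3 subset.

    Format is sniffed: `.gff`/`.gff3` suffix or a `##gff-version` header means
    GFF3.  Duplicate gene ids are an error.
    """
    p = Path(path)
    is_gff = p.suffix.lower() in (".gff", ".gff3")
    if not is_gff:
        head = p.read_text().splitlines()
        is_gff = bool(head) and head[0].startswith("##gff-version")
    genes = _genes_from_gff3(p) if is_gff else _genes_from_bed12(p)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ParseError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def write_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes as BED6; interval spans TSS..TES regardless of strand."""
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
            fh.write(f"{g.chrom}\t{lo}\t{hi + 1}\t{g.gene_id}\t0\t{g.strand}\n")


def write_read_stats(stats: ReadStats, path: str | Path) -> None:
    cols = ("total", "mapped", "clonal", "usable", "usable_over_mapped", "usable_over_total")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(str(getattr(stats, c)) for c in cols) + "\n")


def load_config(path: str | Path) -> dict:
    """Load the YAML run configuration (one block per pipeline stage)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: top-level config must be a mapping")
    return cfg


def caller_params_from_config(cfg: dict) -> CallerParams:
    return CallerParams(**cfg.get("caller", {}))


def annotation_params_from_config(cfg: dict) -> AnnotationParams:
    return AnnotationParams(**cfg.get("annotation", {}))


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
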