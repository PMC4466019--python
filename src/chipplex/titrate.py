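"""Lane-fraction titration: downsample, re-call, re-annotate, measure recovery.

Emulates increasing multiplexing by drawing fractions of the full-depth
(usable) libraries — 90% down to 10% in 10% steps by default, five
independent replicates each — re-running peak calling and gene annotation on
every cell, and scoring each against the full-depth reference: what fraction
of the subsample's peaks fall inside reference peaks, what fraction of the
reference peaks are still captured, and what fraction of reference-annotated
genes remain annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import annotate_peaks, gene_recovery, percent_overlap
from .model import AnnotationParams, CallerParams, GeneModel, Genome, Peak, ReadSet
from .peaks import call_peaks
from .reads import subsample

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.9, 0.0, -0.1), 1))

CELL_COLUMNS = [
    "fraction",
    "replicate",
    "n_ip_reads",
    "n_peaks",
    "query_peaks_in_reference_pct",
    "reference_peaks_captured_pct",
    "gene_recovery_pct",
    "n_genes",
    "low_reads_flag",
]


@dataclass(frozen=True)
class TitrationConfig:
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    replicates: int = 5
    base_seed: int = 0
    downsample_input: bool = True  # proportional input; False keeps full input
    caller: CallerParams = field(default_factory=CallerParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    min_reads_warn: int = 1000

    def __post_init__(self) -> None:
        fr = self.fractions
        if any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError("fractions must lie in (0, 1]")
        if list(fr) != sorted(set(fr), reverse=True):
            raise ValueError("fractions must be unique and sorted descending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def cell_seed(base_seed: int, fraction_index: int, replicate: int, stream: int = 0) -> int:
    """Deterministic per-cell seed: SeedSequence keyed on (base, cell, stream).

    Replicates are independent draws (not nested subsets), and IP and input
    use separate streams within a cell.
    """
    ss = np.random.SeedSequence([base_seed, fraction_index, replicate, stream])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class RecoveryCurve:
    """Per-cell recovery of peaks and annotated genes versus the full-depth run."""

    cells: pd.DataFrame  # one row per (fraction, replicate); CELL_COLUMNS
    reference_peaks: list[Peak]
    reference_genes: set[str]
    config: TitrationConfig

    def per_fraction(self) -> pd.DataFrame:
        """Mean and sd over replicates, one row per fraction."""
        g = self.cells.groupby("fraction", sort=False)
        agg = g.agg(
            mean_gene_recovery_pct=("gene_recovery_pct", "mean"),
            sd_gene_recovery_pct=("gene_recovery_pct", "std"),
            mean_query_peaks_in_reference_pct=("query_peaks_in_reference_pct", "mean"),
            mean_reference_peaks_captured_pct=("reference_peaks_captured_pct", "mean"),
            mean_n_peaks=("n_peaks", "mean"),
        ).reset_index()
        return agg.sort_values("fraction", ascending=False).reset_index(drop=True)


def run_titration(
    ip_reads: ReadSet,
    input_reads: ReadSet,
    genome: Genome,
    genes: Sequence[GeneModel],
    config: TitrationConfig = TitrationConfig(),
) -> RecoveryCurve:
    """Run the full titration grid against a full-depth reference.

    The inputs are assumed already deduplicated (subsampling operates on
    usable reads; duplicate removal is not re-run per cell).  At fraction 1.0
    a cell reproduces the reference exactly, so recovery is 100 by
    construction.
    """
    ref_peaks = call_peaks(ip_reads, input_reads, genome, config.caller)
    _, ref_genes = annotate_peaks(ref_peaks, genes, config.annotation)

    rows = []
    for fi, frac in enumerate(config.fractions):
        for r in range(config.replicates):
            if frac == 1.0:
                sub_ip, sub_in = ip_reads, input_reads
            else:
                sub_ip = subsample(ip_reads, fraction=frac, seed=cell_seed(config.base_seed, fi, r, 0))
                sub_in = (
                    subsample(input_reads, fraction=frac, seed=cell_seed(config.base_seed, fi, r, 1))
                    if config.downsample_input
                    else input_reads
                )
            q_peaks = call_peaks(sub_ip, sub_in, genome, config.caller)
            _, q_genes = annotate_peaks(q_peaks, genes, config.annotation)
            ov_q = percent_overlap(q_peaks, ref_peaks)
            ov_r = percent_overlap(ref_peaks, q_peaks)
            rec = gene_recovery(ref_genes, q_genes)
            rows.append(
                {
                    "fraction": float(frac),
                    "replicate": r,
                    "n_ip_reads": len(sub_ip),
                    "n_peaks": len(q_peaks),
                    "query_peaks_in_reference_pct": ov_q.percent_overlap_of_x,
                    "reference_peaks_captured_pct": ov_r.percent_overlap_of_x,
                    "gene_recovery_pct": np.nan if rec is None else rec,
                    "n_genes": len(q_genes),
                    "low_reads_flag": len(sub_ip) < config.min_reads_warn,
                }
            )
    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    return RecoveryCurve(cells=cells, reference_peaks=ref_peaks, reference_genes=ref_genes, config=config)


def summarize_titration(curve: RecoveryCurve) -> pd.DataFrame:
    """Long-form report: one row per cell plus mean/sd rows per fraction.

    Aggregate rows carry replicate labels 'mean' and 'sd'; the column set is
    CELL_COLUMNS with `replicate` as string.
    """
    if curve.cells.empty:
        raise ValueError("empty recovery curve")
    cells = curve.cells.copy()
    cells["replicate"] = cells["replicate"].astype(str)
    num_cols = [c for c in CELL_COLUMNS if c not in ("fraction", "replicate", "low_reads_flag")]
    agg_rows = []
    for frac, grp in cells.groupby("fraction", sort=False):
        for label, fn in (("mean", "mean"), ("sd", "std")):
            row = {"fraction": frac, "replicate": label, "low_reads_flag": False}
            for c in num_cols:
                row[c] = getattr(grp[c], fn)()
            agg_rows.append(row)
    return pd.concat([cells, pd.DataFrame(agg_rows, columns=cells.columns)], ignore_index=True)


def write_titration_tsv(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_titration_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"replicate": str})
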