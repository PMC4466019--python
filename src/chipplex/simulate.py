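"""Synthetic ChIP-seq generator with a sharp, TSS-anchored mark in mind.

The generator emulates what an H3K4me3 immunoprecipitation looks like after
mapping: an IP library whose fragments pile up in ~500–3000 bp regions
anchored near transcription start sites, an input library of near-uniform
background, and PCR-duplicate (clonal) reads at a configurable rate.  Reads
are fragment 5' ends — fragments, not reads, are placed over enriched
regions, so the familiar strand asymmetry around a peak arises naturally.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import GeneModel, Genome, ReadSet, SimParams, TruePeak

MIN_TSS_SPACING = 4_000  # bp between neighbouring TSSs in generated gene sets
TRUE_PEAK_MIN_WIDTH = 200
TRUE_PEAK_MEDIAN_WIDTH = 751  # calibration target for the width distribution
TRUE_PEAK_WIDTH_LOG_SD = 0.4
TSS_JITTER = 500  # anchored peaks are centred within +/- this of the TSS
MIN_ENRICHMENT = 4.0


def make_genome_and_genes(
    n_chroms: int, chrom_length: int, n_genes: int, seed: int
) -> tuple[Genome, list[GeneModel]]:
    """Build a toy genome and a gene set with well-separated TSSs.

    TSS positions are uniform per chromosome subject to a 4 kb minimum
    spacing (so anchored peaks rarely collide); strands are fair coin flips
    and gene lengths uniform in 2–20 kb, truncated at chromosome ends.
    """
    rng = np.random.default_rng(seed)
    genome = Genome.from_pairs((f"chr{i + 1}", int(chrom_length)) for i in range(n_chroms))
    per_chrom = np.full(n_chroms, n_genes // n_chroms, dtype=int)
    per_chrom[: n_genes % n_chroms] += 1
    genes: list[GeneModel] = []
    gid = 0
    for (chrom, length), k in zip(genome.chroms, per_chrom):
        if k == 0:
            continue
        margin = 2 * MIN_TSS_SPACING  # keep TSSs away from the very edges
        free = length - 2 * margin - (k - 1) * MIN_TSS_SPACING
        if free <= 0:
            raise ValueError(
                f"cannot place {k} TSSs with {MIN_TSS_SPACING} bp spacing on a "
                f"{length} bp chromosome"
            )
        # Sorted uniform draws in the slack, then re-inflate the spacing.
        slack = np.sort(rng.integers(0, free, size=k))
        tss = margin + slack + np.arange(k) * MIN_TSS_SPACING
        strands = rng.random(k) < 0.5
        glen = rng.integers(2_000, 20_001, size=k)
        for t, plus, gl in zip(tss, strands, glen):
            gid += 1
            if plus:
                tes = min(int(t + gl), length - 1)
                genes.append(GeneModel(f"gene_{gid}", chrom, "+", int(t), tes))
            else:
                tes = max(int(t - gl), 0)
                genes.append(GeneModel(f"gene_{gid}", chrom, "-", int(t), tes))
    return genome, genes


def place_true_peaks(
    genes: Sequence[GeneModel],
    genome: Genome,
    n_peaks: int,
    params: SimParams,
    seed: int,
) -> list[TruePeak]:
    """Drop ground-truth enriched regions on the genome.

    ``round(tss_fraction * n_peaks)`` regions are centred within ±500 bp of
    distinct TSSs; the rest land uniformly (intergenic signal).  Widths are
    log-normal with median ~751 bp (floored at 200 bp) and fold enrichments
    log-normal per ``params.enrichment_law``, floored at 4.
    """
    rng = np.random.default_rng(seed)
    n_anchored = int(round(params.tss_fraction * n_peaks))
    if n_anchored > len(genes):
        raise ValueError(f"need {n_anchored} distinct TSS anchors but only {len(genes)} genes")
    lengths = genome.lengths
    anchor_idx = rng.choice(len(genes), size=n_anchored, replace=False)

    widths = np.exp(
        rng.normal(np.log(TRUE_PEAK_MEDIAN_WIDTH), TRUE_PEAK_WIDTH_LOG_SD, size=n_peaks)
    ).astype(int)
    widths = np.maximum(widths, TRUE_PEAK_MIN_WIDTH)
    folds = np.maximum(
        np.exp(rng.normal(params.enrichment_log_mean, params.enrichment_log_sd, size=n_peaks)),
        MIN_ENRICHMENT,
    )

    peaks: list[TruePeak] = []
    for i in range(n_anchored):
        g = genes[anchor_idx[i]]
        center = g.tss + int(rng.integers(-TSS_JITTER, TSS_JITTER + 1))
        w = int(widths[i])
        start = max(0, center - w // 2)
        end = min(lengths[g.chrom], start + w)
        start = min(start, end - TRUE_PEAK_MIN_WIDTH)
        peaks.append(TruePeak(g.chrom, int(start), int(end), float(folds[i]), g.gene_id))

    names = genome.names
    probs = np.array([lengths[n] for n in names], dtype=float)
    probs /= probs.sum()
    for i in range(n_anchored, n_peaks):
        chrom = names[rng.choice(len(names), p=probs)]
        w = int(widths[i])
        start = int(rng.integers(0, lengths[chrom] - w))
        peaks.append(TruePeak(chrom, start, start + w, float(folds[i]), None))
    return peaks


def _apply_duplicates(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Return a source index per emission under resampling-with-history.

    Each read after the first is, with probability ``rate``, a verbatim copy
    of a uniformly chosen earlier emission (which may itself be a copy — the
    chain is resolved so copies of copies share one origin).
    """
    source = np.arange(n, dtype=np.int64)
    if rate <= 0.0 or n < 2:
        return source
    dup = np.flatnonzero(rng.random(n) < rate)
    dup = dup[dup > 0]
    # rng.integers(0, i) per duplicate; vectorised draw then chain-resolve.
    targets = (rng.random(len(dup)) * dup).astype(np.int64)
    for i, j in zip(dup, targets):
        source[i] = source[j]
    return source


def _place_fragments_background(
    n: int, genome: Genome, fragment_length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform fragment 5'-start placement: (chrom_code, fragment_start)."""
    lengths = np.array([l for _, l in genome.chroms], dtype=np.int64)
    probs = lengths / lengths.sum()
    code = rng.choice(len(lengths), size=n, p=probs)
    span = lengths[code] - fragment_length
    fstart = (rng.random(n) * span).astype(np.int64)
    return code.astype(np.int32), fstart


def simulate_reads(
    genome: Genome, true_peaks: Sequence[TruePeak], params: SimParams
) -> tuple[ReadSet, ReadSet, dict]:
    """Simulate an IP / input library pair plus a truth manifest.

    Input fragments start uniformly over the genome.  IP fragments target a
    true peak with probability ``1 - background_fraction``; the peak is drawn
    with probability proportional to width × enrichment and the fragment is
    placed uniformly among all positions whose extension overlaps the peak.
    A duplicate process then replaces each read, with probability
    ``duplicate_rate``, by a copy of an earlier emission.
    """
    if params.read_length > params.fragment_length:
        raise ValueError("read_length must not exceed fragment_length")
    if not true_peaks and params.background_fraction < 1.0:
        raise ValueError("no true peaks given but background_fraction < 1")
    rng = np.random.default_rng(params.seed)
    lf, lr = params.fragment_length, params.read_length
    code_of = {n: i for i, n in enumerate(genome.names)}
    chrom_lengths = np.array([l for _, l in genome.chroms], dtype=np.int64)

    def emit(code: np.ndarray, fstart: np.ndarray, n: int) -> ReadSet:
        plus = rng.random(n) < 0.5
        # Read is the fragment's 5'-most read_length bases on its strand.
        start = np.where(plus, fstart, fstart + lf - lr)
        src = _apply_duplicates(n, params.duplicate_rate, rng)
        return ReadSet(
            genome.names,
            code[src],
            start[src],
            np.full(n, lr, dtype=np.int32),
            plus[src],
        )

    # --- IP library ---
    n_ip = params.n_ip_reads
    targeted = rng.random(n_ip) < (1.0 - params.background_fraction)
    n_t = int(targeted.sum())
    code = np.empty(n_ip, dtype=np.int32)
    fstart = np.empty(n_ip, dtype=np.int64)

    if n_t:
        pw = np.array([p.width for p in true_peaks], dtype=float)
        pe = np.array([p.enrichment for p in true_peaks])
        weight = pw * pe
        weight /= weight.sum()
        pick = rng.choice(len(true_peaks), size=n_t, p=weight)
        pstart = np.array([p.start for p in true_peaks], dtype=np.int64)[pick]
        pend = np.array([p.end for p in true_peaks], dtype=np.int64)[pick]
        pcode = np.array([code_of[p.chrom] for p in true_peaks], dtype=np.int32)[pick]
        lo = pstart - lf + 1  # any fragment start whose extension touches the peak
        hi = pend - 1
        f = lo + (rng.random(n_t) * (hi - lo + 1)).astype(np.int64)
        f = np.clip(f, 0, chrom_lengths[pcode] - lf)
        code[targeted] = pcode
        fstart[targeted] = f
    n_b = n_ip - n_t
    if n_b:
        bcode, bf = _place_fragments_background(n_b, genome, lf, rng)
        code[~targeted] = bcode
        fstart[~targeted] = bf
    ip = emit(code, fstart, n_ip)

    # --- input library ---
    icode, ifstart = _place_fragments_background(params.n_input_reads, genome, lf, rng)
    inp = emit(icode, ifstart, params.n_input_reads)

    manifest = {
        "n_ip_reads": int(n_ip),
        "n_input_reads": int(params.n_input_reads),
        "n_true_peaks": len(true_peaks),
        "n_targeted_ip_reads": int(n_t),
        "fragment_length": lf,
        "read_length": lr,
        "duplicate_rate": params.duplicate_rate,
        "background_fraction": params.background_fraction,
        "seed": params.seed,
        "true_peaks": [
            {
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "enrichment": p.enrichment,
                "anchor_gene": p.anchor_gene,
            }
            for p in true_peaks
        ],
    }
    return ip, inp, manifest


def write_truth(true_peaks: Sequence[TruePeak], path) -> None:
    """Write ground-truth regions as BED6: name = anchor gene or '.', score = fold."""
    with open(path, "w") as fh:
        for p in true_peaks:
            name = p.anchor_gene if p.anchor_gene is not None else "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.enrichment:.3f}\t.\n")


def read_truth(path) -> list[TruePeak]:
    out = []
    for line in open(path):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        anchor = None if f[3] == "." else f[3]
        out.append(TruePeak(f[0], int(f[1]), int(f[2]), float(f[4]), anchor))
    return out


def default_simulation(
    seed: int,
    n_ip_reads: int = 2_000_000,
    n_input_reads: int = 1_000_000,
) -> tuple[Genome, list[GeneModel], list[TruePeak], ReadSet, ReadSet, dict]:
    """The desk-scale reference scenario: 2×5 Mb, 500 genes, 400 true peaks.

    Library sizes (2M IP / 1M input by default) keep the reads-per-peak ratio
    of a deeply sequenced lane at roughly 1/100 linear scale, so the pipeline
    runs in minutes on one core.
    """
    params = SimParams(n_ip_reads=n_ip_reads, n_input_reads=n_input_reads, seed=seed)
    genome, genes = make_genome_and_genes(2, 5_000_000, 500, seed)
    truth = place_true_peaks(genes, genome, 400, params, seed + 1)
    ip, inp, manifest = simulate_reads(genome, truth, params)
    return genome, genes, truth, ip, inp, manifest
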