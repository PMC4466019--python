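import numpy as np
import pytest

from chipplex.model import Genome, ReadSet, SimParams
from chipplex.peaks import call_peaks
from chipplex.reads import deduplicate
from chipplex.simulate import make_genome_and_genes, place_true_peaks, simulate_reads


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    return Genome.from_pairs([("chr1", 1_000_000), ("chr2", 500_000)])


def make_readset(genome: Genome, rows):
    """rows: iterable of (chrom, start, length, strand)."""
    code_of = {n: i for i, n in enumerate(genome.names)}
    if not rows:
        return ReadSet.empty(genome.names)
    code, start, length, plus = zip(
        *[(code_of[c], s, l, st == "+") for c, s, l, st in rows]
    )
    return ReadSet(
        genome.names,
        np.array(code),
        np.array(start),
        np.array(length),
        np.array(plus),
    )


@pytest.fixture(scope="session")
def mini_simulation():
    """A small but realistic IP/input pair: 1 Mb, 30 genes, 20 true peaks."""
    params = SimParams(n_ip_reads=60_000, n_input_reads=30_000, seed=11)
    genome, genes = make_genome_and_genes(1, 1_000_000, 30, seed=11)
    truth = place_true_peaks(genes, genome, 20, params, seed=12)
    ip, inp, manifest = simulate_reads(genome, truth, params)
    return genome, genes, truth, ip, inp, manifest


@pytest.fixture(scope="session")
def mini_called(mini_simulation):
    genome, genes, truth, ip, inp, _ = mini_simulation
    ip_u, _ = deduplicate(ip)
    inp_u, _ = deduplicate(inp)
    peaks = call_peaks(ip_u, inp_u, genome)
    return genome, genes, truth, ip_u, inp_u, peaks
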