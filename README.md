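# chipplex

How many ChIP-seq samples can share a sequencing lane before you start losing
biology?  `chipplex` is a self-contained pipeline for answering that question
for sharp, promoter-proximal marks (H3K4me3 being the canonical case): it
emulates multiplexing by downsampling a deeply sequenced library, re-calls
peaks at every depth, and measures what fraction of the full-depth peaks and
of their gene annotations survive.

The pipeline covers:

- **Simulation** — a synthetic genome, gene set, and IP/input read pair with
  H3K4me3-like structure: enriched regions anchored near transcription start
  sites, near-uniform input background, and PCR-duplicate (clonal) reads at a
  configurable rate.  Real mapped reads in BED6/tagAlign are equally welcome.
- **Read processing** — clonal-read removal keyed on (chrom, 5′ start,
  strand), uniform subsampling without replacement, and lane-report read
  accounting (usable = mapped − clonal).
- **Peak calling** — a window-scan Poisson test of IP fragment counts against
  depth-scaled input.  Reads are extended to the expected fragment length;
  each fixed window is tested with mean
  λ = max(input·r, ρ·span), where r is the IP/input depth ratio and ρ the
  genome-wide IP fragment rate; significant windows merge into regions that
  are re-tested and gated at p ≤ 10⁻¹⁵ and IP/input fold ≥ 2.
- **Empirical FDR** — swap IP and input and call again; peaks enriched in the
  control are false calls, reported as a percentage of forward calls.
- **Evaluation** — percent overlap between peak sets (≥ 1 bp, half-open
  intervals), apex-shift distributions, peak-to-gene annotation within 1 kb
  of a TSS or TES, gene recovery, and quartile placement of the peaks behind
  lost genes.
- **Titration** — the orchestration of all of the above over a 90% → 10%
  downsampling grid with independent replicates, producing recovery curves.

## Worked example

```bash
chipplex simulate --seed 11 --config sim.yaml --out demo/      # or library defaults
chipplex dedup --reads demo/reads.ip.bed    --genome demo/genome.chrom.sizes --out demo/ip.u.bed
chipplex dedup --reads demo/reads.input.bed --genome demo/genome.chrom.sizes --out demo/in.u.bed
chipplex callpeaks --ip demo/ip.u.bed --input demo/in.u.bed \
    --genome demo/genome.chrom.sizes --out demo/peaks.bed
chipplex fdr --ip demo/ip.u.bed --input demo/in.u.bed --genome demo/genome.chrom.sizes
chipplex titrate --ip demo/ip.u.bed --input demo/in.u.bed \
    --genome demo/genome.chrom.sizes --genes demo/genes.bed --seed 3 --out demo/titr
```

The same run through the library, on the default desk-scale scenario
(2 chromosomes × 5 Mb, 500 genes, 400 true enriched regions, 2 M IP / 1 M
input reads):

```python
>>> import chipplex as cp
>>> genome, genes, truth, ip, inp, _ = cp.default_simulation(seed=1)
>>> ip_u, clonal = cp.deduplicate(ip)
>>> peaks = cp.call_peaks(ip_u, cp.deduplicate(inp)[0], genome)
>>> len(peaks)
397
>>> cp.empirical_fdr_swap(ip_u, cp.deduplicate(inp)[0], genome).fdr_percent
0.0
```

397 of the 400 simulated regions come back as peaks (every region with fold
enrichment ≥ 6 is recovered), and the swapped-role caller finds nothing —
an empirical FDR of 0% at this signal strength.  Running the titration
(`cp.run_titration`) on the same data shows mean gene recovery declining
gently from 100% at 90% of the lane to ~99% at 10%, with the genes that do
drop out carrying the least significant reference peaks (fourth p-value
quartile).

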