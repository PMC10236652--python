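# coraldup

Tandem gene duplication analysis for coral-like genomes.

Stony coral genomes carry unusually large numbers of tandemly duplicated
genes (TDG) — arrays of near-identical gene copies lying next to each other
on a contig, often amplifying innate-immunity receptor families. These
arrays are easy to miss: short-read assemblies collapse them, spliced
protein alignments fuse neighbouring copies into chimeric gene models, and
residual allelic duplications masquerade as true duplicates. `coraldup`
re-implements, as a tested and reusable library + CLI, the computational
procedures needed to find and characterize such arrays, and ships a
synthetic-data generator with planted ground truth so every stage can be
validated without downloading genome-scale data. It is aimed at comparative
genomicists annotating repeat-rich metazoan assemblies.

## What it computes

**Tandem duplicate detection.** All-vs-all protein similarity (a seeded
Smith–Waterman search with Karlin–Altschul e-values, interchangeable with
any 12-column tabular similarity file); a pair of genes is a tandem
duplicate when some hit has e-value ≤ 10⁻²⁰ with ≥ 80% of the smaller
protein aligned, the genes share a contig, and their gene-rank distance is
≤ 10. Pairs are grouped by single-linkage clustering (connected components).

**Long-read validation.** An adjacent pair of cluster members is validated
when at least one primary read alignment completely contains both gene
intervals; a cluster is validated when one read contains every member.

**Duplicate ageing.** Pairwise synonymous distance by Nei–Gojobori (1986)
pathway counting with the Jukes–Cantor correction,

&nbsp;&nbsp;&nbsp;&nbsp;dS = −¾ ln(1 − 4/3 · Sd/S),

on codon alignments back-propagated from the protein alignment, plus
positional exon/intron length comparison (fully conserved / exons conserved
/ divergent).

**Chimera splitting for annotation.** Spliced protein-to-genome alignments
with an intron > 5 kb are split at the intron midpoint; the query is
realigned (six-frame, splice-less) on both severed windows and the split is
kept when the summed scores beat the original alignment. Applied
recursively, a chimera spanning k tandem copies decomposes into k
single-locus alignments while genuine long-intron genes stay intact. The
module also implements the mapping-noise filters (intronless alignments
> 40% per proteome; unique-intron alignments covering ≥ 10 known exons) and
the gene-candidate filter (single-exon CDS ≤ 100 aa dropped; then homology
in > 1 species or spliced with CDS/UTR ≥ 0.75).

**Gene-family machinery.** Orthogroup consensus building (outlier removal at
mean + 1.5 SD of pairwise distance, majority-rule consensus, conditional
second pass when the consensus exceeds the median input length by > 15%);
masking of unspecific 30-aa windows shared at ≥ 85% identity between
consensuses; selection of single-copy orthogroups (exactly one copy in at
least S−1 species); read-depth copy-number estimation normalized by the
single-copy set (copy number = raw depth / single-copy depth); and an exact
binomial amplification screen — for species groups A, B the group-A gene
count of an orthogroup is tested against Binomial(n, |A|/(|A|+|B|)), with
Benjamini–Hochberg control and calls at adjusted p < 0.001.

**Synteny.** Ortholog pairs chain into syntenic clusters when fewer than 15
ortholog-bearing genes separate them on both genomes (orientation-agnostic,
≥ 5 pairs per cluster); per-genome coverage by cluster spans; dotplot and
circular-link exports.

**Telomeric repeats.** Exhaustive sliding-window scan for (TTAGGG)₄ on both
strands (identity > 75%, coverage ≥ 75%, ≤ 2 mismatches), merging of hits
< 400 bp apart into interstitial telomeric sequence (ITS) records, and
terminal/interstitial classification.

**Synthetic data.** `coraldup.synthetic_data` plants all of the above:
tandem arrays grown by serial birth-and-death duplication (including 2–3
gene block duplications) with codon-aware divergence to target dS values,
intron drift, error-prone long reads, copy-number read sets, orthogroup
count matrices with planted amplifications, shuffled-segment genome pairs
for synteny, and telomeric arrays — every artifact keyed by a truth table.

## Worked example

```python
from coraldup import synthetic_data as sd, tdg, seqcore

params = sd.SimulationParams(seed=42)           # ~2 Mb, ~500 genes, 40 arrays
sim = sd.simulate_genome(params)

hits = tdg.similarity_search(sim.proteins)
lengths = {g: len(p) for g, p in sim.proteins.items()}
pairs = tdg.filter_similarity(hits, lengths)            # e <= 1e-20, cov >= 0.8
tandem = tdg.find_tandem_pairs(pairs, sim.models)       # rank distance <= 10
clusters = tdg.cluster_single_linkage(tandem, sim.models)

reads_params = sd.SimulationParams(seed=42, long_read_error_rate=0.05)
_, spans = sd.simulate_long_reads(sim.genome, reads_params)
clusters, summary = tdg.validate_with_reads(clusters, spans, sim.models)

a, b = sim.truth.planted_clusters[0][:2]
est = seqcore.ng86_ds_pair(sim.cds[a], sim.cds[b], a, b)
```

This prints (with the formatting of `examples` in the docstrings):

```
simulated 2,088,043 bp, 494 genes, 39 planted clusters
39 clusters, 225 tandemly duplicated genes (45.5% of the catalog), largest cluster 10 genes
read validation: 100.0% of adjacent pairs, 71.8% of whole clusters
dS(cl026_00, cl026_01) = 0.0326  (dN = 0.0164, 217 codons)
```

Reading: detection recovered all 39 planted arrays exactly (the simulated
catalog is deliberately TDG-rich); every adjacent duplicate pair is spanned
by at least one 25 kb read but only 72% of whole arrays fit inside a single
read; the first array's two adjacent copies differ at dS ≈ 0.033 — a recent
duplication — with dN/dS ≈ 0.5 of the simulated constraint.

The same pipeline is available from the shell:

```bash
coraldup --seed 42 --outdir out simulate --preset tdg
coraldup --outdir out detect out/genes.gff3 out/proteins.fasta
coraldup --outdir out telomere out/genome.fasta
coraldup --seed 42 --outdir run run --simulate full
```

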