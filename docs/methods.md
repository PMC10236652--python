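# Methods

This note documents the models and procedures implemented in `coraldup`,
the tunable parameters and their defaults, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Tandem duplicate detection

Two genes are duplicate candidates when their proteins match strongly:
e-value ≤ 10⁻²⁰ and an aligned span covering ≥ 80% of the smaller protein
(`max_evalue`, `min_coverage`). Candidates become tandem pairs when they lie
on the same contig within `max_gene_distance = 10` gene ranks. "Not more
than 10 genes apart" is read as rank distance ≤ 10 (up to 9 intervening
genes), boundary inclusive; the cutoff is a parameter. Pairs are clustered
by single linkage (connected components of the pair graph); cluster
identifiers derive from the lexicographically smallest member, and of
several rows supporting a pair the highest bitscore is kept. Re-clustering
cluster output is a no-op, and total cluster membership is monotone in the
rank-distance cutoff.

The bundled all-vs-all search seeds candidate pairs on shared 5-mers
(pairs sharing ≥ 3 distinct 5-mers are aligned; k-mers occurring in > 50
proteins are skipped as uninformative) and scores them with the same local
aligner used everywhere else. E-values follow the Karlin–Altschul formula
E = m·n·2^(−S′) with the standard gapped BLOSUM62 parameters
(λ = 0.267, K = 0.041) and the total residue count of the set as database
length. The search exists so the pipeline is self-contained; any 12-column
tabular similarity file can be supplied instead, and the test suite checks
that the filtered pair set matches `blastp` exactly on a planted-cluster
proteome.

## Local and translated alignment

`align_local` is an optimal local (Smith–Waterman contract) protein
alignment under BLOSUM62 with affine gaps: a gap of length L costs
`gap_open + L · gap_extend` = 11 + L, matching the convention of common
protein search tools. The implementation rides Biopython's PairwiseAligner
(C engine); scores are verified against a naive Gotoh dynamic program in the
tests. Where several tracebacks are optimal the engine's first alignment is
taken — deterministic across runs, which is the property downstream code
relies on. Scores ≤ 0 are reported as an empty alignment with score 0.

`realign_protein_to_dna` translates a genomic window in all six frames
(internal stops translate to `*`, penalized at −4 by the matrix) and keeps
the best protein-vs-translation local alignment, ties resolved + strand
first, then lowest frame; block coordinates are mapped back to forward-strand
genomic bp. It is deliberately splice-less: its single job is to score how
much of a query lives on one side of a candidate split.

## Chimera splitting

Spliced alignments spanning several tandem copies show up with implausibly
large "introns". For each intron longer than `max_intron = 5000` bp
(longest first), the alignment's full query span is realigned against the
two genomic sides, each extended to the intron midpoint. The split is
accepted when

  score_left + score_right > total_score · (1 + `split_min_gain_fraction`),

after which the original blocks are partitioned at the intron and the
procedure recurses on both halves; otherwise the next qualifying intron is
tried. Acceptance strictly increases the summed score and the score is
bounded, so recursion terminates; because the returned alignments keep the
original blocks, the summed score of the output never falls below the input.

The relative margin (default 0.05) is a numerical guard: a local alignment
realigned on a window extended into intron sequence can pick up a few
points of chance extension, and with a strictly-greater rule a genuine
long-intron gene would split on roughly half of random inputs. A real
chimera gains on the order of the severed copy's full score (≈ +100% for a
two-copy chimera), so the margin costs no sensitivity. Intron gaps carry no
penalty in `total_score` by default (`intron_penalty = 0`), as in spliced
aligners.

Mapping-noise filters follow the stated rules verbatim: per source
proteome, intronless alignments are all removed when they exceed 40% of
that proteome's alignments (exactly 40% is kept); an alignment carrying an
intron whose exact coordinates occur nowhere else is removed when its span
covers ≥ 10 exons of the global exon set, where "exons" are distinct
genomic coordinates over all alignments. The gene-candidate filter removes
single-exon genes of ≤ 100 aa, then keeps genes with homology in more than
one species or spliced genes with CDS/UTR ≥ 0.75 (genes without UTR
trivially satisfy the ratio); transposon flags are consumed as input, never
computed.

## Synonymous distance (dS)

`ng86_ds` implements Nei–Gojobori (1986): per codon, each position
contributes the fraction of its three single-nucleotide changes that are
synonymous (changes to stop codons count as nonsynonymous, so S + N = 3 ×
codons compared); differences are averaged over all orderings of the
changed positions, excluding pathways through stop codons (all pathways are
kept when every one is blocked). Proportions are Jukes–Cantor corrected;
pS ≥ 3/4 flags saturation. Codon columns containing gaps are skipped
pairwise and internal stops are rejected. For unaligned CDS pairs the codon
alignment is back-propagated from the local protein alignment with gap
columns dropped pairwise.

This is a deliberate substitution of a counting estimator for
maximum-likelihood dS: it is self-contained and oracle-verifiable (the
tests enumerate sites and paths by brute force), and all quantitative
claims about it are made against simulator truth, never against published
dS distributions. At coral-like divergences (dS ≲ 0.5) the two families of
estimators rank pairs identically, which is what the downstream analyses
use. Polarity is standard throughout: higher dS = more diverged.

Structure comparison orients both genes 5′→3′ and compares exon and intron
length vectors positionally; classes are `fully_conserved` (both equal),
`exons_conserved` (exons equal, introns not) and `divergent`.

## Gene-family machinery

*Outlier removal*: per-row score = mean pairwise distance (fraction of
differing columns; gap-vs-residue is a difference, shared-gap columns are
skipped); rows above mean + 1.5 SD (population SD) are removed; fewer than
three rows are returned unchanged. *Consensus*: majority residue over
columns with < 50% gap occupancy, ties broken alphabetically — a
deterministic stand-in for profile-HMM emission; when the consensus exceeds
the median ungapped input length by > 15% of the median (a gappy,
pulled-apart alignment), outlier removal runs once more and the consensus
is rebuilt. MSAs are accepted precomputed; the simulator emits indel-free
families whose identity alignment is exact, so no aligner dependency is
needed in the tests.

*Unspecific masking*: every pair of consensuses is compared ungapped along
all diagonals; any 30-aa window at ≥ 85% identity is masked on both sides,
and orthogroups with more than `unspecific_flag_fraction = 0.5` of their
consensus masked are flagged and excluded from screens. *Single-copy set*:
orthogroups with exactly one gene in at least S − 1 of S species, minus
flagged ones.

*Copy number*: per read, the single best-scoring hit is kept and score ties
discard the read as ambiguous. Raw depth = aligned bases on unmasked
consensus positions / unmasked length (masked positions leave both
numerator and denominator). The normalization factor is the pooled depth
over the single-copy set after discarding single-copy orthogroups more than
3 MADs from the set median — the formalization chosen for "discarding a few
outlier orthogroups"; copy number is the ratio, making the estimator
invariant to uniform rescaling of the read set.

*Amplification screen*: for orthogroup counts x in group A of n total, the
p-value is the exact binomial test against p₀ = |A|/(|A|+|B|), two-sided by
minimum likelihood (the sum of all outcome probabilities ≤ P(X = x); a
central 2·min(tails) option is provided since sidedness conventions vary
between tools). Benjamini–Hochberg runs across all
tested orthogroups and calls are made at adjusted p < 0.001 in the
direction of the observed share. Operating characteristics measured by the
benchmarks at the default study conditions (baseline Poisson mean 3
genes/species, 11-vs-3 groups, 5000 orthogroups, 100 planted 4-fold
amplifications): realized null call fraction 0, no false calls on the
planted table, recall ≈ 0.67 — a typical amplified family reaches
p ≈ 10⁻⁶–10⁻⁴ while the BH cutoff sits near 2·10⁻⁵, so detecting
substantially more of a 4-fold amplification at this baseline would require
either larger families or a weaker error target.

## Synteny

Many-to-many ortholog candidates reduce to mutually-best pairs by score.
Contigs need ≥ 5 ortholog-bearing genes to participate. Pairs sharing a
(contig A, contig B) combination chain by single linkage when their
ortholog-rank gap — ranks counted among ortholog-bearing genes only — is
strictly < 15 on *both* genomes (the stricter reading; a flag relaxes it to
genome A only). Gap magnitude ignores orientation, so inverted blocks
chain. Clusters need ≥ 5 pairs. Coverage is the union of cluster spans over
the assembly length per genome. Dotplot exports one midpoint pair per
ortholog and one link per cluster, deterministically sorted.

## Telomeric repeats

The scanner slides the 24-nt query (TTAGGG)₄ (and its reverse complement)
over every position, vectorized as 24 shifted equality comparisons; a full
window is a hit at ≤ 2 mismatches and identity > 75%, and truncated windows
at contig edges are allowed down to 75% query coverage. Overlapping hits per
strand collapse into maximal runs; runs < 400 bp apart merge strand-agnostically
into one ITS record (merging is order-invariant); records within
`terminal_end_window = 1000` bp of a contig end are terminal, the rest
interstitial. The end-window cutoff is this package's convention; there is
no standard value. The same scanner accepts any user-supplied
satellite consensus via the `motif`/`units` parameters.

## Synthetic data: what it emulates, what it does not

One master seed drives labeled substreams (`substream(seed, stage)`), so
each stage is reproducible in isolation and every artifact is byte-stable
under its seed.

*Genomes.* Defaults simulate the benchmark condition: 4 contigs × 125
genes (~2 Mb), 40 planted clusters with sizes uniform on 2–10 (the data
model admits up to 64), genes of 2–6 exons (120–300 bp, codon-aligned),
lognormal intron lengths (median ≈ 500 bp, long tail past 5 kb) and
lognormal intergenic spacers (median ≈ 1100 bp) — the intergenic
distribution is a modeling choice, exposed as a parameter. Arrays grow by
serial duplication: each event copies the youngest gene (or, with
probability 0.1, a block of 2–3 adjacent genes) next to its source, then
mutates the copy codon-aware — synonymous proposals always accepted,
nonsynonymous with probability ω = 0.2, stops rejected — until NG86 dS to
its parent reaches `ds_step = 0.03`. Older duplicates therefore sit at
larger rank distance, and true pair divergence is the duplication-tree path
length × step (recorded per pair, alongside dS recomputed from the emitted
CDS). Introns drift with 5% substitutions and occasional indels per event,
so duplicate pairs are typically `exons_conserved`. With ≤ 10 copies per
array the maximum planted protein divergence stays ≈ 5%, within the
detection filter's reach by construction.

*Reads.* Long reads sample uniformly with lognormal lengths (mean 25 kb)
and errors split 60/20/20 substitution/insertion/deletion at a 5% default
rate — a generic long-read error profile, not a pore-level model. True
origins are emitted as primary PAF rows. Short-read hit tables place 100-nt
reads uniformly on orthogroup consensus sequences at 20× per gene copy.

*Count matrices.* Per-species counts are Poisson(3); amplified orthogroups
have the group-A rate multiplied by the fold (default 4). The depth
experiment plants copy numbers {1, 2, 5, 10} with a designated single-copy
subset.

*Telomeres.* Arrays of 4–40 units with a 2% per-unit mismatch rate, planted
terminally and interstitially; truth records mark arrays whose every 24-nt
window stays within 2 mismatches (recoverable by construction) and group
arrays < 400 bp apart (expected to merge).

*Synteny.* A gene-order genome pair built by shuffling conserved segments
(16–24 genes; the chaining rule only needs ≥ 5) with 30% inversion,
rejection-sampled so no two genes from different segments are chainable —
planted segments are exactly the recoverable clusters.

What passing these tests does **not** show about real data: no repeats or
low-complexity sequence (real seeds collide more; a real search needs
masking), no haplotype mixture (allelic duplicates are assumed resolved
upstream), clean uniform read coverage (real depth has GC and mappability
structure), independent Poisson family sizes (real orthogroup counts are
overdispersed and phylogenetically correlated), and divergence generated
under the same codon process the estimator assumes.

## Benchmark problem sizes

The planted-truth benchmarks run at: one 2 Mb / ~500 gene genome for
detection; 500 random instances (≤ 200 nodes) per clustering/chaining
oracle; 20 × 5000-orthogroup null tables and one 5000-orthogroup table with
100 planted amplifications for the screen; 2 species × 20 orthogroups at
20× per-copy depth for copy number; 100 random 300-nt pairs for the dS
oracle and ~180 planted pairs for the dS correlations; two chimera fixtures
and one genuine-gene fixture for the splitter; two 150 kb contigs of
planted arrays for the telomere scan; and a reduced full-pipeline run
executed twice for determinism. The whole set completes in about a minute
on one CPU.

## Known limitations

dS is a counting estimate, not ML; saturation is flagged, not modeled. The
realigner is splice-less by design and would under-score a query whose
match is itself interrupted by real introns on one side of a split. The
consensus is majority-rule, not an HMM emission, so consensus *sequences*
are not expected to match profile-HMM outputs (analyses here depend only on
depth over the consensus, which the benchmarks validate). The unspecific
mask compares consensuses ungapped; indel-shifted domain copies below 85%
ungapped identity escape masking. The screen treats species as exchangeable
within groups and ignores phylogeny — an assumption inherent to the binomial
design itself.
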