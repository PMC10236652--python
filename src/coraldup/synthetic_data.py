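"""Synthetic genomes, reads and orthogroup tables with planted ground truth.

The generator emulates the structures the pipeline is built to detect:

* contigs carrying planted tandem gene arrays grown by a serial
  birth-and-death process (each duplication copies the youngest gene, or a
  block of 2-3 adjacent genes, next to its source and then diverges until a
  target synonymous distance to its parent is reached) — older duplicates
  therefore sit at larger rank distance;
* intron/exon gene structures in which exons stay conserved between copies
  while introns accumulate substitutions and small indels;
* long reads with configurable length and error profile, and uniform
  short-read coverage over orthogroup consensus sequences proportional to the
  planted copy number;
* multi-species orthogroup count matrices with planted amplified families;
* telomeric (TTAGGG)n arrays, terminal and interstitial.

Every artifact is deterministic under the master seed; independent stages
draw from labeled substreams so one stage can be re-run in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import seqcore
from .annot_refine import AlignedBlock, SplicedAlignment
from .io_formats import GeneModel, ReadSpan, assign_ranks

_BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = sorted(
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in seqcore.STOP_CODONS
)


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(label.encode())])
    )


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Parameters and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Study conditions for every simulator stage (defaults are the target
    conditions of the planted-truth experiments)."""

    seed: int = 0
    # genome layout: ~2 Mb, ~500 genes, 40 planted clusters of size 2-10
    n_contigs: int = 4
    genes_per_contig: int = 125
    n_clusters: int = 40
    cluster_size_range: Tuple[int, int] = (2, 10)   # admissible support 2..64
    p_multi_gene_unit: float = 0.1
    # gene structure
    exon_count_range: Tuple[int, int] = (2, 6)
    exon_length_range: Tuple[int, int] = (120, 300)  # bp, rounded to codons
    intron_length_log_mu: float = 6.2
    intron_length_log_sigma: float = 0.8
    intergenic_log_mu: float = 7.0
    intergenic_log_sigma: float = 0.5
    # divergence per duplication event
    ds_step: float = 0.03
    omega: float = 0.2
    intron_sub_rate: float = 0.05
    intron_indel_prob: float = 0.5
    # long reads
    long_read_mean_length: int = 25000
    long_read_length_sigma: float = 0.25   # lognormal sigma (0 = fixed length)
    long_read_error_rate: float = 0.05
    long_read_coverage: float = 30.0
    error_split: Tuple[float, float, float] = (0.6, 0.2, 0.2)  # sub/ins/del
    # short reads over orthogroup consensus
    short_read_length: int = 100
    short_read_coverage: float = 20.0      # per gene copy
    depth_og_count: int = 24
    depth_single_copy_count: int = 8
    consensus_length: int = 1200           # nt
    copy_number_choices: Tuple[int, ...] = (1, 2, 5, 10)
    depth_species: int = 3
    # orthogroup count matrix (amplification screen)
    og_count: int = 5000
    n_species_group_a: int = 11
    n_species_group_b: int = 3
    baseline_copy_rate: float = 3.0
    n_amplified: int = 100
    amplification_fold: float = 4.0
    # telomeric arrays
    its_unit: str = "TTAGGG"
    its_unit_count_range: Tuple[int, int] = (4, 40)
    its_mismatch_rate: float = 0.02
    its_end_window: int = 1000

    def __post_init__(self) -> None:
        for name in ("p_multi_gene_unit", "intron_sub_rate", "intron_indel_prob",
                     "long_read_error_rate", "its_mismatch_rate", "omega"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo, hi = self.cluster_size_range
        if not (2 <= lo <= hi <= 64):
            raise ValueError("cluster sizes must lie in 2..64")
        if abs(sum(self.error_split) - 1.0) > 1e-9:
            raise ValueError("error_split must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth keyed to the emitted identifiers."""

    planted_clusters: List[List[str]] = field(default_factory=list)  # birth order
    gene_to_cluster: Dict[str, str] = field(default_factory=dict)
    target_ds: Dict[Tuple[str, str], float] = field(default_factory=dict)
    pairwise_true_ds: Dict[Tuple[str, str], float] = field(default_factory=dict)
    true_copy_number: Dict[str, Dict[str, float]] = field(default_factory=dict)
    amplified_og_ids: Dict[str, List[str]] = field(default_factory=dict)
    single_copy_og_ids: List[str] = field(default_factory=list)
    its_intervals: List[dict] = field(default_factory=list)
    syntenic_segments: List[List[Tuple[str, str]]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Coding-sequence mutation engine
# ---------------------------------------------------------------------------

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def mutate_cds_to_ds(cds: str, target_ds: float, omega: float,
                     rng: np.random.Generator) -> str:
    """Codon-aware mutation until the NG86 dS to the input reaches target_ds.

    Proposals are uniform single-nucleotide changes; synonymous changes are
    always accepted, nonsynonymous ones with probability ``omega``; changes
    creating a stop codon are rejected.
    """
    if target_ds <= 0:
        return cds
    cur = list(cds)
    n = len(cur)
    check_every = max(1, n // 600)
    accepted = 0
    max_accept = 4 * n  # saturation guard
    while accepted < max_accept:
        pos = int(rng.integers(n))
        base = "ACGT"[int(rng.integers(4))]
        if base == cur[pos]:
            continue
        ci = pos // 3
        old_codon = "".join(cur[3 * ci: 3 * ci + 3])
        new_codon = old_codon[: pos % 3] + base + old_codon[pos % 3 + 1:]
        if new_codon in seqcore.STOP_CODONS:
            continue
        synonymous = (seqcore._translate_codon(new_codon)
                      == seqcore._translate_codon(old_codon))
        if not synonymous and rng.random() >= omega:
            continue
        cur[pos] = base
        accepted += 1
        if accepted % check_every == 0:
            est = seqcore.ng86_ds(cds, "".join(cur))
            if est.saturated or est.dS >= target_ds:
                break
    return "".join(cur)


def _mutate_intron(intron: str, params: SimulationParams,
                   rng: np.random.Generator) -> str:
    seq = list(intron)
    n_sub = rng.binomial(len(seq), params.intron_sub_rate)
    for pos in rng.integers(0, len(seq), size=n_sub):
        seq[pos] = "ACGT"[int(rng.integers(4))]
    out = "".join(seq)
    if rng.random() < params.intron_indel_prob and len(out) > 80:
        size = int(rng.integers(1, max(2, len(out) // 5)))
        pos = int(rng.integers(0, len(out) - size))
        if rng.random() < 0.5:
            out = out[:pos] + out[pos + size:]
        else:
            out = out[:pos] + random_dna(size, rng) + out[pos:]
    return out


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass
class _SimGene:
    gene_id: str
    cds: str
    exon_lengths: List[int]           # transcript order, sum == len(cds)
    introns: List[str]                # transcript order
    strand: str
    birth_order: int = 0
    parent: Optional[int] = None      # birth_order of the duplication source


@dataclass
class SimulatedGenome:
    params: SimulationParams
    genome: Dict[str, str]
    models: Dict[str, List[GeneModel]]
    cds: Dict[str, str]
    proteins: Dict[str, str]
    truth: SyntheticTruth

    def all_models(self) -> List[GeneModel]:
        return [g for glist in self.models.values() for g in glist]


def _new_gene_structure(n_codons_rng: np.random.Generator,
                        params: SimulationParams) -> Tuple[str, List[int], List[str]]:
    rng = n_codons_rng
    n_exons = int(rng.integers(params.exon_count_range[0],
                               params.exon_count_range[1] + 1))
    lo, hi = params.exon_length_range
    exon_lengths = [3 * int(rng.integers(lo // 3, hi // 3 + 1))
                    for _ in range(n_exons)]
    cds = random_cds(sum(exon_lengths) // 3, rng)
    introns = []
    for _ in range(n_exons - 1):
        length = max(60, int(rng.lognormal(params.intron_length_log_mu,
                                           params.intron_length_log_sigma)))
        introns.append(random_dna(length, rng))
    return cds, exon_lengths, introns


def _duplicate_gene(src: _SimGene, gene_id: str, target_ds: float,
                    params: SimulationParams, rng: np.random.Generator,
                    birth_order: int) -> _SimGene:
    cds = mutate_cds_to_ds(src.cds, target_ds, params.omega, rng)
    introns = [_mutate_intron(i, params, rng) for i in src.introns]
    return _SimGene(gene_id, cds, list(src.exon_lengths), introns,
                    src.strand, birth_order, parent=src.birth_order)


def _grow_cluster(founder: _SimGene, size: int, params: SimulationParams,
                  rng: np.random.Generator, id_prefix: str) -> List[_SimGene]:
    """Serial birth-and-death growth: each event copies the most recent gene
    (or a 2-3 gene unit) and appends it adjacent to the source."""
    genes = [founder]
    event = 0
    while len(genes) < size:
        if len(genes) >= 2 and rng.random() < params.p_multi_gene_unit:
            unit = min(int(rng.integers(2, 4)), len(genes), size - len(genes))
            sources = genes[-unit:]
        else:
            sources = [genes[-1]]
        for src in sources:
            event += 1
            gid = f"{id_prefix}_{len(genes):02d}"
            genes.append(_duplicate_gene(src, gid, params.ds_step, params,
                                         rng, birth_order=len(genes)))
    return genes


def _tree_path_length(parents: Dict[int, Optional[int]], i: int, j: int) -> int:
    """Number of duplication events separating two genes on the cluster tree."""

    def chain(x: int) -> List[int]:
        out = [x]
        while parents[x] is not None:
            x = parents[x]  # type: ignore[assignment]
            out.append(x)
        return out

    depth_i = {node: d for d, node in enumerate(chain(i))}
    for d_j, node in enumerate(chain(j)):
        if node in depth_i:
            return depth_i[node] + d_j
    raise ValueError("genes on disjoint trees")


def _render_gene(gene: _SimGene, offset: int) -> Tuple[str, GeneModel]:
    """Emit the genomic sequence of a gene and its model at ``offset``."""
    parts, exon_rel = [], []
    cursor = pos = 0
    for i, elen in enumerate(gene.exon_lengths):
        parts.append(gene.cds[cursor: cursor + elen])
        exon_rel.append((pos, pos + elen))
        cursor += elen
        pos += elen
        if i < len(gene.introns):
            parts.append(gene.introns[i])
            pos += len(gene.introns[i])
    transcript_seq = "".join(parts)
    length = len(transcript_seq)
    if gene.strand == "+":
        genomic_seq = transcript_seq
        exons = [(offset + s, offset + e) for s, e in exon_rel]
    else:
        from Bio.Seq import Seq

        genomic_seq = str(Seq(transcript_seq).reverse_complement())
        exons = sorted((offset + length - e, offset + length - s)
                       for s, e in exon_rel)
    model = GeneModel(
        gene_id=gene.gene_id, contig="", start=offset, end=offset + length,
        strand=gene.strand, exons=exons, cds_length=len(gene.cds),
        utr_length=0,
    )
    return genomic_seq, model


def simulate_genome(params: SimulationParams) -> SimulatedGenome:
    """Simulate contigs with planted tandem arrays and background genes."""
    rng = substream(params.seed, "genome")
    truth = SyntheticTruth()

    # plan cluster sizes and per-contig composition
    lo, hi = params.cluster_size_range
    cluster_sizes = [int(rng.integers(lo, hi + 1)) for _ in range(params.n_clusters)]
    total_genes = params.n_contigs * params.genes_per_contig
    if sum(cluster_sizes) > total_genes:
        raise ValueError("contigs too short for the requested clusters")

    # build units (clusters + singletons) and deal them over contigs
    units: List[List[_SimGene]] = []
    for ci, size in enumerate(cluster_sizes):
        prefix = f"cl{ci:03d}"
        cds, exon_lengths, introns = _new_gene_structure(rng, params)
        founder = _SimGene(f"{prefix}_00", cds, exon_lengths, introns,
                           "+" if rng.random() < 0.5 else "-", 0)
        units.append(_grow_cluster(founder, size, params, rng, prefix))
    n_singletons = total_genes - sum(cluster_sizes)
    for si in range(n_singletons):
        cds, exon_lengths, introns = _new_gene_structure(rng, params)
        units.append([_SimGene(f"sg{si:04d}", cds, exon_lengths, introns,
                               "+" if rng.random() < 0.5 else "-", 0)])
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    # deal units to contigs, filling each to genes_per_contig genes
    genome: Dict[str, str] = {}
    models: Dict[str, List[GeneModel]] = {}
    cds_out: Dict[str, str] = {}
    unit_iter = iter(units)
    leftover: Optional[List[_SimGene]] = None
    for k in range(params.n_contigs):
        contig = f"ctg{k:02d}"
        parts: List[str] = []
        contig_models: List[GeneModel] = []
        offset = 0
        count = 0
        while count < params.genes_per_contig:
            unit = leftover if leftover is not None else next(unit_iter, None)
            leftover = None
            if unit is None:
                break
            if count + len(unit) > params.genes_per_contig and count > 0:
                leftover = unit
                break
            for gene in unit:
                spacer = max(200, int(rng.lognormal(params.intergenic_log_mu,
                                                    params.intergenic_log_sigma)))
                parts.append(random_dna(spacer, rng))
                offset += spacer
                seq, model = _render_gene(gene, offset)
                model.contig = contig
                parts.append(seq)
                offset += len(seq)
                contig_models.append(model)
                cds_out[gene.gene_id] = gene.cds
                count += 1
        tail = max(200, int(rng.lognormal(params.intergenic_log_mu,
                                          params.intergenic_log_sigma)))
        parts.append(random_dna(tail, rng))
        genome[contig] = "".join(parts)
        models[contig] = contig_models

    by_contig = assign_ranks([g for glist in models.values() for g in glist])

    # truth: clusters in birth order + pairwise dS recomputed from emitted CDS
    for ci, unit in enumerate(u for u in units if len(u) > 1):
        members = sorted(unit, key=lambda g: g.birth_order)
        ids = [g.gene_id for g in members]
        if ids[0] not in cds_out:  # unit was never placed (contig space ran out)
            continue
        cluster_id = ids[0].rsplit("_", 1)[0]
        truth.planted_clusters.append(ids)
        for gid in ids:
            truth.gene_to_cluster[gid] = cluster_id
        parents = {g.birth_order: g.parent for g in members}
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                key = (a.gene_id, b.gene_id)
                truth.target_ds[key] = params.ds_step * _tree_path_length(
                    parents, a.birth_order, b.birth_order)
                est = seqcore.ng86_ds(a.cds, b.cds, a.gene_id, b.gene_id)
                truth.pairwise_true_ds[key] = est.dS

    from Bio.Seq import Seq

    proteins = {gid: str(Seq(c).translate()) for gid, c in cds_out.items()}
    return SimulatedGenome(params, genome, by_contig, cds_out, proteins, truth)


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------

def _apply_read_errors(seq: str, rate: float, split: Tuple[float, float, float],
                       rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = sorted(rng.integers(0, len(seq), size=n_err), reverse=True)
    kinds = rng.choice(3, size=n_err, p=list(split))
    out = list(seq)
    for pos, kind in zip(positions, kinds):
        if pos >= len(out):  # an earlier deletion shortened the read
            if not out:
                break
            pos = len(out) - 1
        if kind == 0:   # substitution
            out[pos] = "ACGT"[int(rng.integers(4))]
        elif kind == 1:  # insertion
            out.insert(pos, "ACGT"[int(rng.integers(4))])
        else:            # deletion
            del out[pos]
    return "".join(out)


def simulate_long_reads(genome: Dict[str, str], params: SimulationParams,
                        ) -> Tuple[Dict[str, str], List[ReadSpan]]:
    """Sample error-prone long reads uniformly; return reads + true spans."""
    rng = substream(params.seed, "long_reads")
    reads: Dict[str, str] = {}
    spans: List[ReadSpan] = []
    if params.long_read_coverage <= 0:
        return reads, spans
    for contig in sorted(genome):
        seq = genome[contig]
        L = len(seq)
        mean_len = min(params.long_read_mean_length, max(1, L))
        n_reads = int(np.ceil(params.long_read_coverage * L / mean_len))
        for i in range(n_reads):
            if params.long_read_length_sigma > 0:
                length = int(rng.lognormal(np.log(params.long_read_mean_length),
                                           params.long_read_length_sigma))
            else:
                length = params.long_read_mean_length
            length = max(100, length)
            if length >= L:
                start, end = 0, L
            else:
                start = int(rng.integers(0, L - length + 1))
                end = start + length
            rid = f"read_{contig}_{i:05d}"
            reads[rid] = _apply_read_errors(seq[start:end],
                                            params.long_read_error_rate,
                                            params.error_split, rng)
            spans.append(ReadSpan(rid, contig, start, end, is_primary=True))
    return reads, spans


def spans_to_paf(spans: Sequence[ReadSpan], reads: Dict[str, str],
                 genome: Dict[str, str]) -> str:
    """Serialize true read origins as minimap2-dialect PAF (primary rows)."""
    lines = []
    for sp in spans:
        qlen = len(reads[sp.read_id])
        alen = sp.end - sp.start
        tag = "P" if sp.is_primary else "S"
        lines.append("\t".join(map(str, [
            sp.read_id, qlen, 0, qlen, "+", sp.contig, len(genome[sp.contig]),
            sp.start, sp.end, alen, alen, 60, f"tp:A:{tag}",
        ])))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Copy-number / orthogroup count simulation
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberSim:
    consensus: Dict[str, str]
    hits: pd.DataFrame                 # columns: species + 12-column dialect
    count_matrix: pd.DataFrame         # OG x species gene counts
    truth: SyntheticTruth


def simulate_copy_number_data(params: SimulationParams) -> CopyNumberSim:
    """Reads over OG consensus proportional to copy number + count matrix.

    The short-read hit table covers a compact set of "depth" orthogroups with
    copy numbers drawn from ``copy_number_choices`` (a designated subset is
    single-copy in every species).  The count matrix covers ``og_count``
    orthogroups with per-species Poisson counts; ``n_amplified`` of them have
    their group-A rate multiplied by ``amplification_fold``.
    """
    if params.og_count < 1:
        raise ValueError("og_count must be >= 1")
    rng = substream(params.seed, "copy_number")
    truth = SyntheticTruth()

    species_a = [f"spA{i:02d}" for i in range(params.n_species_group_a)]
    species_b = [f"spB{i:02d}" for i in range(params.n_species_group_b)]
    species = species_a + species_b

    # --- count matrix with planted amplifications ---
    og_ids = [f"OG{i:05d}" for i in range(params.og_count)]
    counts = rng.poisson(params.baseline_copy_rate,
                         size=(params.og_count, len(species))).astype(float)
    amplified = sorted(rng.choice(params.og_count,
                                  size=min(params.n_amplified, params.og_count),
                                  replace=False)) if params.n_amplified else []
    fold = params.amplification_fold
    if fold != 1.0:
        for row in amplified:
            counts[row, : len(species_a)] = rng.poisson(
                params.baseline_copy_rate * fold, size=len(species_a))
        truth.amplified_og_ids = {"A": [og_ids[r] for r in amplified], "B": []}
    else:
        truth.amplified_og_ids = {"A": [], "B": []}
    count_matrix = pd.DataFrame(counts, index=og_ids, columns=species)

    # --- depth orthogroups: consensus + uniform short reads ---
    depth_species = [f"dsp{i:02d}" for i in range(params.depth_species)]
    consensus: Dict[str, str] = {}
    rows = []
    choices = list(params.copy_number_choices)
    L, rl = params.consensus_length, params.short_read_length
    for i in range(params.depth_og_count):
        og = f"DOG{i:03d}"
        consensus[og] = random_dna(L, rng)
        single = i < params.depth_single_copy_count
        if single:
            truth.single_copy_og_ids.append(og)
        truth.true_copy_number[og] = {}
        for sp in depth_species:
            cn = 1 if single else choices[(i - params.depth_single_copy_count)
                                          % len(choices)]
            truth.true_copy_number[og][sp] = float(cn)
            n_reads = int(round(cn * params.short_read_coverage * L / rl))
            starts = rng.integers(0, L - rl + 1, size=n_reads)
            for k, s in enumerate(sorted(starts.tolist())):
                rows.append((sp, f"{sp}_{og}_r{k:05d}", og, 100.0, rl, 0, 0,
                             1, rl, s + 1, s + rl, 1e-50, 2.0 * rl))
    hits = pd.DataFrame(rows, columns=[
        "species", "qseqid", "sseqid", "pident", "length", "mismatch",
        "gapopen", "qstart", "qend", "sstart", "send", "evalue", "bitscore"])
    return CopyNumberSim(consensus, hits, count_matrix, truth)


# ---------------------------------------------------------------------------
# Telomeric arrays
# ---------------------------------------------------------------------------

def _make_its_array(n_units: int, unit: str, mismatch_rate: float,
                    rng: np.random.Generator) -> str:
    units = []
    for _ in range(n_units):
        u = list(unit)
        if rng.random() < mismatch_rate:
            pos = int(rng.integers(len(u)))
            u[pos] = "ACGT"[int(rng.integers(4))]
        units.append("".join(u))
    return "".join(units)


def plant_telomeric_arrays(genome: Dict[str, str], params: SimulationParams,
                           placements: Optional[Sequence[Tuple[str, int, int]]] = None,
                           ) -> Tuple[Dict[str, str], List[dict]]:
    """Overwrite genome stretches with (unit)n arrays; return truth records.

    ``placements`` is a list of (contig, position, n_units); when omitted,
    2-3 interior arrays plus one terminal array are planted per contig.
    Records carry the exact interval, terminal/interstitial classification
    (within ``its_end_window`` of a contig end) and a ``merge_group`` index
    linking arrays less than 400 bp apart.
    """
    rng = substream(params.seed, "telomere")
    unit = params.its_unit
    if placements is None:
        placements = []
        for contig in sorted(genome):
            L = len(genome[contig])
            for _ in range(int(rng.integers(2, 4))):
                n_units = int(rng.integers(*params.its_unit_count_range))
                pos = int(rng.integers(params.its_end_window + 1000,
                                       L - params.its_end_window - 1000
                                       - n_units * len(unit)))
                placements.append((contig, pos, n_units))
            placements.append((contig, 0,
                               int(rng.integers(*params.its_unit_count_range))))

    occupied: Dict[str, List[Tuple[int, int]]] = {}
    new_genome = {c: list(s) for c, s in genome.items()}
    records: List[dict] = []
    for contig, pos, n_units in placements:
        array = _make_its_array(n_units, unit, params.its_mismatch_rate, rng)
        start, end = pos, pos + len(array)
        if end > len(genome[contig]):
            raise ValueError(f"array at {contig}:{pos} exceeds contig bounds")
        for s, e in occupied.get(contig, []):
            if start < e and s < end:
                raise ValueError(f"overlapping array placement at {contig}:{pos}")
        occupied.setdefault(contig, []).append((start, end))
        new_genome[contig][start:end] = list(array)
        perfect = (unit * n_units)
        mismatches = sum(1 for a, b in zip(array, perfect) if a != b)
        terminal = (start < params.its_end_window
                    or end > len(genome[contig]) - params.its_end_window)
        records.append({"contig": contig, "start": start, "end": end,
                        "n_units": n_units, "mismatches": mismatches,
                        "terminal": terminal, "clean": _max_window_mismatch(
                            array, unit * 4) <= 2})
    # merge groups: arrays on a contig separated by < 400 bp
    records.sort(key=lambda r: (r["contig"], r["start"]))
    group = -1
    prev = None
    for rec in records:
        if (prev is None or rec["contig"] != prev["contig"]
                or rec["start"] - prev["end"] >= 400):
            group += 1
        rec["merge_group"] = group
        prev = rec
    return {c: "".join(s) for c, s in new_genome.items()}, records


def _max_window_mismatch(array: str, window_motif: str) -> int:
    w = len(window_motif)
    if len(array) < w:
        return sum(1 for a, b in zip(array, window_motif) if a != b)
    worst = 0
    for i in range(0, len(array) - w + 1, len(window_motif) // 4):
        mm = sum(1 for a, b in zip(array[i:i + w], window_motif) if a != b)
        worst = max(worst, mm)
    return worst


# ---------------------------------------------------------------------------
# Synteny fixture: one genome, segment-shuffled partner
# ---------------------------------------------------------------------------

def simulate_synteny_pair(params: SimulationParams, n_genes: int = 120,
                          n_contigs_a: int = 2, n_contigs_b: int = 2,
                          segment_size_range: Tuple[int, int] = (16, 24),
                          max_gap: int = 15,
                          ) -> Tuple[Dict[str, List[GeneModel]],
                                     Dict[str, List[GeneModel]],
                                     List[Tuple[str, str]],
                                     Dict[str, Dict[str, int]],
                                     List[List[Tuple[str, str]]]]:
    """Genome A plus a partner built by shuffling conserved gene segments.

    Every gene has a one-to-one ortholog.  Genome A is cut into conserved
    segments (never straddling a contig); genome B carries the segments in
    shuffled order, each possibly inverted, and segments are also kept whole
    on B contigs.  The shuffle is rejected and redrawn until no pair of genes
    from *different* segments is chainable (closer than ``max_gap`` ortholog
    ranks on both genomes), so the planted segments are exactly the
    recoverable syntenic clusters.  Returns (models_a, models_b, ortholog
    pairs, assembly lengths, true segments as ortholog-pair lists).
    """
    rng = substream(params.seed, "synteny")
    spacing = 10_000
    gene_len = 2_000

    a_ids = [f"ga{i:04d}" for i in range(n_genes)]
    b_ids = [f"gb{i:04d}" for i in range(n_genes)]
    pairs = list(zip(a_ids, b_ids))

    # A-side layout: contigs of equal gene counts; ranks are positional
    per_a = int(np.ceil(n_genes / n_contigs_a))
    a_contig = np.array([i // per_a for i in range(n_genes)])
    a_rank = np.array([i % per_a for i in range(n_genes)])

    # cut A into segments, never straddling an A contig boundary
    segments: List[List[int]] = []
    i = 0
    while i < n_genes:
        size = int(rng.integers(*segment_size_range))
        boundary = (int(a_contig[i]) + 1) * per_a
        size = min(size, boundary - i, n_genes - i)
        if boundary - (i + size) < segment_size_range[0]:
            size = min(boundary, n_genes) - i
        segments.append(list(range(i, i + size)))
        i += size
    n_seg = len(segments)
    seg_of = np.empty(n_genes, dtype=int)
    for si, seg in enumerate(segments):
        for g in seg:
            seg_of[g] = si

    per_b = int(np.ceil(n_genes / n_contigs_b))
    for _attempt in range(2000):
        perm = rng.permutation(n_seg)
        flips = rng.random(n_seg) < 0.3
        b_contig = np.empty(n_genes, dtype=int)
        b_rank = np.empty(n_genes, dtype=int)
        b_order: List[int] = []
        contig_idx, filled = 0, 0
        ok = True
        for k, seg_idx in enumerate(perm):
            seg = segments[seg_idx][::-1] if flips[k] else segments[seg_idx]
            if filled + len(seg) > per_b and contig_idx + 1 < n_contigs_b:
                contig_idx, filled = contig_idx + 1, 0
            elif filled + len(seg) > per_b:
                ok = False  # would straddle the last contig
                break
            for g in seg:
                b_contig[g] = contig_idx
                b_rank[g] = filled
                filled += 1
                b_order.append(g)
        if not ok:
            continue
        # exact check: no cross-segment pair may chain on both genomes
        clash = False
        for g in range(n_genes):
            for h in range(g + 1, n_genes):
                if seg_of[g] == seg_of[h]:
                    continue
                if (a_contig[g] == a_contig[h]
                        and abs(int(a_rank[g]) - int(a_rank[h])) < max_gap
                        and b_contig[g] == b_contig[h]
                        and abs(int(b_rank[g]) - int(b_rank[h])) < max_gap):
                    clash = True
                    break
            if clash:
                break
        if not clash:
            break
    else:  # pragma: no cover - parameters make acceptance near-certain
        raise RuntimeError("could not place segments without chainable overlap")

    def make_models(prefix: str, contig_arr: np.ndarray, rank_arr: np.ndarray,
                    ids: Sequence[str]) -> Dict[str, List[GeneModel]]:
        models = []
        for g, gid in enumerate(ids):
            contig = f"{prefix}_ctg{int(contig_arr[g]):02d}"
            pos = int(rank_arr[g]) * spacing + 1000
            models.append(GeneModel(gid, contig, pos, pos + gene_len, "+",
                                    [(pos, pos + gene_len)],
                                    cds_length=gene_len))
        return assign_ranks(models)

    models_a = make_models("A", a_contig, a_rank, a_ids)
    models_b = make_models("B", b_contig, b_rank, b_ids)
    true_segments = [[(a_ids[g], b_ids[g]) for g in seg] for seg in segments]
    lengths = {
        "A": {c: max(g.end for g in gl) + 5000 for c, gl in models_a.items()},
        "B": {c: max(g.end for g in gl) + 5000 for c, gl in models_b.items()},
    }
    return models_a, models_b, pairs, lengths, true_segments


# ---------------------------------------------------------------------------
# Chimeric-alignment fixtures for the intron splitter
# ---------------------------------------------------------------------------

def _segment_score(query_aa: str, target_aa: str,
                   scoring: Optional[seqcore.Scoring] = None) -> float:
    matrix = (scoring or seqcore.Scoring()).matrix
    return float(sum(matrix[a, b] for a, b in zip(query_aa, target_aa)))


def simulate_chimeric_alignment(params: SimulationParams, k: int = 2,
                                separation: int = 8000, n_codons: int = 250,
                                copy_ds: float = 0.05,
                                ) -> Tuple[Dict[str, str], SplicedAlignment,
                                           List[Tuple[int, int]]]:
    """Plant k single-exon tandem copies and a chimeric alignment over them.

    The query protein is the ancestor of the copies; the chimera distributes
    consecutive query segments over consecutive copies, separated by fake
    "introns" larger than any plausible real intron.  Returns the genome,
    the chimeric alignment and the true gene loci.
    """
    from Bio.Seq import Seq

    rng = substream(params.seed, f"chimera_k{k}")
    ancestor = random_cds(n_codons, rng)
    copies = [mutate_cds_to_ds(ancestor, copy_ds, params.omega, rng)
              for _ in range(k)]
    query = str(Seq(ancestor).translate())

    flank = 2000
    parts = [random_dna(flank, rng)]
    loci: List[Tuple[int, int]] = []
    pos = flank
    for i, cds in enumerate(copies):
        loci.append((pos, pos + len(cds)))
        parts.append(cds)
        pos += len(cds)
        if i < k - 1:
            parts.append(random_dna(separation, rng))
            pos += separation
    parts.append(random_dna(flank, rng))
    genome = {"chim_ctg": "".join(parts)}

    bounds = [round(j * n_codons / k) for j in range(k + 1)]
    blocks = []
    for i in range(k):
        qs, qe = bounds[i], bounds[i + 1]
        gstart = loci[i][0] + 3 * qs
        gend = loci[i][0] + 3 * qe
        copy_aa = str(Seq(copies[i]).translate())
        score = _segment_score(query[qs:qe], copy_aa[qs:qe])
        blocks.append(AlignedBlock(gstart, gend, qs, qe, score))
    aln = SplicedAlignment("chim_query", "chim_ctg", "+", query, blocks)
    return genome, aln, loci


def simulate_genuine_long_intron_gene(params: SimulationParams,
                                      intron_length: int = 6000,
                                      exon_codons: int = 150,
                                      ) -> Tuple[Dict[str, str], SplicedAlignment]:
    """A real two-exon gene with a long intron and its faithful alignment."""
    from Bio.Seq import Seq

    rng = substream(params.seed, "genuine_intron")
    cds = random_cds(2 * exon_codons, rng)
    exon1, exon2 = cds[: 3 * exon_codons], cds[3 * exon_codons:]
    intron = random_dna(intron_length, rng)
    flank = 2000
    genome_seq = random_dna(flank, rng) + exon1 + intron + exon2 + random_dna(flank, rng)
    genome = {"gen_ctg": genome_seq}
    query = str(Seq(cds).translate())
    b1 = AlignedBlock(flank, flank + len(exon1), 0, exon_codons,
                      _segment_score(query[:exon_codons], query[:exon_codons]))
    start2 = flank + len(exon1) + intron_length
    b2 = AlignedBlock(start2, start2 + len(exon2), exon_codons, 2 * exon_codons,
                      _segment_score(query[exon_codons:], query[exon_codons:]))
    return genome, SplicedAlignment("gen_query", "gen_ctg", "+", query, [b1, b2])
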