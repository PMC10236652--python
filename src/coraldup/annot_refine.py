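"""Tandem-array-aware annotation refinement.

Spliced protein-to-genome alignments that span several tandem gene copies
show up as chimeras with very large "introns".  ``split_long_introns``
recursively breaks such alignments inside every intron larger than 5 kb,
keeping the split whenever realigning the query on the two severed genomic
regions scores higher than the original chimera.  The module also implements
the mapping-noise filters applied to protein alignments and the gene
candidate filter applied after gene calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from . import seqcore
from .io_formats import GeneModel


@dataclass
class AlignedBlock:
    """One exon-like aligned segment (genomic and query aa coordinates)."""

    gstart: int
    gend: int
    qstart: int
    qend: int
    score: float

    def __post_init__(self) -> None:
        if self.gstart >= self.gend:
            raise ValueError("empty genomic block")


@dataclass
class SplicedAlignment:
    """A spliced alignment of one protein query against a genomic region.

    Blocks are monotone and non-overlapping on both sequences.  Implied
    introns are the gaps between consecutive blocks.  ``intron_penalty`` is
    charged per intron in ``total_score`` (0 by default: spliced aligners do
    not penalize introns at this stage).
    """

    query_id: str
    contig: str
    strand: str
    query_seq: str
    blocks: List[AlignedBlock]
    source_proteome: str = ""
    intron_penalty: float = 0.0

    def __post_init__(self) -> None:
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if cur.gstart < prev.gend or cur.qstart < prev.qend:
                raise ValueError("blocks not monotone")

    @property
    def total_score(self) -> float:
        return sum(b.score for b in self.blocks) - self.intron_penalty * len(self.introns())

    def introns(self) -> List[Tuple[int, int]]:
        """(start, end) of every implied intron, genomic half-open."""
        return [(a.gend, b.gstart) for a, b in zip(self.blocks, self.blocks[1:])]

    @property
    def genomic_span(self) -> Tuple[int, int]:
        return (self.blocks[0].gstart, self.blocks[-1].gend)

    @property
    def query_span(self) -> Tuple[int, int]:
        return (self.blocks[0].qstart, self.blocks[-1].qend)

    @property
    def is_intronless(self) -> bool:
        return len(self.blocks) <= 1


RealignFn = Callable[[str, str], float]


def _default_realigner(scoring: Optional[seqcore.Scoring] = None) -> RealignFn:
    def fn(protein: str, window: str) -> float:
        if len(window) < 3 or not protein:
            return 0.0
        return seqcore.realign_protein_to_dna(protein, window, scoring).score
    return fn


def split_long_introns(aln: SplicedAlignment, genome: Dict[str, str],
                       realigner: Optional[RealignFn] = None,
                       max_intron: int = 5000,
                       min_gain_fraction: float = 0.05) -> List[SplicedAlignment]:
    """Recursively split an alignment inside introns larger than ``max_intron``.

    For each qualifying intron (longest first) the full query span of the
    alignment is realigned against the two genomic sides, each extended to
    the intron midpoint.  The split is accepted when the summed realignment
    scores exceed the original score by more than ``min_gain_fraction``
    (relative margin guarding against chance local-alignment extension into
    intron sequence); accepted splits partition the blocks at the intron and
    the procedure recurses on both halves.
    """
    realigner = realigner or _default_realigner()
    contig_seq = genome.get(aln.contig)
    if contig_seq is None:
        raise KeyError(f"contig {aln.contig} absent from genome (alignment {aln.query_id})")

    candidates = sorted(
        ((end - start, i) for i, (start, end) in enumerate(aln.introns())
         if end - start > max_intron),
        key=lambda t: (-t[0], t[1]),
    )
    qs, qe = aln.query_span if aln.blocks else (0, 0)
    query = aln.query_seq[qs:qe]
    for _, i in candidates:
        intron_start = aln.blocks[i].gend
        intron_end = aln.blocks[i + 1].gstart
        mid = (intron_start + intron_end) // 2
        left_window = contig_seq[aln.blocks[0].gstart: mid]
        right_window = contig_seq[mid: aln.blocks[-1].gend]
        try:
            score_left = realigner(query, left_window)
            score_right = realigner(query, right_window)
        except Exception as exc:  # pragma: no cover - propagated with context
            raise RuntimeError(
                f"realigner failed for {aln.query_id} on {aln.contig}:"
                f"{intron_start}-{intron_end}") from exc
        if score_left + score_right > aln.total_score * (1.0 + min_gain_fraction):
            left = replace(aln, blocks=list(aln.blocks[: i + 1]))
            right = replace(aln, blocks=list(aln.blocks[i + 1:]))
            return (split_long_introns(left, genome, realigner, max_intron,
                                       min_gain_fraction)
                    + split_long_introns(right, genome, realigner, max_intron,
                                         min_gain_fraction))
    return [aln]


# ---------------------------------------------------------------------------
# Mapping-noise filters
# ---------------------------------------------------------------------------

def filter_intronless(alignments_by_proteome: Dict[str, List[SplicedAlignment]],
                      max_fraction: float = 0.40) -> Dict[str, List[SplicedAlignment]]:
    """Drop all intronless alignments of a proteome when they exceed 40%.

    The threshold applies per source proteome and is strict ("more than"):
    exactly 40% intronless alignments are kept.
    """
    out: Dict[str, List[SplicedAlignment]] = {}
    for proteome, alns in alignments_by_proteome.items():
        if not alns:
            out[proteome] = []
            continue
        n_intronless = sum(1 for a in alns if a.is_intronless)
        if n_intronless > max_fraction * len(alns):
            out[proteome] = [a for a in alns if not a.is_intronless]
        else:
            out[proteome] = list(alns)
    return out


def filter_unique_introns(alignments: Sequence[SplicedAlignment],
                          min_exons_covered: int = 10) -> List[SplicedAlignment]:
    """Drop alignments with a unique intron that span many known exons.

    An intron is unique when its exact genomic coordinates occur in exactly
    one alignment.  An alignment carrying at least one unique intron is
    removed if its genomic span contains at least ``min_exons_covered``
    distinct exon coordinates from the global exon set of all alignments.
    """
    intron_counts: Dict[Tuple[str, int, int], int] = {}
    exon_set = set()
    for aln in alignments:
        for s, e in aln.introns():
            intron_counts[(aln.contig, s, e)] = intron_counts.get((aln.contig, s, e), 0) + 1
        for b in aln.blocks:
            exon_set.add((aln.contig, b.gstart, b.gend))
    kept = []
    for aln in alignments:
        has_unique = any(intron_counts[(aln.contig, s, e)] == 1
                         for s, e in aln.introns())
        if not has_unique:
            kept.append(aln)
            continue
        span_s, span_e = aln.genomic_span
        covered = sum(1 for (c, s, e) in exon_set
                      if c == aln.contig and s >= span_s and e <= span_e)
        if covered < min_exons_covered:
            kept.append(aln)
    return kept


def filter_gene_candidates(genes: Sequence[GeneModel],
                           homology_species_counts: Dict[str, int],
                           min_cds_aa: int = 100,
                           min_cds_utr_ratio: float = 0.75,
                           te_like: Optional[Dict[str, bool]] = None) -> List[GeneModel]:
    """Post-prediction gene candidate filter, applied in the stated order.

    1. single-exon genes with CDS length <= ``min_cds_aa`` amino acids are
       removed;
    2. of the remaining genes, only those with homology in more than one
       species, or spliced genes with CDS/UTR length ratio >=
       ``min_cds_utr_ratio``, are kept;
    3. genes carrying a precomputed transposable-element flag are removed
       (the flag is consumed, never computed here).
    """
    te_like = te_like or {}
    kept = []
    for g in genes:
        if te_like.get(g.gene_id, False):
            continue
        cds_aa = g.cds_length / 3.0
        if g.n_exons == 1 and cds_aa <= min_cds_aa:
            continue
        n_species = homology_species_counts.get(g.gene_id, 0)
        spliced = g.n_exons > 1
        ratio_ok = spliced and (
            g.utr_length == 0 or g.cds_length / g.utr_length >= min_cds_utr_ratio
        )
        if n_species > 1 or ratio_ok:
            kept.append(g)
    return kept
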