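"""Sequence-level primitives.

Pairwise local protein alignment (Smith-Waterman contract, BLOSUM62 with
BLAST-style affine gaps), six-frame translated realignment of a protein
against a genomic window, the Nei-Gojobori (1986) synonymous substitution
rate with Jukes-Cantor correction, and exon/intron structure comparison of
duplicate gene pairs.

A gap of length L costs ``gap_open + gap_extend * L`` (defaults 11 + L),
matching the convention of common protein search tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import GeneModel

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD_TABLE.stop_codons)
_BASES = "ACGT"


@dataclass
class Scoring:
    """Substitution matrix plus affine gap costs."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # first gap residue costs open+extend so a length-L gap costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass
class AlignmentResult:
    """A local alignment as monotone, non-overlapping aligned blocks.

    ``blocks`` is a list of ``((q_start, q_end), (t_start, t_end))`` pairs of
    0-based half-open intervals, monotone on both sequences.  For translated
    alignments, target coordinates are genomic bp and ``strand``/``frame``
    record the frame of the best alignment.
    """

    query_id: str
    target_id: str
    score: float
    blocks: List[Tuple[Tuple[int, int], Tuple[int, int]]] = field(default_factory=list)
    identity_pct: float = 0.0
    strand: str = "+"
    frame: int = 0

    @property
    def is_empty(self) -> bool:
        return not self.blocks

    def query_span(self) -> Tuple[int, int]:
        if self.is_empty:
            return (0, 0)
        return (self.blocks[0][0][0], self.blocks[-1][0][1])

    def target_span(self) -> Tuple[int, int]:
        if self.is_empty:
            return (0, 0)
        starts = [b[1][0] for b in self.blocks]
        ends = [b[1][1] for b in self.blocks]
        return (min(starts), max(ends))


def _check_protein(seq: str, name: str, alphabet: str) -> None:
    for i, aa in enumerate(seq):
        if aa not in alphabet:
            raise ValueError(f"{name}: invalid residue {aa!r} at position {i}")


def align_local(protein_a: str, protein_b: str,
                scoring: Optional[Scoring] = None,
                query_id: str = "a", target_id: str = "b") -> AlignmentResult:
    """Optimal local alignment of two protein sequences (Smith-Waterman).

    Returns score 0 with no blocks when no positive-scoring alignment exists.
    """
    scoring = scoring or Scoring()
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    alphabet = str(scoring.matrix.alphabet)
    _check_protein(protein_a, "protein_a", alphabet)
    _check_protein(protein_b, "protein_b", alphabet)
    aligner = _aligner(scoring.matrix_name, scoring.gap_open, scoring.gap_extend)
    score = aligner.score(protein_a, protein_b)
    if score <= 0:
        return AlignmentResult(query_id, target_id, 0.0)
    aln = aligner.align(protein_a, protein_b)[0]
    blocks = [((int(q[0]), int(q[1])), (int(t[0]), int(t[1])))
              for q, t in zip(aln.aligned[0], aln.aligned[1])]
    matches = aligned = 0
    for (qs, qe), (ts, te) in blocks:
        for i in range(qe - qs):
            aligned += 1
            if protein_a[qs + i] == protein_b[ts + i]:
                matches += 1
    identity = 100.0 * matches / aligned if aligned else 0.0
    return AlignmentResult(query_id, target_id, float(score), blocks, identity)


def align_score(protein_a: str, protein_b: str,
                scoring: Optional[Scoring] = None) -> float:
    """Local alignment score only (no traceback; used by bulk searches)."""
    scoring = scoring or Scoring()
    aligner = _aligner(scoring.matrix_name, scoring.gap_open, scoring.gap_extend)
    return float(aligner.score(protein_a, protein_b))


# ---------------------------------------------------------------------------
# Translated realignment
# ---------------------------------------------------------------------------

def _translate_frame(dna: str, frame: int) -> str:
    sub = dna[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def realign_protein_to_dna(protein: str, genomic_window: str,
                           scoring: Optional[Scoring] = None,
                           query_id: str = "query",
                           target_id: str = "window") -> AlignmentResult:
    """Best of six splice-less translated local alignments.

    The window is translated in all three frames on both strands; the
    highest-scoring protein-vs-translation local alignment wins (ties by
    + strand first, then lowest frame).  Block target coordinates are mapped
    back to genomic bp on the forward strand of the window.
    """
    if len(genomic_window) < 3:
        raise ValueError("genomic window shorter than 3 bp")
    scoring = scoring or Scoring()
    best: Optional[AlignmentResult] = None
    length = len(genomic_window)
    rc = str(Seq(genomic_window).reverse_complement())
    for strand, seq in (("+", genomic_window), ("-", rc)):
        for frame in range(3):
            trans = _translate_frame(seq, frame)
            if not trans:
                continue
            res = align_local(protein, trans, scoring, query_id, target_id)
            if best is None or res.score > best.score:
                res.strand, res.frame = strand, frame
                best = res
    assert best is not None
    # map aa coordinates on the translation back to genomic bp
    genomic_blocks = []
    for (q, t) in best.blocks:
        ts, te = t
        if best.strand == "+":
            gs, ge = best.frame + 3 * ts, best.frame + 3 * te
        else:
            gs, ge = length - best.frame - 3 * te, length - best.frame - 3 * ts
        genomic_blocks.append((q, (gs, ge)))
    best.blocks = genomic_blocks
    return best


# ---------------------------------------------------------------------------
# NG86 dS / dN
# ---------------------------------------------------------------------------

@dataclass
class DsEstimate:
    """Synonymous/nonsynonymous site and difference counts plus corrected rates."""

    id_a: str
    id_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    dS: float
    dN: float
    saturated: bool = False
    n_codons: int = 0


def _translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous; changes to stop codons count as
    nonsynonymous, so the two counts always sum to 3.
    """
    aa = _translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and _translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _codon_pair_diffs(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over substitution pathways.

    All orderings of the differing positions are considered; pathways passing
    through a stop codon are excluded (all pathways are kept if every one is
    blocked).  Each retained pathway weighs equally.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if (cur in STOP_CODONS or nxt in STOP_CODONS):
                nd += 1.0
            elif _translate_codon(cur) == _translate_codon(nxt):
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


def _jukes_cantor(p: float) -> Tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    if p <= 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def ng86_ds(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> DsEstimate:
    """Nei-Gojobori (1986) pathway counting with Jukes-Cantor correction.

    Input CDS must be aligned (equal length, multiple of 3).  Codon columns
    containing a gap character are skipped pairwise; internal stop codons are
    rejected.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS length mismatch")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length not a multiple of 3")
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    n_total = len(cds_a) // 3
    for i in range(n_total):
        ca = cds_a[3 * i: 3 * i + 3]
        cb = cds_b[3 * i: 3 * i + 3]
        if "-" in ca or "-" in cb:
            continue
        for name, codon in (("a", ca), ("b", cb)):
            if codon in STOP_CODONS and i < n_total - 1:
                raise ValueError(f"internal stop codon in cds_{name} at codon {i}")
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue  # terminal stop: not counted
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _codon_pair_diffs(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    dS, sat_s = _jukes_cantor(ps)
    dN, _ = _jukes_cantor(pn)
    return DsEstimate(id_a, id_b, S, N, Sd, Nd, dS, dN,
                      saturated=sat_s, n_codons=n_codons)


def codon_alignment_from_proteins(cds_a: str, cds_b: str,
                                  scoring: Optional[Scoring] = None) -> Tuple[str, str]:
    """Codon alignment back-propagated from the local protein alignment.

    Only matched protein blocks are kept (gap columns dropped pairwise), so
    the returned CDS pair is equal-length and codon-aligned.
    """
    prot_a = str(Seq(cds_a).translate()).rstrip("*")
    prot_b = str(Seq(cds_b).translate()).rstrip("*")
    aln = align_local(prot_a, prot_b, scoring)
    out_a, out_b = [], []
    for (qs, qe), (ts, te) in aln.blocks:
        out_a.append(cds_a[3 * qs: 3 * qe])
        out_b.append(cds_b[3 * ts: 3 * te])
    return "".join(out_a), "".join(out_b)


def ng86_ds_pair(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b",
                 scoring: Optional[Scoring] = None) -> DsEstimate:
    """NG86 dS of two unaligned CDS via protein-alignment back-propagation."""
    a, b = codon_alignment_from_proteins(cds_a, cds_b, scoring)
    return ng86_ds(a, b, id_a, id_b)


# ---------------------------------------------------------------------------
# Gene structure comparison
# ---------------------------------------------------------------------------

@dataclass
class StructureComparison:
    id_a: str
    id_b: str
    exon_count_equal: bool
    exon_lengths_equal: bool
    intron_lengths_equal: bool
    conservation_class: str  # fully_conserved | exons_conserved | divergent


def compare_structures(gene_a: GeneModel, gene_b: GeneModel) -> StructureComparison:
    """Compare exon/intron length vectors positionally, both oriented 5'->3'."""
    for g in (gene_a, gene_b):
        if not g.exons:
            raise ValueError(f"gene {g.gene_id} has no exons")

    def oriented(g: GeneModel) -> Tuple[List[int], List[int]]:
        ex, intr = g.exon_lengths(), g.intron_lengths()
        if g.strand == "-":
            ex, intr = ex[::-1], intr[::-1]
        return ex, intr

    ex_a, in_a = oriented(gene_a)
    ex_b, in_b = oriented(gene_b)
    count_eq = len(ex_a) == len(ex_b)
    ex_eq = count_eq and ex_a == ex_b
    in_eq = count_eq and in_a == in_b
    if ex_eq and in_eq:
        cls = "fully_conserved"
    elif ex_eq:
        cls = "exons_conserved"
    else:
        cls = "divergent"
    return StructureComparison(gene_a.gene_id, gene_b.gene_id,
                               count_eq, ex_eq, in_eq, cls)
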