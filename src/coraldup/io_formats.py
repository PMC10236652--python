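"""Readers/writers for the external formats the pipeline touches.

Coordinate convention: every interval held in memory is 0-based half-open.
GFF3 (1-based inclusive) is converted at the parsing/writing boundary and the
conversion is bijective on valid input.  Gene ranks are 0-based indices per
contig, ordered by start position (ties broken by gene id).
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A located gene with ordered exons and a per-contig rank.

    ``start``/``end`` and every exon interval are 0-based half-open genomic
    coordinates.  ``rank`` is the 0-based index of the gene on its contig
    ordered by start (ties by gene id).
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: List[Tuple[int, int]]
    rank: int = -1
    cds_length: int = 0
    utr_length: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s},{e})")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene bounds"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def intron_lengths(self) -> List[int]:
        """Intron lengths in genomic order."""
        return [
            self.exons[i + 1][0] - self.exons[i][1]
            for i in range(len(self.exons) - 1)
        ]

    def exon_lengths(self) -> List[int]:
        return [e - s for s, e in self.exons]


@dataclass
class SimilarityHit:
    """One row of an all-vs-all protein similarity table (filtered later)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    q_aln_span: int
    s_aln_span: int
    identity_pct: float
    is_self: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.evalue) or self.evalue < 0:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: bad e-value")
        if self.q_aln_span < 0 or self.s_aln_span < 0:
            raise ValueError("negative alignment span")


@dataclass
class ReadSpan:
    """A long-read alignment interval on the reference (0-based half-open)."""

    read_id: str
    contig: str
    start: int
    end: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"read {self.read_id}: start ({self.start}) >= end ({self.end})"
            )


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, with published defaults.

    Serializes to / from a flat ``key = value`` text file and round-trips
    losslessly.
    """

    # tandem duplicate detection
    max_evalue: float = 1e-20
    min_coverage: float = 0.8          # fraction of the smaller protein aligned
    max_gene_distance: int = 10        # rank distance on the contig
    # annotation refinement
    max_intron: int = 5000             # bp; introns above this trigger a split
    split_min_gain_fraction: float = 0.05
    intronless_max_fraction: float = 0.40
    unique_intron_min_exons: int = 10
    min_cds_aa: int = 100
    min_cds_utr_ratio: float = 0.75
    # orthogroup consensus / copy number
    odseq_sd_threshold: float = 1.5
    consensus_length_excess: float = 0.15
    mask_window_aa: int = 30
    mask_min_identity: float = 0.85
    unspecific_flag_fraction: float = 0.5
    single_copy_min_species: int = 13  # of 14 (S - 1 rule)
    depth_outlier_mad: float = 3.0
    short_read_length: int = 100
    # amplification screen
    screen_alpha: float = 0.001
    # synteny
    synteny_min_ortholog_genes: int = 5
    synteny_max_gap: int = 15
    synteny_min_size: int = 5
    # telomere scan
    telomere_motif: str = "TTAGGG"
    telomere_units: int = 4
    telomere_max_mismatch: int = 2
    telomere_min_identity: float = 0.75
    telomere_min_coverage: float = 0.75
    its_merge_gap: int = 400
    terminal_end_window: int = 1000
    # alignment scoring
    gap_open: int = 11
    gap_extend: int = 1
    # randomness
    seed: int = 0

    _RANGES = {
        "min_coverage": (0.0, 1.0),
        "split_min_gain_fraction": (0.0, 1.0),
        "intronless_max_fraction": (0.0, 1.0),
        "min_cds_utr_ratio": (0.0, 10.0),
        "consensus_length_excess": (0.0, 1.0),
        "mask_min_identity": (0.0, 1.0),
        "unspecific_flag_fraction": (0.0, 1.0),
        "telomere_min_identity": (0.0, 1.0),
        "telomere_min_coverage": (0.0, 1.0),
        "screen_alpha": (0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"config {name}={v} outside [{lo}, {hi}]")

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        import ast

        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"config line {lineno}: missing '='")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in valid:
                raise FormatError(f"config line {lineno}: unknown key {key!r}")
            kwargs[key] = ast.literal_eval(value.strip())
        return cls(**kwargs)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(col: str) -> Dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source) if "\n" in source or "\t" in source else open(source)
    return source


def assign_ranks(genes: Iterable[GeneModel]) -> Dict[str, List[GeneModel]]:
    """Group genes by contig and assign per-contig ranks (start, then id)."""
    by_contig: Dict[str, List[GeneModel]] = {}
    seen: Dict[str, str] = {}
    for g in genes:
        if g.gene_id in seen and seen[g.gene_id] != g.contig:
            raise ValueError(f"gene id {g.gene_id} appears on two contigs")
        seen[g.gene_id] = g.contig
        by_contig.setdefault(g.contig, []).append(g)
    for contig, glist in by_contig.items():
        glist.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(glist):
            g.rank = i
    return by_contig


def parse_gene_models(source: Union[str, TextIO]) -> Dict[str, List[GeneModel]]:
    """Parse GFF3 into GeneModels grouped by contig, ranks assigned.

    One representative transcript per gene: the mRNA with the longest total
    CDS (ties by transcript id).  Coordinates are converted from 1-based
    inclusive to 0-based half-open.
    """
    stream = _as_stream(source)
    genes: Dict[str, dict] = {}            # gene_id -> info
    transcripts: Dict[str, dict] = {}      # mrna_id -> info
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        contig, _, ftype, start_s, end_s, _, strand, _, attr_s = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(f"GFF3 line {lineno}: non-numeric coordinates") from None
        start, end = start1 - 1, end1  # to 0-based half-open
        attrs = _parse_attributes(attr_s)
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise FormatError(f"GFF3 line {lineno}: gene without ID")
            genes[gid] = {"contig": contig, "start": start, "end": end,
                          "strand": strand, "mrnas": []}
        elif ftype == "mRNA":
            tid, parent = attrs.get("ID"), attrs.get("Parent")
            if tid is None or parent is None:
                raise FormatError(f"GFF3 line {lineno}: mRNA without ID/Parent")
            transcripts[tid] = {"gene": parent, "exons": [], "cds": [], "utr": 0}
            if parent in genes:
                genes[parent]["mrnas"].append(tid)
        elif ftype in ("exon", "CDS"):
            parent = attrs.get("Parent")
            if parent is None or parent not in transcripts:
                raise FormatError(f"GFF3 line {lineno}: {ftype} with unknown Parent")
            key = "exons" if ftype == "exon" else "cds"
            transcripts[parent][key].append((start, end))
        # other feature types are ignored

    out: List[GeneModel] = []
    for gid, info in genes.items():
        best = None
        for tid in info["mrnas"]:
            tr = transcripts[tid]
            cds_len = sum(e - s for s, e in tr["cds"])
            key = (-cds_len, tid)
            if best is None or key < best[0]:
                best = (key, tid, cds_len)
        if best is None:
            continue  # gene without transcript: skipped
        _, tid, cds_len = best
        tr = transcripts[tid]
        exons = sorted(tr["exons"] or tr["cds"])
        exon_len = sum(e - s for s, e in exons)
        model = GeneModel(
            gene_id=gid, contig=info["contig"], start=info["start"],
            end=info["end"], strand=info["strand"], exons=exons,
            cds_length=cds_len, utr_length=max(0, exon_len - cds_len),
        )
        out.append(model)
    return assign_ranks(out)


def write_gene_models(by_contig: Dict[str, List[GeneModel]], path: str) -> None:
    """Write GeneModels back to GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(by_contig):
            for g in sorted(by_contig[contig], key=lambda g: (g.start, g.gene_id)):
                base = f"{contig}\tcoraldup\t"
                fh.write(f"{base}gene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}\n")
                tid = g.gene_id + ".t1"
                fh.write(f"{base}mRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                         f"ID={tid};Parent={g.gene_id}\n")
                for s, e in g.exons:
                    fh.write(f"{base}exon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                             f"Parent={tid}\n")
                    fh.write(f"{base}CDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                             f"Parent={tid}\n")


# ---------------------------------------------------------------------------
# Similarity tables (12-column local-alignment tabular dialect)
# ---------------------------------------------------------------------------

_TAB12 = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
          "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def parse_similarity_table(source: Union[str, TextIO]) -> List[SimilarityHit]:
    """Parse the 12-column tabular local-alignment format, order preserved."""
    stream = _as_stream(source)
    hits: List[SimilarityHit] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise FormatError(
                f"similarity table line {lineno}: expected 12 columns, got {len(cols)}"
            )
        try:
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
            evalue = float(cols[10])
            bitscore = float(cols[11])
            pident = float(cols[2])
        except ValueError:
            raise FormatError(
                f"similarity table line {lineno}: non-numeric field"
            ) from None
        hits.append(SimilarityHit(
            query_id=cols[0], subject_id=cols[1], evalue=evalue,
            bitscore=bitscore,
            q_aln_span=abs(qend - qstart) + 1,
            s_aln_span=abs(send - sstart) + 1,
            identity_pct=pident, is_self=cols[0] == cols[1],
        ))
    return hits


def write_similarity_table(rows: Sequence[dict], path: str) -> None:
    """Write 12-column tabular rows (dicts keyed by the standard field names)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(row[k]) for k in _TAB12) + "\n")


# ---------------------------------------------------------------------------
# Read spans (PAF or 4-column TSV)
# ---------------------------------------------------------------------------

def parse_read_spans(source: Union[str, TextIO],
                     drop_secondary: bool = True) -> List[ReadSpan]:
    """Parse PAF (minimap2 dialect) or 4-column TSV read alignments.

    PAF rows carry a ``tp:A:P``/``tp:A:S`` tag; when ``drop_secondary`` only
    primary alignments are kept.  Rows of the TSV dialect are all primary.
    """
    stream = _as_stream(source)
    spans: List[ReadSpan] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 12:  # PAF
            read_id, contig = cols[0], cols[5]
            start, end = int(cols[7]), int(cols[8])
            is_primary = True
            for tag in cols[12:]:
                if tag.startswith("tp:A:"):
                    is_primary = tag[5:] == "P"
        elif len(cols) == 4:  # TSV dialect
            read_id, contig = cols[0], cols[1]
            start, end = int(cols[2]), int(cols[3])
            is_primary = True
        else:
            raise FormatError(f"read span line {lineno}: unrecognized column count")
        if start >= end:
            raise FormatError(f"read span line {lineno}: start >= end")
        if drop_secondary and not is_primary:
            continue
        spans.append(ReadSpan(read_id, contig, start, end, is_primary))
    return spans


# ---------------------------------------------------------------------------
# FASTA (thin Biopython wrappers keeping plain dict interfaces)
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Generic TSV report round-trip
# ---------------------------------------------------------------------------

def write_table(rows: Sequence[dict], columns: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_table(path: str) -> List[Dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]
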