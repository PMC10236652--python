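"""Telomeric repeat detection and interstitial telomeric sequence (ITS) calls.

A (TTAGGG)4 query (24 nt) is slid exhaustively over both strands; a window
is a hit when it covers at least 75% of the query with identity above 75%
and at most two mismatches.  Overlapping hits on a strand collapse into
maximal runs, runs less than 400 bp apart merge into a single ITS record,
and records within a fixed window of a contig end are classified terminal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Seq import Seq


@dataclass
class RawTelomericHit:
    contig: str
    start: int
    end: int
    strand: str
    n_windows: int
    mean_identity: float


@dataclass
class ITSRecord:
    contig: str
    start: int
    end: int
    n_windows_merged: int
    mean_identity: float
    classification: str = ""   # terminal | interstitial


def _window_mismatches(seq: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Mismatch count of the pattern at every full-window offset."""
    w = len(pattern)
    n = len(seq) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    mism = np.zeros(n, dtype=np.int32)
    for k in range(w):
        mism += (seq[k: k + n] != pattern[k]).astype(np.int32)
    return mism


def scan_telomeric_windows(genome: Mapping[str, str], motif: str = "TTAGGG",
                           units: int = 4, max_mismatch: int = 2,
                           min_identity: float = 0.75,
                           min_coverage: float = 0.75,
                           ) -> List[RawTelomericHit]:
    """Exhaustive sliding-window scan for the repeated motif on both strands.

    Full windows of ``units * len(motif)`` nt are hits when mismatches <=
    ``max_mismatch`` and identity > ``min_identity``; truncated windows at
    contig edges are allowed down to ``min_coverage`` of the query length.
    Overlapping hits on the same strand are merged into maximal runs.
    """
    if not motif:
        raise ValueError("empty motif")
    query = motif * units
    w = len(query)
    min_w = int(np.ceil(min_coverage * w))
    queries = {"+": query, "-": str(Seq(query).reverse_complement())}
    hits: List[RawTelomericHit] = []
    for contig in sorted(genome):
        seq = np.frombuffer(genome[contig].upper().encode(), dtype=np.uint8)
        for strand, q in queries.items():
            pattern = np.frombuffer(q.encode(), dtype=np.uint8)
            windows: List[Tuple[int, int, float]] = []
            mism = _window_mismatches(seq, pattern)
            for i in np.nonzero((mism <= max_mismatch)
                                & ((w - mism) / w > min_identity))[0]:
                windows.append((int(i), int(i) + w, (w - int(mism[i])) / w))
            # truncated edge windows (query overhanging a contig end)
            for trunc in range(min_w, min(w, len(seq))):
                tail = seq[-trunc:]
                mm = int((tail != pattern[:trunc]).sum())
                if mm <= max_mismatch and (trunc - mm) / trunc > min_identity:
                    windows.append((len(seq) - trunc, len(seq), (trunc - mm) / trunc))
                head = seq[:trunc]
                mm = int((head != pattern[-trunc:]).sum())
                if mm <= max_mismatch and (trunc - mm) / trunc > min_identity:
                    windows.append((0, trunc, (trunc - mm) / trunc))
            # collapse overlapping windows into maximal runs
            windows.sort()
            run: Optional[List] = None
            for s, e, ident in windows:
                if run is not None and s <= run[1]:
                    run[1] = max(run[1], e)
                    run[2].append(ident)
                else:
                    if run is not None:
                        hits.append(RawTelomericHit(
                            contig, run[0], run[1], strand, len(run[2]),
                            float(np.mean(run[2]))))
                    run = [s, e, [ident]]
            if run is not None:
                hits.append(RawTelomericHit(contig, run[0], run[1], strand,
                                            len(run[2]), float(np.mean(run[2]))))
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.strand))
    return hits


def merge_into_its(raw_hits: Sequence[RawTelomericHit],
                   max_gap: int = 400) -> List[ITSRecord]:
    """Strand-agnostic chaining of hits less than ``max_gap`` bp apart."""
    records: List[ITSRecord] = []
    by_contig: Dict[str, List[RawTelomericHit]] = {}
    for h in raw_hits:
        by_contig.setdefault(h.contig, []).append(h)
    for contig in sorted(by_contig):
        hits = sorted(by_contig[contig], key=lambda h: (h.start, h.end))
        cur: Optional[List] = None
        for h in hits:
            if cur is not None and h.start - cur[1] < max_gap:
                cur[1] = max(cur[1], h.end)
                cur[2] += h.n_windows
                cur[3].append((h.mean_identity, h.n_windows))
            else:
                if cur is not None:
                    records.append(_finish_record(contig, cur))
                cur = [h.start, h.end, h.n_windows,
                       [(h.mean_identity, h.n_windows)]]
        if cur is not None:
            records.append(_finish_record(contig, cur))
    return records


def _finish_record(contig: str, cur: List) -> ITSRecord:
    weights = sum(n for _, n in cur[3])
    ident = sum(i * n for i, n in cur[3]) / weights if weights else 0.0
    return ITSRecord(contig, cur[0], cur[1], cur[2], ident)


def classify_terminal(records: Sequence[ITSRecord],
                      contig_lengths: Mapping[str, int],
                      end_window: int = 1000) -> List[ITSRecord]:
    """Terminal when within ``end_window`` of a contig end, else interstitial."""
    if end_window < 0:
        raise ValueError("end_window must be >= 0")
    out = []
    for rec in records:
        clen = contig_lengths[rec.contig]
        if rec.start < 0 or rec.end > clen:
            raise ValueError(
                f"ITS record {rec.contig}:{rec.start}-{rec.end} beyond contig bounds")
        terminal = rec.start < end_window or rec.end > clen - end_window
        rec.classification = "terminal" if terminal else "interstitial"
        out.append(rec)
    return out


def records_to_bed(records: Sequence[ITSRecord]) -> str:
    lines = [f"{r.contig}\t{r.start}\t{r.end}\tITS\t{r.mean_identity:.3f}\t"
             f"{r.classification}" for r in records]
    return "\n".join(lines) + ("\n" if lines else "")
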