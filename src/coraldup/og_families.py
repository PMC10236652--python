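"""Orthogroup-level machinery.

Consensus construction with outlier removal and unspecific-region masking,
selection of the single-copy orthogroup set used for depth normalization,
read-depth gene copy-number estimation, the binomial gene-family
amplification screen (with Benjamini-Hochberg FDR control), and
domain-prevalence orthogroup classification.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class OrthogroupTable:
    """og_id -> species -> member gene ids, plus TE/unspecific flags."""

    memberships: Dict[str, Dict[str, List[str]]]
    te_like: Dict[str, bool] = field(default_factory=dict)
    unspecific: Dict[str, bool] = field(default_factory=dict)

    def count_matrix(self) -> pd.DataFrame:
        species = sorted({sp for m in self.memberships.values() for sp in m})
        data = {og: [len(m.get(sp, [])) for sp in species]
                for og, m in self.memberships.items()}
        return pd.DataFrame.from_dict(data, orient="index",
                                      columns=species).sort_index()


@dataclass
class ConsensusProfile:
    og_id: str
    consensus: str
    masked_intervals: List[Tuple[int, int]] = field(default_factory=list)
    n_sequences_used: int = 0
    outliers_removed: List[str] = field(default_factory=list)
    n_passes: int = 1  # outlier-removal passes that actually ran

    def unmasked_length(self) -> int:
        return len(self.consensus) - sum(e - s for s, e in self.masked_intervals)


@dataclass
class CopyNumberEstimate:
    og_id: str
    species: str
    raw_depth: float
    norm_factor: float
    copy_number: float


@dataclass
class AmplificationResult:
    og_id: str
    count_group_a: int
    count_group_b: int
    expected_ratio: float
    p_value: float
    p_adjusted: float
    call: str  # amplified_A | amplified_B | none


# ---------------------------------------------------------------------------
# Outlier removal and consensus
# ---------------------------------------------------------------------------

def _check_msa(msa: Sequence[Tuple[str, str]]) -> None:
    lengths = {len(seq) for _, seq in msa}
    if len(lengths) > 1:
        raise ValueError("ragged MSA: rows have different lengths")


def _pairwise_distance_scores(msa: Sequence[Tuple[str, str]]) -> np.ndarray:
    """Mean pairwise distance of each row (fraction of differing columns;
    gap-vs-residue counts as a difference, both-gap columns are skipped)."""
    arr = np.array([list(seq) for _, seq in msa])
    n = len(msa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            informative = ~((a == GAP) & (b == GAP))
            total = int(informative.sum())
            d = float((a != b)[informative].sum()) / total if total else 0.0
            dist[i, j] = dist[j, i] = d
    return dist.sum(axis=1) / max(1, n - 1)


def remove_outlier_sequences(msa: Sequence[Tuple[str, str]],
                             sd_threshold: float = 1.5,
                             ) -> Tuple[List[Tuple[str, str]], List[str]]:
    """Drop rows whose mean pairwise distance exceeds mean + threshold*SD.

    Below 3 rows the MSA is returned unchanged (no distribution to judge
    against).
    """
    _check_msa(msa)
    if len(msa) < 3:
        return list(msa), []
    scores = _pairwise_distance_scores(msa)
    cutoff = scores.mean() + sd_threshold * scores.std()
    kept, removed = [], []
    for (name, seq), score in zip(msa, scores):
        if score > cutoff + 1e-12:
            removed.append(name)
        else:
            kept.append((name, seq))
    if not kept:  # degenerate: everything equally distant
        return list(msa), []
    return kept, removed


def _majority_consensus(msa: Sequence[Tuple[str, str]],
                        max_gap_fraction: float = 0.5) -> str:
    arr = np.array([list(seq) for _, seq in msa])
    n = arr.shape[0]
    out = []
    for col in arr.T:
        gaps = int((col == GAP).sum())
        if gaps / n >= max_gap_fraction:
            continue
        residues = col[col != GAP]
        counts = Counter(residues.tolist())
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def build_consensus(og_id: str, msa: Sequence[Tuple[str, str]],
                    sd_threshold: float = 1.5,
                    max_gap_fraction: float = 0.5,
                    length_excess: float = 0.15) -> ConsensusProfile:
    """Majority-rule consensus with a conditional second outlier pass.

    Columns with at least ``max_gap_fraction`` gaps are dropped.  When the
    consensus exceeds the median ungapped input length by more than
    ``length_excess`` of that median (a symptom of a gappy alignment pulled
    apart by stragglers), outlier removal runs once more and the consensus is
    rebuilt.
    """
    _check_msa(msa)
    if not msa:
        raise ValueError(f"orthogroup {og_id}: empty MSA")
    kept, removed = remove_outlier_sequences(msa, sd_threshold)
    if not kept:
        raise ValueError(f"orthogroup {og_id}: no sequences left after filtering")
    consensus = _majority_consensus(kept, max_gap_fraction)
    n_passes = 1
    median_len = float(np.median([len(seq.replace(GAP, "")) for _, seq in kept]))
    if len(consensus) - median_len > length_excess * median_len:
        n_passes = 2
        kept2, removed2 = remove_outlier_sequences(kept, sd_threshold)
        if kept2:
            kept = kept2
            removed = removed + removed2
            consensus = _majority_consensus(kept, max_gap_fraction)
    return ConsensusProfile(og_id, consensus, [], len(kept), removed,
                            n_passes=n_passes)


# ---------------------------------------------------------------------------
# Unspecific-region masking
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _window_hits(seq_a: str, seq_b: str, window: int, min_identity: float,
                 ) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int]]]:
    """Ungapped sliding-window hits between two sequences (all diagonals)."""
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    la, lb = len(a), len(b)
    if la < window or lb < window:
        return [], []
    need = int(math.ceil(min_identity * window))
    kernel = np.ones(window, dtype=int)
    hits_a, hits_b = [], []
    for offset in range(-(lb - window), la - window + 1):
        # diagonal: a[i] vs b[i - offset]
        a_lo = max(0, offset)
        a_hi = min(la, lb + offset)
        if a_hi - a_lo < window:
            continue
        eq = (a[a_lo:a_hi] == b[a_lo - offset: a_hi - offset]).astype(int)
        sums = np.convolve(eq, kernel, mode="valid")
        for i in np.nonzero(sums >= need)[0]:
            s = a_lo + int(i)
            hits_a.append((s, s + window))
            hits_b.append((s - offset, s - offset + window))
    return hits_a, hits_b


def mask_unspecific_regions(consensus_set: Mapping[str, ConsensusProfile],
                            window: int = 30, min_identity: float = 0.85,
                            flag_fraction: float = 0.5,
                            ) -> Dict[str, ConsensusProfile]:
    """Mask windows shared at high identity between different consensuses.

    Any ``window``-length stretch of one consensus matching another consensus
    at >= ``min_identity`` (ungapped) is masked on both sides; orthogroups
    whose masked fraction exceeds ``flag_fraction`` are tagged unspecific by
    the caller (the masked intervals are recorded on the profiles here).
    """
    ids = sorted(consensus_set)
    masks: Dict[str, List[Tuple[int, int]]] = {og: [] for og in ids}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            hits_a, hits_b = _window_hits(consensus_set[a].consensus,
                                          consensus_set[b].consensus,
                                          window, min_identity)
            masks[a].extend(hits_a)
            masks[b].extend(hits_b)
    out = {}
    for og in ids:
        prof = consensus_set[og]
        out[og] = ConsensusProfile(prof.og_id, prof.consensus,
                                   _merge_intervals(masks[og]),
                                   prof.n_sequences_used,
                                   list(prof.outliers_removed))
    return out


def unspecific_flags(consensus_set: Mapping[str, ConsensusProfile],
                     flag_fraction: float = 0.5) -> Dict[str, bool]:
    flags = {}
    for og, prof in consensus_set.items():
        masked = sum(e - s for s, e in prof.masked_intervals)
        flags[og] = bool(prof.consensus) and masked / len(prof.consensus) > flag_fraction
    return flags


# ---------------------------------------------------------------------------
# Single-copy set and copy-number estimation
# ---------------------------------------------------------------------------

def select_single_copy_ogs(count_matrix: pd.DataFrame,
                           min_species_exact_one: Optional[int] = None,
                           exclude: Optional[Mapping[str, bool]] = None,
                           ) -> List[str]:
    """Orthogroups with exactly one copy in nearly all species.

    Defaults to the S-1 rule: at least (number of species - 1) species must
    have exactly one gene; TE-like/unspecific orthogroups are excluded.
    """
    if count_matrix.shape[1] < 2:
        raise ValueError("need at least 2 species columns")
    if min_species_exact_one is None:
        min_species_exact_one = count_matrix.shape[1] - 1
    exclude = exclude or {}
    n_exact_one = (count_matrix == 1).sum(axis=1)
    kept = count_matrix.index[(n_exact_one >= min_species_exact_one)
                              & ~count_matrix.index.map(
                                  lambda og: exclude.get(og, False))]
    return sorted(kept)


def _unique_best_hits(read_hits: pd.DataFrame) -> pd.DataFrame:
    """Per read keep the single best-scoring hit; score ties drop the read."""
    best = read_hits.groupby("qseqid")["bitscore"].transform("max")
    at_best = read_hits[read_hits["bitscore"] >= best - 1e-9]
    n_best = at_best.groupby("qseqid")["sseqid"].transform("size")
    return at_best[n_best == 1]


def _unmasked_overlap(start: int, end: int,
                      masked: Sequence[Tuple[int, int]]) -> int:
    covered = end - start
    for ms, me in masked:
        covered -= max(0, min(end, me) - max(start, ms))
    return max(0, covered)


def estimate_copy_numbers(read_hits: pd.DataFrame,
                          consensus_set: Mapping[str, ConsensusProfile],
                          single_copy_ogs: Sequence[str],
                          species: str = "",
                          outlier_mad: float = 3.0,
                          ) -> Dict[str, CopyNumberEstimate]:
    """Depth-based copy number per orthogroup for one species.

    raw depth = aligned bases over unmasked consensus positions / unmasked
    length.  The normalization factor is the pooled depth over the
    single-copy set after discarding single-copy orthogroups whose raw depth
    deviates more than ``outlier_mad`` MADs from the set median; the copy
    number is the ratio.
    """
    hits = _unique_best_hits(read_hits)
    aligned: Dict[str, float] = {og: 0.0 for og in consensus_set}
    for og, sstart, send in zip(hits["sseqid"], hits["sstart"], hits["send"]):
        if og not in consensus_set:
            continue
        lo, hi = (sstart - 1, send) if sstart <= send else (send - 1, sstart)
        aligned[og] += _unmasked_overlap(lo, hi,
                                         consensus_set[og].masked_intervals)
    raw = {}
    for og, prof in consensus_set.items():
        length = prof.unmasked_length()
        raw[og] = aligned[og] / length if length else 0.0

    sc = [og for og in single_copy_ogs if og in raw]
    if not sc:
        raise ValueError("empty single-copy set after outlier removal")
    depths = np.array([raw[og] for og in sc])
    med = float(np.median(depths))
    mad = float(stats.median_abs_deviation(depths)) if len(depths) > 1 else 0.0
    if mad > 0:
        retained = [og for og, d in zip(sc, depths)
                    if abs(d - med) <= outlier_mad * mad]
    else:
        retained = list(sc)
    if not retained:
        raise ValueError("empty single-copy set after outlier removal")
    total_bases = sum(aligned[og] for og in retained)
    total_len = sum(consensus_set[og].unmasked_length() for og in retained)
    norm = total_bases / total_len
    if norm <= 0:
        raise ValueError("single-copy normalization depth is zero")
    return {og: CopyNumberEstimate(og, species, raw[og], norm, raw[og] / norm)
            for og in consensus_set}


# ---------------------------------------------------------------------------
# Amplification screen
# ---------------------------------------------------------------------------

def binomial_pvalue(x: int, n: int, p0: float, method: str = "minlike") -> float:
    """Exact binomial test p-value.

    ``minlike``: sum of all outcome probabilities not exceeding P(X=x)
    (the classic two-sided exact test).  ``central``: twice the smaller tail,
    capped at 1.
    """
    if not 0 <= x <= n:
        raise ValueError("x outside [0, n]")
    if method == "minlike":
        pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
        p = float(pmf[pmf <= pmf[x] * (1.0 + 1e-7)].sum())
    elif method == "central":
        lower = float(stats.binom.cdf(x, n, p0))
        upper = float(stats.binom.sf(x - 1, n, p0))
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(1.0, p)


def amplification_screen(count_matrix: pd.DataFrame,
                         group_a: Sequence[str], group_b: Sequence[str],
                         alpha: float = 0.001,
                         method: str = "minlike",
                         exclude: Optional[Mapping[str, bool]] = None,
                         ) -> List[AmplificationResult]:
    """Binomial screen for families amplified in one species group.

    Under the null of equal per-species gene numbers, the group-A share of an
    orthogroup's genes is Binomial(n, |A|/(|A|+|B|)).  P-values are BH
    corrected; an orthogroup is called amplified in the group whose observed
    share exceeds the expectation when the adjusted p-value is below
    ``alpha``.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("species groups overlap")
    if not set_a or not set_b:
        raise ValueError("both species groups must be non-empty")
    exclude = exclude or {}
    p0 = len(set_a) / (len(set_a) + len(set_b))

    rows = []
    for og in count_matrix.index:
        if exclude.get(og, False):
            continue
        xa = int(count_matrix.loc[og, list(set_a)].sum())
        xb = int(count_matrix.loc[og, list(set_b)].sum())
        n = xa + xb
        if n == 0:
            continue
        rows.append((og, xa, xb, binomial_pvalue(xa, n, p0, method)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for (og, xa, xb, p), padj in zip(rows, p_adj):
        call = "none"
        if padj < alpha:
            share = xa / (xa + xb)
            call = "amplified_A" if share > p0 else (
                "amplified_B" if share < p0 else "none")
        results.append(AmplificationResult(og, xa, xb, p0, p, float(padj), call))
    return results


# ---------------------------------------------------------------------------
# Domain-prevalence classification
# ---------------------------------------------------------------------------

def classify_og_by_domain(og_table: OrthogroupTable,
                          gene_domains: Mapping[str, Iterable[str]],
                          rules: Sequence[Tuple[str, Iterable[str], float]],
                          ) -> Dict[str, List[str]]:
    """Label orthogroups by domain prevalence among member genes.

    ``rules`` is a list of (label, domain ids, min_prevalence); an orthogroup
    gets every label whose domains occur in at least ``min_prevalence`` of
    its member genes.
    """
    known_genes = {g for m in og_table.memberships.values()
                   for genes in m.values() for g in genes}
    for gid in gene_domains:
        if gid not in known_genes:
            logger.warning("domain table gene %s not in any orthogroup", gid)
    labels: Dict[str, List[str]] = {}
    for og, members in og_table.memberships.items():
        genes = [g for glist in members.values() for g in glist]
        out = []
        for label, domains, min_prev in rules:
            dset = set(domains)
            carrying = sum(1 for g in genes if dset & set(gene_domains.get(g, ())))
            if genes and carrying / len(genes) >= min_prev:
                out.append(label)
        labels[og] = out
    return labels
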