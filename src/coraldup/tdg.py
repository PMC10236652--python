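"""Tandem gene duplication detection, clustering and long-read validation.

Two genes are tandem duplicates when their proteins match (e-value <= 1e-20
with at least 80% of the smaller protein aligned) and they sit on the same
contig no more than 10 gene ranks apart.  Duplicate pairs are grouped into
clusters by single linkage.  A pair of adjacent cluster members is validated
when at least one primary long-read alignment completely contains both gene
intervals; a cluster is validated when one read contains every member.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import seqcore
from .io_formats import GeneModel, ReadSpan, SimilarityHit

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for BLOSUM62 with affine gaps 11/1
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class TandemPair:
    gene_a: str            # ordered by rank
    gene_b: str
    contig: str
    rank_distance: int
    evalue: float
    bitscore: float
    coverage: float

    def __post_init__(self) -> None:
        if self.rank_distance < 1:
            raise ValueError("rank_distance must be >= 1")


@dataclass
class TDGCluster:
    cluster_id: str
    contig: str
    members: List[str]                 # rank-ordered
    span: Tuple[int, int]
    validated_pairs: int = 0
    n_adjacent_pairs: int = 0
    cluster_validated: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# All-vs-all protein similarity (seeded Smith-Waterman search)
# ---------------------------------------------------------------------------

def bit_score(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2.0)


def karlin_altschul_evalue(raw_score: float, query_len: int, db_len: int) -> float:
    return query_len * db_len * 2.0 ** (-bit_score(raw_score))


def similarity_search(proteins: Mapping[str, str], seed_k: int = 5,
                      min_shared_seeds: int = 3,
                      scoring: Optional[seqcore.Scoring] = None,
                      ) -> List[SimilarityHit]:
    """All-vs-all protein search: exact k-mer seeding, then local alignment.

    Pairs sharing at least ``min_shared_seeds`` distinct k-mers are aligned
    with Smith-Waterman; e-values follow the Karlin-Altschul formula with the
    total residue count of the set as database length.  One hit per unordered
    pair is emitted.
    """
    scoring = scoring or seqcore.Scoring()
    ids = sorted(proteins)
    db_len = sum(len(proteins[i]) for i in ids)
    index: Dict[str, List[str]] = {}
    for pid in ids:
        seq = proteins[pid]
        for kmer in {seq[i:i + seed_k] for i in range(len(seq) - seed_k + 1)}:
            index.setdefault(kmer, []).append(pid)
    shared: Counter = Counter()
    for kmer, members in index.items():
        if len(members) < 2 or len(members) > 50:  # uninformative seed
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                shared[(members[i], members[j])] += 1
    hits: List[SimilarityHit] = []
    for (a, b), n_seeds in sorted(shared.items()):
        if n_seeds < min_shared_seeds:
            continue
        aln = seqcore.align_local(proteins[a], proteins[b], scoring, a, b)
        if aln.is_empty:
            continue
        qs, qe = aln.query_span()
        ts, te = aln.target_span()
        evalue = karlin_altschul_evalue(aln.score, len(proteins[a]), db_len)
        hits.append(SimilarityHit(
            query_id=a, subject_id=b, evalue=evalue, bitscore=bit_score(aln.score),
            q_aln_span=qe - qs, s_aln_span=te - ts,
            identity_pct=aln.identity_pct))
    return hits


# ---------------------------------------------------------------------------
# Pair filtering and clustering
# ---------------------------------------------------------------------------

def filter_similarity(hits: Iterable[SimilarityHit],
                      protein_lengths: Mapping[str, int],
                      max_evalue: float = 1e-20,
                      min_cov: float = 0.8) -> Dict[Tuple[str, str], SimilarityHit]:
    """Keep undirected gene pairs with a strong, near-full-length match.

    A pair is kept when some row has e-value <= ``max_evalue`` and its
    aligned span on the smaller protein covers at least ``min_cov`` of it.
    Self hits are ignored; of several supporting rows the one with the
    highest bitscore is retained.
    """
    kept: Dict[Tuple[str, str], SimilarityHit] = {}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        for gid in (hit.query_id, hit.subject_id):
            if gid not in protein_lengths:
                raise KeyError(f"no protein length for {gid}")
        len_q = protein_lengths[hit.query_id]
        len_s = protein_lengths[hit.subject_id]
        smaller_span = hit.q_aln_span if len_q <= len_s else hit.s_aln_span
        if hit.evalue > max_evalue or smaller_span < min_cov * min(len_q, len_s):
            continue
        key = tuple(sorted((hit.query_id, hit.subject_id)))
        if key not in kept or hit.bitscore > kept[key].bitscore:
            kept[key] = hit
    return kept


def _model_index(gene_models: Mapping[str, List[GeneModel]]) -> Dict[str, GeneModel]:
    return {g.gene_id: g for glist in gene_models.values() for g in glist}


def find_tandem_pairs(pairs: Mapping[Tuple[str, str], SimilarityHit],
                      gene_models: Mapping[str, List[GeneModel]],
                      max_gene_distance: int = 10) -> List[TandemPair]:
    """Retain similar pairs co-located within ``max_gene_distance`` ranks."""
    index = _model_index(gene_models)
    out: List[TandemPair] = []
    for (a, b), hit in sorted(pairs.items()):
        for gid in (a, b):
            if gid not in index:
                raise KeyError(f"gene {gid} absent from gene models")
        ga, gb = index[a], index[b]
        if ga.contig != gb.contig:
            continue
        dist = abs(ga.rank - gb.rank)
        if dist == 0 or dist > max_gene_distance:
            continue
        first, second = (a, b) if ga.rank < gb.rank else (b, a)
        len_small = min(hit.q_aln_span, hit.s_aln_span)
        out.append(TandemPair(first, second, ga.contig, dist,
                              hit.evalue, hit.bitscore, len_small))
    return out


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:  # deterministic roots
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_single_linkage(tandem_pairs: Sequence[TandemPair],
                           gene_models: Optional[Mapping[str, List[GeneModel]]] = None,
                           ) -> List[TDGCluster]:
    """Connected components of the tandem-pair graph.

    Cluster ids are the lexicographically smallest member prefixed ``tdg_``;
    members are rank-ordered when models are supplied, else id-ordered.
    """
    uf = _UnionFind()
    contig_of: Dict[str, str] = {}
    for p in tandem_pairs:
        uf.union(p.gene_a, p.gene_b)
        contig_of[p.gene_a] = contig_of[p.gene_b] = p.contig
    components: Dict[str, List[str]] = {}
    for gene in contig_of:
        components.setdefault(uf.find(gene), []).append(gene)
    index = _model_index(gene_models) if gene_models else {}
    clusters = []
    for members in components.values():
        if len(members) < 2:
            continue
        if index:
            members.sort(key=lambda g: (index[g].rank, g))
            span = (min(index[g].start for g in members),
                    max(index[g].end for g in members))
        else:
            members.sort()
            span = (0, 0)
        clusters.append(TDGCluster(
            cluster_id="tdg_" + min(members), contig=contig_of[members[0]],
            members=members, span=span))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


# ---------------------------------------------------------------------------
# Long-read validation
# ---------------------------------------------------------------------------

class _ReadIndex:
    """Per-contig reads sorted by start with running max end, for O(log n)
    'is some read interval containing [s, e)?' queries."""

    def __init__(self, spans: Sequence[ReadSpan]) -> None:
        self.by_contig: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        grouped: Dict[str, List[Tuple[int, int]]] = {}
        for sp in spans:
            grouped.setdefault(sp.contig, []).append((sp.start, sp.end))
        for contig, ivals in grouped.items():
            ivals.sort()
            starts = np.array([s for s, _ in ivals])
            ends = np.maximum.accumulate(np.array([e for _, e in ivals]))
            self.by_contig[contig] = (starts, ends)

    def contains(self, contig: str, start: int, end: int) -> bool:
        if contig not in self.by_contig:
            return False
        starts, max_ends = self.by_contig[contig]
        i = int(np.searchsorted(starts, start, side="right"))
        return bool(i > 0 and max_ends[i - 1] >= end)


def validate_with_reads(clusters: Sequence[TDGCluster],
                        read_spans: Sequence[ReadSpan],
                        gene_models: Mapping[str, List[GeneModel]],
                        ) -> Tuple[List[TDGCluster], Dict[str, float]]:
    """Flag adjacent pairs / whole clusters contained in single reads.

    Containment is strict on the aligned read interval: the read must cover
    each gene interval entirely.  Returns the annotated clusters and summary
    fractions of validated pairs and clusters.
    """
    index = _model_index(gene_models)
    primary = [sp for sp in read_spans if sp.is_primary]
    known_contigs = set(gene_models)
    for sp in primary:
        if sp.contig not in known_contigs:
            logger.warning("read %s on unknown contig %s skipped",
                           sp.read_id, sp.contig)
    ridx = _ReadIndex([sp for sp in primary if sp.contig in known_contigs])

    n_pairs = n_validated_pairs = n_validated_clusters = 0
    for cluster in clusters:
        genes = [index[g] for g in cluster.members]
        validated = 0
        for ga, gb in zip(genes, genes[1:]):
            n_pairs += 1
            s, e = min(ga.start, gb.start), max(ga.end, gb.end)
            if ridx.contains(cluster.contig, s, e):
                validated += 1
        cluster.validated_pairs = validated
        cluster.n_adjacent_pairs = len(genes) - 1
        n_validated_pairs += validated
        s = min(g.start for g in genes)
        e = max(g.end for g in genes)
        cluster.cluster_validated = ridx.contains(cluster.contig, s, e)
        n_validated_clusters += cluster.cluster_validated
    summary = {
        "n_pairs": float(n_pairs),
        "pair_fraction": n_validated_pairs / n_pairs if n_pairs else 0.0,
        "n_clusters": float(len(clusters)),
        "cluster_fraction": (n_validated_clusters / len(clusters)
                             if clusters else 0.0),
    }
    return list(clusters), summary


# ---------------------------------------------------------------------------
# Cluster statistics / duplicate ageing report
# ---------------------------------------------------------------------------

_DISTANCE_BINS = ("1", "2", "3", ">=4")


def _distance_bin(d: int) -> str:
    return str(d) if d <= 3 else ">=4"


def cluster_statistics(clusters: Sequence[TDGCluster],
                       ds_estimates: Mapping[Tuple[str, str], float],
                       gene_models: Mapping[str, List[GeneModel]]) -> dict:
    """Cluster size distribution and dS stratified by rank distance.

    ``ds_estimates`` maps unordered member-pair keys to dS values; pairs
    without an estimate are left out of the dS section.  Spearman correlation
    between dS and rank distance quantifies the age-vs-spacing trend (older
    duplicates, larger dS, sit farther apart under serial duplication).
    """
    report: dict = {"n_clusters": len(clusters)}
    if not clusters:
        report.update({"size_histogram": {}, "mean_size": 0.0, "max_size": 0,
                       "ds_by_distance": {}, "spearman_ds_distance": float("nan")})
        return report
    sizes = [c.size for c in clusters]
    report["size_histogram"] = dict(sorted(Counter(sizes).items()))
    report["mean_size"] = float(np.mean(sizes))
    report["max_size"] = int(max(sizes))

    index = _model_index(gene_models)
    ds_by_bin: Dict[str, List[float]] = {b: [] for b in _DISTANCE_BINS}
    xs, ys = [], []
    for cluster in clusters:
        for i in range(cluster.size):
            for j in range(i + 1, cluster.size):
                a, b = cluster.members[i], cluster.members[j]
                key = tuple(sorted((a, b)))
                ds = ds_estimates.get(key, ds_estimates.get((key[1], key[0])))
                if ds is None or not math.isfinite(ds):
                    continue
                dist = abs(index[a].rank - index[b].rank)
                ds_by_bin[_distance_bin(dist)].append(ds)
                xs.append(dist)
                ys.append(ds)
    report["ds_by_distance"] = {
        b: {"n": len(v), "mean": float(np.mean(v)) if v else float("nan"),
            "median": float(np.median(v)) if v else float("nan")}
        for b, v in ds_by_bin.items()}
    if len(set(xs)) > 1:
        rho = stats.spearmanr(xs, ys).statistic
    else:
        rho = float("nan")
    report["spearman_ds_distance"] = float(rho)
    return report
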