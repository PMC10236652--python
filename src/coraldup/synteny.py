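"""Synteny chaining between two annotated genomes.

Orthologous gene pairs are chained into syntenic clusters: pairs on the same
contig pair belong to one cluster when fewer than 15 other ortholog-bearing
genes separate them on both genomes (orientation-agnostic single linkage);
clusters need at least 5 pairs.  Coverage of each assembly by the union of
cluster spans and dotplot/circular-link exports complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .io_formats import GeneModel


@dataclass
class SyntenyCluster:
    cluster_id: str
    contig_a: str
    contig_b: str
    pairs: List[Tuple[str, str]]          # ordered by rank on genome A
    span_a: Tuple[int, int]
    span_b: Tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.pairs)


def reduce_to_best_pairs(candidates: Sequence[Tuple[str, str, float]],
                         ) -> List[Tuple[str, str]]:
    """Reduce many-to-many ortholog candidates to mutually-best pairs.

    ``candidates`` rows are (gene_a, gene_b, score); a pair is kept when it
    is the best-scoring partner for both genes (ties broken by partner id).
    """
    best_a: Dict[str, Tuple[float, str]] = {}
    best_b: Dict[str, Tuple[float, str]] = {}
    for a, b, score in candidates:
        key = (score, b)
        if a not in best_a or (key[0], key[1]) > (best_a[a][0], best_a[a][1]):
            pass
        if a not in best_a or score > best_a[a][0] or (
                score == best_a[a][0] and b < best_a[a][1]):
            best_a[a] = (score, b)
        if b not in best_b or score > best_b[b][0] or (
                score == best_b[b][0] and a < best_b[b][1]):
            best_b[b] = (score, a)
    return sorted((a, sb) for a, (_, sb) in best_a.items()
                  if best_b[sb][1] == a)


def _ortholog_ranks(gene_models: Mapping[str, List[GeneModel]],
                    ortholog_genes: Set[str]) -> Dict[str, Tuple[str, int, int, int]]:
    """gene -> (contig, rank among ortholog-bearing genes, start, end)."""
    out = {}
    for contig, genes in gene_models.items():
        bearing = [g for g in sorted(genes, key=lambda g: (g.start, g.gene_id))
                   if g.gene_id in ortholog_genes]
        for orank, g in enumerate(bearing):
            out[g.gene_id] = (contig, orank, g.start, g.end)
    return out


def select_contigs(gene_models: Mapping[str, List[GeneModel]],
                   ortholog_genes: Set[str],
                   min_ortholog_genes: int = 5) -> List[str]:
    """Contigs carrying at least ``min_ortholog_genes`` ortholog-bearing genes."""
    out = []
    for contig, genes in gene_models.items():
        n = sum(1 for g in genes if g.gene_id in ortholog_genes)
        if n >= min_ortholog_genes:
            out.append(contig)
    return sorted(out)


def chain_clusters(ortholog_pairs: Sequence[Tuple[str, str]],
                   gene_models_a: Mapping[str, List[GeneModel]],
                   gene_models_b: Mapping[str, List[GeneModel]],
                   max_gap: int = 15, min_size: int = 5,
                   require_both_sides: bool = True,
                   min_ortholog_genes: int = 5) -> List[SyntenyCluster]:
    """Single-linkage chaining of ortholog pairs into syntenic clusters.

    Two pairs on the same (contig_a, contig_b) chain when their ortholog-rank
    gap is strictly below ``max_gap`` on both genomes (on genome A only when
    ``require_both_sides`` is off).  Gap magnitude is orientation-agnostic,
    so inverted blocks chain.  Components smaller than ``min_size`` are
    discarded; contigs with fewer than ``min_ortholog_genes`` ortholog genes
    are excluded up front.
    """
    seen_a: Set[str] = set()
    seen_b: Set[str] = set()
    for a, b in ortholog_pairs:
        if a in seen_a or b in seen_b:
            raise ValueError(
                f"gene in several ortholog pairs ({a}/{b}); reduce to best pairs first")
        seen_a.add(a)
        seen_b.add(b)
    ranks_a = _ortholog_ranks(gene_models_a, seen_a)
    ranks_b = _ortholog_ranks(gene_models_b, seen_b)
    ok_a = set(select_contigs(gene_models_a, seen_a, min_ortholog_genes))
    ok_b = set(select_contigs(gene_models_b, seen_b, min_ortholog_genes))

    located = []
    for a, b in ortholog_pairs:
        if a not in ranks_a or b not in ranks_b:
            raise KeyError(f"ortholog pair ({a}, {b}) not located in gene models")
        ca, ra, sa, ea = ranks_a[a]
        cb, rb, sb, eb = ranks_b[b]
        if ca in ok_a and cb in ok_b:
            located.append((ca, cb, ra, rb, a, b, sa, ea, sb, eb))
    located.sort()

    # group by contig pair, then single-linkage on rank gaps
    clusters: List[SyntenyCluster] = []
    groups: Dict[Tuple[str, str], List[tuple]] = {}
    for row in located:
        groups.setdefault((row[0], row[1]), []).append(row)
    for (ca, cb), rows in sorted(groups.items()):
        n = len(rows)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                gap_a = abs(rows[i][2] - rows[j][2])
                gap_b = abs(rows[i][3] - rows[j][3])
                linked = gap_a < max_gap and (gap_b < max_gap
                                              or not require_both_sides)
                if linked:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        comps: Dict[int, List[tuple]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(rows[i])
        for comp in comps.values():
            if len(comp) < min_size:
                continue
            comp.sort(key=lambda r: r[2])
            pairs = [(r[4], r[5]) for r in comp]
            span_a = (min(r[6] for r in comp), max(r[7] for r in comp))
            span_b = (min(r[8] for r in comp), max(r[9] for r in comp))
            clusters.append(SyntenyCluster(
                cluster_id=f"syn_{pairs[0][0]}", contig_a=ca, contig_b=cb,
                pairs=pairs, span_a=span_a, span_b=span_b))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def synteny_coverage(clusters: Sequence[SyntenyCluster],
                     assembly_lengths_a: Mapping[str, int],
                     assembly_lengths_b: Mapping[str, int],
                     ) -> Dict[str, float]:
    """Fraction of each assembly covered by the union of cluster spans."""

    def covered(spans: Dict[str, List[Tuple[int, int]]],
                lengths: Mapping[str, int]) -> float:
        total = 0
        for contig, ivals in spans.items():
            if contig not in lengths:
                raise KeyError(f"contig {contig} missing from assembly lengths")
            clen = lengths[contig]
            ivals.sort()
            cur_s, cur_e = None, None
            for s, e in ivals:
                if e > clen:
                    raise ValueError(f"span ({s},{e}) exceeds contig {contig}")
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
        assembly = sum(lengths.values())
        return total / assembly if assembly else 0.0

    spans_a: Dict[str, List[Tuple[int, int]]] = {}
    spans_b: Dict[str, List[Tuple[int, int]]] = {}
    for c in clusters:
        spans_a.setdefault(c.contig_a, []).append(tuple(c.span_a))
        spans_b.setdefault(c.contig_b, []).append(tuple(c.span_b))
    return {"A": covered(spans_a, assembly_lengths_a),
            "B": covered(spans_b, assembly_lengths_b)}


def export_dotplot(clusters: Sequence[SyntenyCluster],
                   gene_models_a: Mapping[str, List[GeneModel]],
                   gene_models_b: Mapping[str, List[GeneModel]],
                   ) -> Tuple[List[dict], List[dict]]:
    """Dotplot points (one per ortholog pair) and circular-link records.

    Points carry gene midpoints on both genomes and the cluster color index;
    coordinates are restricted to the ortholog-bearing contigs the clusters
    live on.  Output is deterministically sorted.
    """
    pos_a = {g.gene_id: (g.contig, (g.start + g.end) // 2)
             for gl in gene_models_a.values() for g in gl}
    pos_b = {g.gene_id: (g.contig, (g.start + g.end) // 2)
             for gl in gene_models_b.values() for g in gl}
    points, links = [], []
    for color, cluster in enumerate(sorted(clusters, key=lambda c: c.cluster_id)):
        for a, b in cluster.pairs:
            points.append({
                "gene_a": a, "gene_b": b,
                "contig_a": pos_a[a][0], "pos_a": pos_a[a][1],
                "contig_b": pos_b[b][0], "pos_b": pos_b[b][1],
                "cluster": cluster.cluster_id, "color": color,
            })
        links.append({
            "cluster": cluster.cluster_id,
            "contig_a": cluster.contig_a, "start_a": cluster.span_a[0],
            "end_a": cluster.span_a[1],
            "contig_b": cluster.contig_b, "start_b": cluster.span_b[0],
            "end_b": cluster.span_b[1], "n_pairs": cluster.size,
        })
    points.sort(key=lambda p: (p["cluster"], p["contig_a"], p["pos_a"]))
    links.sort(key=lambda l: l["cluster"])
    return points, links
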