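"""Planted-truth benchmark experiments.

Each function runs one self-contained experiment on synthetic data with known
ground truth and returns the measured quantities.  The experiments are the
package's evaluation harness: duplicate-detection recovery, oracle agreement
of the clustering/chaining primitives, long-read validation behaviour, the
statistical operating characteristics of the amplification screen, copy-number
estimation error, dS estimator checks, chimera splitting, telomere-array
recovery and whole-pipeline determinism.
"""

from __future__ import annotations

import itertools
import math
import random
import tempfile
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import (annot_refine, og_families, pipeline, seqcore, synteny,
               synthetic_data as sd, tdg, telomere)
from .io_formats import RunConfig


def _seed(base: int, k: int) -> int:
    return (int(base) * 131 + k) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# Tandem duplicate recovery (2 Mb / ~500 genes / 40 planted clusters)
# ---------------------------------------------------------------------------

def tdg_recovery(seed: int) -> Dict[str, float]:
    params = sd.SimulationParams(seed=_seed(seed, 1))
    sim = sd.simulate_genome(params)
    hits = tdg.similarity_search(sim.proteins)
    lengths = {g: len(p) for g, p in sim.proteins.items()}
    pairs = tdg.filter_similarity(hits, lengths)
    tandem = tdg.find_tandem_pairs(pairs, sim.models)
    clusters = tdg.cluster_single_linkage(tandem, sim.models)
    detected = {frozenset(c.members) for c in clusters}
    truth = {frozenset(c) for c in sim.truth.planted_clusters}
    precision = len(detected & truth) / len(detected) if detected else 0.0
    recall = len(detected & truth) / len(truth) if truth else 1.0
    return {"precision": precision, "recall": recall,
            "n_genes": len(sim.proteins), "n_planted": len(truth)}


# ---------------------------------------------------------------------------
# Oracle agreement of single-linkage clustering and synteny chaining
# ---------------------------------------------------------------------------

def _components_bfs(n: int, adj: Dict[int, List[int]]) -> set:
    seen, comps = set(), set()
    for start in range(n):
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v])
        seen |= comp
        comps.add(frozenset(comp))
    return comps


def single_linkage_oracle_agreement(seed: int, n_instances: int = 500) -> float:
    rng = random.Random(_seed(seed, 2))
    agree = 0
    for _ in range(n_instances):
        n = rng.randint(2, 200)
        edges = {tuple(sorted(rng.sample(range(n), 2)))
                 for _ in range(rng.randint(0, n))}
        pairs = [tdg.TandemPair(f"n{a:03d}", f"n{b:03d}", "c", 1, 1e-30,
                                100.0, 50) for a, b in sorted(edges)]
        got = {frozenset(c.members) for c in tdg.cluster_single_linkage(pairs)}
        adj: Dict[int, List[int]] = {i: [] for i in range(n)}
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        want = {frozenset(f"n{i:03d}" for i in comp)
                for comp in _components_bfs(n, adj) if len(comp) >= 2}
        agree += got == want
    return agree / n_instances


def synteny_oracle_agreement(seed: int, n_instances: int = 500,
                             max_gap: int = 15) -> float:
    from .io_formats import GeneModel, assign_ranks

    rng = random.Random(_seed(seed, 3))
    agree = 0
    for _ in range(n_instances):
        n = rng.randint(5, 200)
        perm = list(range(n))
        rng.shuffle(perm)

        def models(prefix, order_positions):
            genes = [GeneModel(f"{prefix}{i:03d}", f"{prefix}c",
                               order_positions[i] * 1000,
                               order_positions[i] * 1000 + 500, "+",
                               [(order_positions[i] * 1000,
                                 order_positions[i] * 1000 + 500)])
                     for i in range(n)]
            return assign_ranks(genes)

        ma = models("a", list(range(n)))
        mb = models("b", perm)
        pairs = [(f"a{i:03d}", f"b{i:03d}") for i in range(n)]
        clusters = synteny.chain_clusters(pairs, ma, mb, max_gap=max_gap,
                                          min_size=1, min_ortholog_genes=1)
        got = {frozenset(c.pairs) for c in clusters}
        adj = {i: [j for j in range(n) if j != i and abs(i - j) < max_gap
                   and abs(perm[i] - perm[j]) < max_gap] for i in range(n)}
        want = {frozenset((f"a{i:03d}", f"b{i:03d}") for i in comp)
                for comp in _components_bfs(n, adj)}
        agree += got == want
    return agree / n_instances


# ---------------------------------------------------------------------------
# Long-read validation behaviour
# ---------------------------------------------------------------------------

def read_validation(seed: int) -> Dict[str, float]:
    params = sd.SimulationParams(seed=_seed(seed, 4), n_contigs=2,
                                 genes_per_contig=50, n_clusters=10)
    sim = sd.simulate_genome(params)
    hits = tdg.similarity_search(sim.proteins)
    pairs = tdg.filter_similarity(hits, {g: len(p)
                                         for g, p in sim.proteins.items()})
    clusters = tdg.cluster_single_linkage(
        tdg.find_tandem_pairs(pairs, sim.models), sim.models)

    spanning = sd.SimulationParams(seed=_seed(seed, 4),
                                   long_read_error_rate=0.0,
                                   long_read_mean_length=10 ** 7,
                                   long_read_length_sigma=0.0,
                                   long_read_coverage=2.0)
    _, spans = sd.simulate_long_reads(sim.genome, spanning)
    _, full = tdg.validate_with_reads(clusters, spans, sim.models)

    short = sd.SimulationParams(seed=_seed(seed, 4),
                                long_read_error_rate=0.0,
                                long_read_mean_length=800,
                                long_read_length_sigma=0.0,
                                long_read_coverage=5.0)
    _, spans = sd.simulate_long_reads(sim.genome, short)
    _, none = tdg.validate_with_reads(clusters, spans, sim.models)
    return {"spanning_pair_fraction": full["pair_fraction"],
            "spanning_cluster_fraction": full["cluster_fraction"],
            "short_pair_fraction": none["pair_fraction"],
            "short_cluster_fraction": none["cluster_fraction"],
            "n_clusters": float(len(clusters))}


# ---------------------------------------------------------------------------
# Amplification screen: null FDR, power, p-value oracle
# ---------------------------------------------------------------------------

def screen_null_fraction(seed: int, reps: int = 20,
                         og_count: int = 5000) -> float:
    fractions = []
    for rep in range(reps):
        params = sd.SimulationParams(seed=_seed(seed, 100 + rep),
                                     og_count=og_count, n_amplified=0,
                                     depth_og_count=1, depth_species=1,
                                     depth_single_copy_count=1)
        cn = sd.simulate_copy_number_data(params)
        cols = list(cn.count_matrix.columns)
        res = og_families.amplification_screen(
            cn.count_matrix, [c for c in cols if c.startswith("spA")],
            [c for c in cols if c.startswith("spB")])
        fractions.append(sum(r.call != "none" for r in res) / len(res))
    return float(np.mean(fractions))


def screen_power(seed: int, og_count: int = 5000,
                 n_amplified: int = 100) -> Dict[str, float]:
    params = sd.SimulationParams(seed=_seed(seed, 5), og_count=og_count,
                                 n_amplified=n_amplified,
                                 amplification_fold=4.0,
                                 depth_og_count=1, depth_species=1,
                                 depth_single_copy_count=1)
    cn = sd.simulate_copy_number_data(params)
    cols = list(cn.count_matrix.columns)
    res = og_families.amplification_screen(
        cn.count_matrix, [c for c in cols if c.startswith("spA")],
        [c for c in cols if c.startswith("spB")])
    called = {r.og_id for r in res if r.call == "amplified_A"}
    planted = set(cn.truth.amplified_og_ids["A"])
    recall = len(called & planted) / len(planted)
    false = len(called - planted)
    return {"recall": recall, "n_false_calls": float(false),
            "n_planted": float(len(planted))}


def binomial_pvalue_oracle_error(seed: int, n_draws: int = 100,
                                 max_n: int = 200) -> float:
    rng = random.Random(_seed(seed, 6))
    p0 = 11 / 14
    worst = 0.0
    for _ in range(n_draws):
        n = rng.randint(1, max_n)
        x = rng.randint(0, n)
        mine = og_families.binomial_pvalue(x, n, p0)
        pmf = [math.comb(n, k) * p0 ** k * (1 - p0) ** (n - k)
               for k in range(n + 1)]
        want = min(1.0, sum(p for p in pmf if p <= pmf[x] * (1 + 1e-7)))
        worst = max(worst, abs(mine - want))
    return worst


# ---------------------------------------------------------------------------
# Copy-number estimation error
# ---------------------------------------------------------------------------

def copy_number_error(seed: int) -> Dict[str, float]:
    params = sd.SimulationParams(seed=_seed(seed, 7), og_count=10,
                                 n_amplified=0, depth_og_count=20,
                                 depth_single_copy_count=8, depth_species=2,
                                 short_read_coverage=20.0,
                                 copy_number_choices=(1, 2, 5, 10))
    cn = sd.simulate_copy_number_data(params)
    profs = {og: og_families.ConsensusProfile(og, seq)
             for og, seq in cn.consensus.items()}
    rel_errors, single = [], []
    for sp in sorted(cn.hits["species"].unique()):
        est = og_families.estimate_copy_numbers(
            cn.hits[cn.hits["species"] == sp], profs,
            cn.truth.single_copy_og_ids, species=sp)
        for og, by_sp in cn.truth.true_copy_number.items():
            true = by_sp[sp]
            rel_errors.append(abs(est[og].copy_number - true) / true)
        single.extend(est[og].copy_number
                      for og in cn.truth.single_copy_og_ids)
    return {"mean_relative_error": float(np.mean(rel_errors)),
            "single_copy_min": float(np.min(single)),
            "single_copy_max": float(np.max(single)),
            "n_estimates": float(len(rel_errors))}


# ---------------------------------------------------------------------------
# NG86 dS checks
# ---------------------------------------------------------------------------

def _enumerator_ng86(cds_a: str, cds_b: str) -> Tuple[float, float, float, float]:
    """Independent brute-force NG86 site/path enumerator."""
    from Bio.Seq import Seq

    def translate(codon):
        return "*" if codon in seqcore.STOP_CODONS else str(Seq(codon).translate())

    S = N = Sd = Nd = 0.0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k:k + 3], cds_b[k:k + 3]
        for codon in (ca, cb):
            syn = sum(1 / 3 for pos in range(3) for base in "ACGT"
                      if base != codon[pos]
                      and translate(codon[:pos] + base + codon[pos + 1:])
                      not in ("*",)
                      and translate(codon[:pos] + base + codon[pos + 1:])
                      == translate(codon))
            S += syn / 2
            N += (3 - syn) / 2
        positions = [p for p in range(3) if ca[p] != cb[p]]
        if not positions:
            continue
        paths = []
        for order in itertools.permutations(positions):
            cur, steps, blocked = ca, [], False
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                blocked = blocked or translate(nxt) == "*"
                steps.append((cur, nxt))
                cur = nxt
            paths.append((blocked, steps))
        usable = [s for b, s in paths if not b] or [s for _, s in paths]
        sd_ = nd_ = 0.0
        for steps in usable:
            for cur, nxt in steps:
                same = (translate(cur) != "*" and translate(nxt) != "*"
                        and translate(cur) == translate(nxt))
                sd_ += same
                nd_ += not same
        Sd += sd_ / len(usable)
        Nd += nd_ / len(usable)
    return S, N, Sd, Nd


def ng86_checks(seed: int, n_pairs: int = 100) -> Dict[str, float]:
    rng = random.Random(_seed(seed, 8))
    non_stop = sorted(c for c in ("".join(t) for t in
                                  itertools.product("ACGT", repeat=3))
                      if c not in seqcore.STOP_CODONS)
    identical = "".join(rng.choice(non_stop) for _ in range(100))
    ds_identical = seqcore.ng86_ds(identical, identical).dS
    worst = 0.0
    for _ in range(n_pairs):
        a = "".join(rng.choice(non_stop) for _ in range(100))
        codons = []
        for k in range(0, 300, 3):
            codon = a[k:k + 3]
            if rng.random() < 0.3:
                for _ in range(10):
                    p = rng.randrange(3)
                    alt = codon[:p] + rng.choice("ACGT") + codon[p + 1:]
                    if alt not in seqcore.STOP_CODONS:
                        codon = alt
                        break
            codons.append(codon)
        b = "".join(codons)
        est = seqcore.ng86_ds(a, b)
        S, N, Sd, Nd = _enumerator_ng86(a, b)
        worst = max(worst, abs(est.S - S), abs(est.N - N),
                    abs(est.Sd - Sd), abs(est.Nd - Nd))
    return {"ds_identical": ds_identical, "count_oracle_max_err": worst}


def ds_truth_experiment(seed: int) -> Dict[str, float]:
    params = sd.SimulationParams(seed=_seed(seed, 9), n_contigs=2,
                                 genes_per_contig=60, n_clusters=12)
    sim = sd.simulate_genome(params)
    keys = sorted(sim.truth.target_ds)
    target = np.array([sim.truth.target_ds[k] for k in keys])
    est = np.array([seqcore.ng86_ds_pair(sim.cds[a], sim.cds[b]).dS
                    for a, b in keys])
    index = {g.gene_id: g for gl in sim.models.values() for g in gl}
    rank_dist = np.array([abs(index[a].rank - index[b].rank)
                          for a, b in keys])
    return {"pearson_target_vs_estimated": float(np.corrcoef(target, est)[0, 1]),
            "spearman_ds_vs_rank_distance": float(
                stats.spearmanr(rank_dist, est).statistic),
            "n_pairs": float(len(keys))}


# ---------------------------------------------------------------------------
# Chimeric-alignment splitting
# ---------------------------------------------------------------------------

def splitter_experiment(seed: int) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for k in (2, 3):
        params = sd.SimulationParams(seed=_seed(seed, 10 + k))
        genome, aln, loci = sd.simulate_chimeric_alignment(params, k=k)
        pieces = annot_refine.split_long_introns(aln, genome)
        on_target = sum(
            1 for piece, locus in zip(pieces, loci)
            if locus[0] <= piece.genomic_span[0]
            and piece.genomic_span[1] <= locus[1])
        out[f"chimera_k{k}_pieces"] = float(len(pieces))
        out[f"chimera_k{k}_on_target"] = float(on_target)
    params = sd.SimulationParams(seed=_seed(seed, 13))
    genome, aln = sd.simulate_genuine_long_intron_gene(params)
    out["genuine_gene_pieces"] = float(
        len(annot_refine.split_long_introns(aln, genome)))
    return out


# ---------------------------------------------------------------------------
# Telomeric arrays
# ---------------------------------------------------------------------------

def its_experiment(seed: int) -> Dict[str, float]:
    rng = sd.substream(_seed(seed, 14), "its_bg")
    genome = {"c0": sd.random_dna(150_000, rng),
              "c1": sd.random_dna(150_000, rng)}
    params = sd.SimulationParams(seed=_seed(seed, 14))
    genome2, truth = sd.plant_telomeric_arrays(genome, params)
    raw = telomere.scan_telomeric_windows(genome2)
    records = telomere.merge_into_its(raw)
    # arrays < 400 bp apart are expected to merge: compare per merge group
    groups: Dict[int, List[dict]] = {}
    for t in truth:
        groups.setdefault(t["merge_group"], []).append(t)
    clean = [g for g in groups.values() if all(t["clean"] for t in g)]
    worst = -1.0
    recovered = 0
    for group in clean:
        start = min(t["start"] for t in group)
        end = max(t["end"] for t in group)
        contig = group[0]["contig"]
        offs = [max(abs(r.start - start), abs(r.end - end))
                for r in records if r.contig == contig]
        best = min(offs) if offs else 1e9
        worst = max(worst, best)
        recovered += best <= 6
    # merge boundary: arrays 399 bp apart merge, 401 bp apart do not
    unit_params = sd.SimulationParams(seed=_seed(seed, 15),
                                      its_mismatch_rate=0.0)
    out = {}
    for gap in (399, 401):
        bg = {"c": sd.random_dna(20_000, sd.substream(_seed(seed, 15), "bg"))}
        planted, _ = sd.plant_telomeric_arrays(
            bg, unit_params, placements=[("c", 5_000, 10),
                                         ("c", 5_000 + 60 + gap, 10)])
        recs = telomere.merge_into_its(telomere.scan_telomeric_windows(planted))
        out[f"records_gap_{gap}"] = float(len(recs))
    out.update({"n_clean_planted": float(len(clean)),
                "n_recovered_within_6bp": float(recovered),
                "max_boundary_offset_bp": float(worst)})
    return out


# ---------------------------------------------------------------------------
# Determinism of the whole pipeline
# ---------------------------------------------------------------------------

def determinism_experiment(seed: int) -> Dict[str, float]:
    cfg = RunConfig(seed=_seed(seed, 16))
    params = sd.SimulationParams(seed=_seed(seed, 16), n_contigs=2,
                                 genes_per_contig=40, n_clusters=8,
                                 og_count=500, n_amplified=10,
                                 amplification_fold=6.0, depth_og_count=8,
                                 depth_single_copy_count=4, depth_species=1,
                                 long_read_coverage=10.0)
    with tempfile.TemporaryDirectory() as tmp:
        m1 = pipeline.run_all(cfg, f"{tmp}/r1", "full", params)
        m2 = pipeline.run_all(cfg, f"{tmp}/r2", "full", params)
    identical = (m1.output_hashes == m2.output_hashes
                 and all(v == "ok" for v in m1.stage_status.values()))
    return {"identical_reruns": float(identical),
            "n_outputs_compared": float(len(m1.output_hashes))}
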