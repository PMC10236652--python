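"""End-to-end orchestration over synthetic (or user-supplied) data.

Runs the analysis graph — duplicate detection, long-read validation,
duplicate ageing (dS and structure), the orthogroup amplification screen and
copy-number estimation, synteny chaining and telomere scanning — and writes
one consolidated report plus a manifest with content hashes so a re-run under
the same seed/config can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import og_families, seqcore, synteny, synthetic_data, tdg, telomere
from .io_formats import RunConfig, write_fasta, write_gene_models, write_table

logger = logging.getLogger(__name__)

PRESETS = ("tdg", "copynumber", "synteny", "telomere", "full")


@dataclass
class RunManifest:
    seed: int
    config_text: str
    stage_status: Dict[str, str] = field(default_factory=dict)
    output_hashes: Dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _register(manifest: RunManifest, outdir: str, *names: str) -> None:
    for name in names:
        manifest.output_hashes[name] = _sha256(os.path.join(outdir, name))


def run_all(config: RunConfig, outdir: str, preset: str = "full",
            sim_params: Optional[synthetic_data.SimulationParams] = None,
            ) -> RunManifest:
    """Execute the pipeline on a simulation preset; return the run manifest.

    A stage failure is recorded in the manifest and downstream stages that
    depend on it are skipped; independent stages still run.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r} (choose from {PRESETS})")
    os.makedirs(outdir, exist_ok=True)
    params = sim_params or synthetic_data.SimulationParams(seed=config.seed)
    manifest = RunManifest(seed=config.seed, config_text=config.to_text())
    report: Dict[str, object] = {"seed": config.seed, "preset": preset}

    sim = None
    clusters = None
    if preset in ("tdg", "full"):
        try:
            sim = synthetic_data.simulate_genome(params)
            write_fasta(sim.genome, os.path.join(outdir, "genome.fasta"))
            write_gene_models(sim.models, os.path.join(outdir, "genes.gff3"))
            write_fasta(sim.proteins, os.path.join(outdir, "proteins.fasta"))
            write_fasta(sim.cds, os.path.join(outdir, "cds.fasta"))
            _register(manifest, outdir, "genome.fasta", "genes.gff3",
                      "proteins.fasta", "cds.fasta")
            manifest.stage_status["simulate"] = "ok"
        except Exception as exc:
            logger.exception("simulation failed")
            manifest.stage_status["simulate"] = f"failed: {exc}"

    if sim is not None:
        try:
            hits = tdg.similarity_search(sim.proteins)
            lengths = {gid: len(p) for gid, p in sim.proteins.items()}
            pairs = tdg.filter_similarity(hits, lengths, config.max_evalue,
                                          config.min_coverage)
            tandem = tdg.find_tandem_pairs(pairs, sim.models,
                                           config.max_gene_distance)
            clusters = tdg.cluster_single_linkage(tandem, sim.models)
            n_tdg = sum(c.size for c in clusters)
            n_genes = len(sim.proteins)
            write_table(
                [{"gene_a": p.gene_a, "gene_b": p.gene_b, "contig": p.contig,
                  "rank_distance": p.rank_distance, "evalue": p.evalue}
                 for p in tandem],
                ["gene_a", "gene_b", "contig", "rank_distance", "evalue"],
                os.path.join(outdir, "tandem_pairs.tsv"))
            write_table(
                [{"cluster_id": c.cluster_id, "contig": c.contig,
                  "size": c.size, "start": c.span[0], "end": c.span[1],
                  "members": ",".join(c.members)} for c in clusters],
                ["cluster_id", "contig", "size", "start", "end", "members"],
                os.path.join(outdir, "tdg_clusters.tsv"))
            _register(manifest, outdir, "tandem_pairs.tsv", "tdg_clusters.tsv")
            report["tdg"] = {
                "n_genes": n_genes, "n_tdg": n_tdg,
                "tdg_fraction_pct": 100.0 * n_tdg / n_genes if n_genes else 0.0,
                "n_clusters": len(clusters),
                "max_cluster_size": max((c.size for c in clusters), default=0),
            }
            manifest.stage_status["tdg_detect"] = "ok"
        except Exception as exc:
            logger.exception("tdg detection failed")
            manifest.stage_status["tdg_detect"] = f"failed: {exc}"

    if sim is not None and clusters is not None:
        try:
            reads, spans = synthetic_data.simulate_long_reads(sim.genome, params)
            clusters, summary = tdg.validate_with_reads(clusters, spans, sim.models)
            write_table(
                [{"cluster_id": c.cluster_id, "validated_pairs": c.validated_pairs,
                  "n_adjacent_pairs": c.n_adjacent_pairs,
                  "cluster_validated": c.cluster_validated} for c in clusters],
                ["cluster_id", "validated_pairs", "n_adjacent_pairs",
                 "cluster_validated"],
                os.path.join(outdir, "validation.tsv"))
            _register(manifest, outdir, "validation.tsv")
            report["validation"] = summary
            manifest.stage_status["validate"] = "ok"
        except Exception as exc:
            logger.exception("validation failed")
            manifest.stage_status["validate"] = f"failed: {exc}"

        try:
            ds: Dict = {}
            structures = {"fully_conserved": 0, "exons_conserved": 0,
                          "divergent": 0}
            index = {g.gene_id: g for gl in sim.models.values() for g in gl}
            for cluster in clusters:
                for i in range(cluster.size):
                    for j in range(i + 1, cluster.size):
                        a, b = cluster.members[i], cluster.members[j]
                        est = seqcore.ng86_ds_pair(sim.cds[a], sim.cds[b], a, b)
                        ds[tuple(sorted((a, b)))] = est.dS
                for a, b in zip(cluster.members, cluster.members[1:]):
                    cmp = seqcore.compare_structures(index[a], index[b])
                    structures[cmp.conservation_class] += 1
            stats_report = tdg.cluster_statistics(clusters, ds, sim.models)
            report["ageing"] = {"structure_classes": structures, **stats_report}
            manifest.stage_status["ageing"] = "ok"
        except Exception as exc:
            logger.exception("ageing failed")
            manifest.stage_status["ageing"] = f"failed: {exc}"

    if preset in ("copynumber", "full"):
        try:
            cn = synthetic_data.simulate_copy_number_data(params)
            species = sorted(cn.count_matrix.columns)
            group_a = [s for s in species if s.startswith("spA")]
            group_b = [s for s in species if s.startswith("spB")]
            results = og_families.amplification_screen(
                cn.count_matrix, group_a, group_b, config.screen_alpha)
            write_table(
                [{"og_id": r.og_id, "count_A": r.count_group_a,
                  "count_B": r.count_group_b, "p_value": r.p_value,
                  "p_adjusted": r.p_adjusted, "call": r.call} for r in results],
                ["og_id", "count_A", "count_B", "p_value", "p_adjusted", "call"],
                os.path.join(outdir, "amplification.tsv"))
            _register(manifest, outdir, "amplification.tsv")
            consensus = {og: og_families.ConsensusProfile(og, seq)
                         for og, seq in cn.consensus.items()}
            sp = sorted(cn.hits["species"].unique())[0]
            estimates = og_families.estimate_copy_numbers(
                cn.hits[cn.hits["species"] == sp], consensus,
                cn.truth.single_copy_og_ids, species=sp,
                outlier_mad=config.depth_outlier_mad)
            report["og_families"] = {
                "n_tested": len(results),
                "n_amplified_A": sum(r.call == "amplified_A" for r in results),
                "n_amplified_B": sum(r.call == "amplified_B" for r in results),
                "single_copy_depth_mean": float(
                    sum(estimates[og].copy_number
                        for og in cn.truth.single_copy_og_ids)
                    / len(cn.truth.single_copy_og_ids)),
            }
            manifest.stage_status["og_families"] = "ok"
        except Exception as exc:
            logger.exception("orthogroup stage failed")
            manifest.stage_status["og_families"] = f"failed: {exc}"

    if preset in ("synteny", "full"):
        try:
            ma, mb, pairs, lengths, truth_segments = \
                synthetic_data.simulate_synteny_pair(params)
            syn_clusters = synteny.chain_clusters(
                pairs, ma, mb, config.synteny_max_gap, config.synteny_min_size,
                min_ortholog_genes=config.synteny_min_ortholog_genes)
            coverage = synteny.synteny_coverage(syn_clusters, lengths["A"],
                                                lengths["B"])
            write_table(
                [{"cluster_id": c.cluster_id, "contig_a": c.contig_a,
                  "contig_b": c.contig_b, "n_pairs": c.size,
                  "span_a": f"{c.span_a[0]}-{c.span_a[1]}",
                  "span_b": f"{c.span_b[0]}-{c.span_b[1]}"}
                 for c in syn_clusters],
                ["cluster_id", "contig_a", "contig_b", "n_pairs",
                 "span_a", "span_b"],
                os.path.join(outdir, "synteny_clusters.tsv"))
            _register(manifest, outdir, "synteny_clusters.tsv")
            report["synteny"] = {"n_clusters": len(syn_clusters),
                                 "n_true_segments": len(truth_segments),
                                 "coverage_A": coverage["A"],
                                 "coverage_B": coverage["B"]}
            manifest.stage_status["synteny"] = "ok"
        except Exception as exc:
            logger.exception("synteny stage failed")
            manifest.stage_status["synteny"] = f"failed: {exc}"

    if preset in ("telomere", "full"):
        try:
            base = sim.genome if sim is not None else {
                "ctg00": synthetic_data.random_dna(
                    200_000, synthetic_data.substream(params.seed, "telo_bg"))}
            genome_t, its_truth = synthetic_data.plant_telomeric_arrays(
                base, params)
            raw = telomere.scan_telomeric_windows(
                genome_t, config.telomere_motif, config.telomere_units,
                config.telomere_max_mismatch, config.telomere_min_identity,
                config.telomere_min_coverage)
            records = telomere.merge_into_its(raw, config.its_merge_gap)
            records = telomere.classify_terminal(
                records, {c: len(s) for c, s in genome_t.items()},
                config.terminal_end_window)
            with open(os.path.join(outdir, "its.bed"), "w") as fh:
                fh.write(telomere.records_to_bed(records))
            _register(manifest, outdir, "its.bed")
            report["telomere"] = {
                "n_planted": len(its_truth),
                "n_records": len(records),
                "n_terminal": sum(r.classification == "terminal"
                                  for r in records),
                "n_interstitial": sum(r.classification == "interstitial"
                                      for r in records)}
            manifest.stage_status["telomere"] = "ok"
        except Exception as exc:
            logger.exception("telomere stage failed")
            manifest.stage_status["telomere"] = f"failed: {exc}"

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _register(manifest, outdir, "report.json")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        fh.write(manifest.to_json())
    return manifest
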