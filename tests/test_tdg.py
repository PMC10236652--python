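import random

import pytest

from coraldup import tdg
from coraldup.io_formats import GeneModel, ReadSpan, SimilarityHit, assign_ranks


def _hit(q, s, evalue=1e-30, span=90, bitscore=200.0):
    return SimilarityHit(q, s, evalue, bitscore, span, span, 95.0)


def _models(positions, contig="c1", length=1000):
    """positions: gene_id -> start (same contig)."""
    genes = [GeneModel(g, contig, p, p + length, "+", [(p, p + length)],
                       cds_length=length) for g, p in positions.items()]
    return assign_ranks(genes)


class TestFilterSimilarity:
    LENGTHS = {"a": 100, "b": 400}

    def test_strong_hit_with_sufficient_coverage_kept(self):
        kept = tdg.filter_similarity([_hit("a", "b", 1e-21, span=85)], self.LENGTHS)
        assert ("a", "b") in kept

    def test_evalue_boundary_is_inclusive_at_threshold(self):
        assert tdg.filter_similarity([_hit("a", "b", 1e-20, span=85)], self.LENGTHS)
        assert not tdg.filter_similarity([_hit("a", "b", 1e-19, span=85)],
                                         self.LENGTHS)

    def test_coverage_below_80pct_of_smaller_protein_dropped(self):
        assert not tdg.filter_similarity([_hit("a", "b", span=79)], self.LENGTHS)
        assert tdg.filter_similarity([_hit("a", "b", span=80)], self.LENGTHS)

    def test_self_hits_ignored_and_best_row_kept(self):
        hits = [_hit("a", "a"), _hit("a", "b", bitscore=100.0),
                _hit("b", "a", bitscore=300.0)]
        kept = tdg.filter_similarity(hits, self.LENGTHS)
        assert list(kept) == [("a", "b")] and kept[("a", "b")].bitscore == 300.0

    def test_missing_length_names_gene(self):
        with pytest.raises(KeyError, match="zz"):
            tdg.filter_similarity([_hit("a", "zz")], self.LENGTHS)


class TestFindTandemPairs:
    def test_rank_distance_boundary_inclusive_at_10(self):
        pos = {f"g{i:02d}": 10_000 * i for i in range(20)}
        models = _models(pos)
        pairs = {("g04", "g14"): _hit("g04", "g14")}
        assert len(tdg.find_tandem_pairs(pairs, models)) == 1
        pairs = {("g04", "g15"): _hit("g04", "g15")}
        assert tdg.find_tandem_pairs(pairs, models) == []

    def test_different_contigs_dropped(self):
        m = _models({"a": 0, "b": 5000}, contig="c1")
        m.update(_models({"x": 0}, contig="c2"))
        assert tdg.find_tandem_pairs({("a", "x"): _hit("a", "x")}, m) == []

    def test_unknown_gene_rejected(self):
        m = _models({"a": 0, "b": 5000})
        with pytest.raises(KeyError, match="nope"):
            tdg.find_tandem_pairs({("a", "nope"): _hit("a", "nope")}, m)


def _tandem(a, b, contig="c1", dist=1):
    return tdg.TandemPair(a, b, contig, dist, 1e-30, 200.0, 90)


class TestSingleLinkage:
    def test_transitive_pairs_form_one_cluster(self):
        clusters = tdg.cluster_single_linkage([_tandem("A", "B"), _tandem("B", "C")])
        assert len(clusters) == 1 and clusters[0].members == ["A", "B", "C"]

    def test_no_pairs_no_clusters(self):
        assert tdg.cluster_single_linkage([]) == []

    def test_matches_transitive_closure_oracle_on_random_instances(self):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(2, 60)
            nodes = [f"n{i}" for i in range(n)]
            edges = {tuple(sorted(rng.sample(nodes, 2)))
                     for _ in range(rng.randint(0, 2 * n))}
            pairs = [_tandem(a, b) for a, b in sorted(edges)]
            got = {frozenset(c.members)
                   for c in tdg.cluster_single_linkage(pairs)}
            # oracle: repeated merging until fixpoint
            comps = [set(e) for e in edges]
            changed = True
            while changed:
                changed = False
                for i in range(len(comps)):
                    for j in range(i + 1, len(comps)):
                        if comps[i] and comps[j] and comps[i] & comps[j]:
                            comps[i] |= comps[j]
                            comps[j] = set()
                            changed = True
            want = {frozenset(c) for c in comps if len(c) >= 2}
            assert got == want

    def test_reclustering_is_idempotent(self, detected, small_sim):
        clusters = detected["clusters"]
        again = tdg.cluster_single_linkage(detected["tandem"], small_sim.models)
        assert [(c.cluster_id, c.members) for c in again] == \
               [(c.cluster_id, c.members) for c in clusters]

    def test_planted_clusters_recovered_exactly(self, detected, small_sim):
        got = {frozenset(c.members) for c in detected["clusters"]}
        want = {frozenset(c) for c in small_sim.truth.planted_clusters}
        assert got == want

    def test_membership_monotone_in_gene_distance(self, detected, small_sim):
        def total(dist):
            pairs = tdg.find_tandem_pairs(detected["pairs"], small_sim.models,
                                          max_gene_distance=dist)
            return sum(c.size for c in tdg.cluster_single_linkage(pairs))

        totals = [total(d) for d in (1, 3, 5, 10)]
        assert totals == sorted(totals)


class TestValidation:
    MODELS = _models({"A": 10_000, "B": 14_000, "C": 18_000})
    CLUSTER = tdg.TDGCluster("tdg_A", "c1", ["A", "B", "C"], (10_000, 19_000))

    def test_read_spanning_whole_cluster_validates_everything(self):
        reads = [ReadSpan("r", "c1", 0, 50_000)]
        clusters, summary = tdg.validate_with_reads([self.CLUSTER], reads,
                                                    self.MODELS)
        assert clusters[0].validated_pairs == 2
        assert clusters[0].cluster_validated
        assert summary["pair_fraction"] == 1.0

    def test_read_covering_half_of_last_gene_validates_pair_not_cluster(self):
        reads = [ReadSpan("r", "c1", 9_000, 18_500)]  # A,B full; C half
        clusters, _ = tdg.validate_with_reads([self.CLUSTER], reads, self.MODELS)
        assert clusters[0].validated_pairs == 1
        assert not clusters[0].cluster_validated

    def test_reads_shorter_than_pair_spans_validate_nothing(self):
        reads = [ReadSpan(f"r{i}", "c1", s, s + 2_000)
                 for i, s in enumerate(range(0, 30_000, 500))]
        clusters, summary = tdg.validate_with_reads([self.CLUSTER], reads,
                                                    self.MODELS)
        assert summary["pair_fraction"] == 0.0
        assert not clusters[0].cluster_validated

    def test_reads_on_unknown_contig_skipped_with_warning(self, caplog):
        reads = [ReadSpan("r", "c9", 0, 50_000)]
        with caplog.at_level("WARNING"):
            _, summary = tdg.validate_with_reads([self.CLUSTER], reads,
                                                 self.MODELS)
        assert "unknown contig" in caplog.text
        assert summary["pair_fraction"] == 0.0


class TestClusterStatistics:
    def test_size_summary(self):
        models = _models({"A": 0, "B": 2000, "C": 4000, "D": 6000,
                          "E": 8000, "F": 10_000, "G": 12_000})
        clusters = [
            tdg.TDGCluster("tdg_A", "c1", ["A", "B"], (0, 3000)),
            tdg.TDGCluster("tdg_C", "c1", ["C", "D"], (4000, 7000)),
            tdg.TDGCluster("tdg_E", "c1", ["E", "F", "G"], (8000, 13_000)),
        ]
        report = tdg.cluster_statistics(clusters, {}, models)
        assert report["mean_size"] == pytest.approx(7 / 3)
        assert report["max_size"] == 3
        assert report["size_histogram"] == {2: 2, 3: 1}

    def test_empty_cluster_list_gives_empty_report(self):
        report = tdg.cluster_statistics([], {}, {})
        assert report["n_clusters"] == 0 and report["size_histogram"] == {}

    def test_ds_increases_with_rank_distance_on_simulated_arrays(
            self, detected, small_sim):
        report = tdg.cluster_statistics(detected["clusters"],
                                        small_sim.truth.pairwise_true_ds,
                                        small_sim.models)
        assert report["spearman_ds_distance"] > 0.5
        means = [report["ds_by_distance"][b]["mean"] for b in ("1", "2", "3", ">=4")]
        assert means == sorted(means)
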