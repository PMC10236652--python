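import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coraldup import og_families as ogf
from coraldup import synthetic_data as sd


class TestOutlierRemoval:
    def test_identical_rows_have_no_outliers(self):
        msa = [(f"s{i}", "MKT" * 10) for i in range(10)]
        kept, removed = ogf.remove_outlier_sequences(msa)
        assert removed == [] and len(kept) == 10

    def test_single_divergent_row_removed(self):
        rng = random.Random(1)
        msa = [(f"s{i}", "MKTLLVAAGH" * 4) for i in range(9)]
        msa.append(("odd", "".join(rng.choice("ACDEFGHIKL") for _ in range(40))))
        kept, removed = ogf.remove_outlier_sequences(msa)
        assert removed == ["odd"]

    def test_two_rows_returned_unchanged(self):
        msa = [("a", "MKT"), ("b", "XYZ")]
        assert ogf.remove_outlier_sequences(msa) == (msa, [])

    def test_ragged_msa_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            ogf.remove_outlier_sequences([("a", "MKT"), ("b", "MK")])


class TestBuildConsensus:
    def test_identical_ungapped_rows_reproduced(self):
        row = "MKTLLVAAGH"
        prof = ogf.build_consensus("og1", [(f"s{i}", row) for i in range(5)])
        assert prof.consensus == row and prof.n_passes == 1

    def test_majority_gap_columns_dropped(self):
        msa = [("a", "MK-T"), ("b", "MK-T"), ("c", "MKAT"), ("d", "MK-T")]
        prof = ogf.build_consensus("og1", msa)
        assert prof.consensus == "MKT"

    def test_second_pass_triggered_above_15pct_excess(self):
        # 5 rows, 231 columns, gaps staggered so every column keeps < 50% gaps:
        # consensus 231 > 1.15 * median ungapped length (200)
        rows = []
        for i in range(5):
            gap_block = set(range(i * 31, i * 31 + 31))
            rows.append((f"s{i}", "".join("-" if c in gap_block else "A"
                                          for c in range(231))))
        prof = ogf.build_consensus("og", rows)
        assert prof.n_passes == 2

    def test_boundary_excess_not_triggered(self):
        # consensus length 230 with median 200: 30 is not > 0.15 * 200
        rows = []
        for i in range(23):
            gap_block = set(range(i * 10, i * 10 + 30))
            rows.append((f"s{i}", "".join("-" if c in gap_block else "A"
                                          for c in range(230))))
        prof = ogf.build_consensus("og", rows)
        assert prof.n_passes == 1

    def test_empty_msa_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ogf.build_consensus("og", [])


class TestMasking:
    def test_shared_block_masked_on_both(self):
        rng = random.Random(2)
        shared = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(40))
        a = "".join(rng.choice("ACDEF") for _ in range(50)) + shared
        b = shared + "".join(rng.choice("GHIKL") for _ in range(60))
        profs = {"A": ogf.ConsensusProfile("A", a),
                 "B": ogf.ConsensusProfile("B", b)}
        masked = ogf.mask_unspecific_regions(profs)
        (s_a, e_a), = masked["A"].masked_intervals
        (s_b, e_b), = masked["B"].masked_intervals
        assert (s_a, e_a) == (50, 90) and (s_b, e_b) == (0, 40)

    def test_unrelated_consensuses_unmasked(self):
        rng = random.Random(3)
        profs = {n: ogf.ConsensusProfile(
            n, "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(120)))
            for n in ("A", "B", "C")}
        masked = ogf.mask_unspecific_regions(profs)
        assert all(p.masked_intervals == [] for p in masked.values())

    def test_duplicated_consensus_fully_masked_and_flagged(self):
        rng = random.Random(4)
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(80))
        profs = {"A": ogf.ConsensusProfile("A", seq),
                 "B": ogf.ConsensusProfile("B", seq)}
        masked = ogf.mask_unspecific_regions(profs)
        assert masked["A"].masked_intervals == [(0, 80)]
        flags = ogf.unspecific_flags(masked)
        assert flags == {"A": True, "B": True}


class TestSingleCopySelection:
    def _matrix(self, rows):
        return pd.DataFrame(rows).T  # rows: og -> list of counts

    def test_all_ones_kept(self):
        m = self._matrix({"og1": [1] * 14})
        assert ogf.select_single_copy_ogs(m) == ["og1"]

    def test_s_minus_one_rule(self):
        m = self._matrix({"og1": [1] * 13 + [2],      # 13 of 14 exactly one
                          "og2": [1] * 12 + [0, 0]})  # only 12
        assert ogf.select_single_copy_ogs(m) == ["og1"]

    def test_flagged_ogs_excluded(self):
        m = self._matrix({"og1": [1] * 14})
        assert ogf.select_single_copy_ogs(m, exclude={"og1": True}) == []

    def test_monotone_in_required_species(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.poisson(1.2, size=(50, 14)))
        sizes = [len(ogf.select_single_copy_ogs(m, k)) for k in range(1, 15)]
        assert sizes == sorted(sizes, reverse=True)


@pytest.fixture(scope="module")
def sim():
    p = sd.SimulationParams(seed=31, og_count=10, n_amplified=0,
                            depth_og_count=16, depth_single_copy_count=6,
                            depth_species=1, short_read_coverage=20.0)
    return sd.simulate_copy_number_data(p)


class TestCopyNumbers:
    def _estimates(self, sim):
        profs = {og: ogf.ConsensusProfile(og, seq)
                 for og, seq in sim.consensus.items()}
        return ogf.estimate_copy_numbers(sim.hits, profs,
                                         sim.truth.single_copy_og_ids,
                                         species="dsp00")

    def test_mean_relative_error_within_10pct(self, sim):
        est = self._estimates(sim)
        errs = [abs(est[og].copy_number - cn["dsp00"]) / cn["dsp00"]
                for og, cn in sim.truth.true_copy_number.items()]
        assert np.mean(errs) <= 0.10

    def test_single_copy_estimates_tightly_around_one(self, sim):
        est = self._estimates(sim)
        for og in sim.truth.single_copy_og_ids:
            assert 0.9 <= est[og].copy_number <= 1.1

    def test_invariant_to_uniform_read_rescaling(self, sim):
        est = self._estimates(sim)
        doubled = pd.concat([sim.hits, sim.hits.assign(
            qseqid=sim.hits["qseqid"] + "_dup")], ignore_index=True)
        profs = {og: ogf.ConsensusProfile(og, seq)
                 for og, seq in sim.consensus.items()}
        est2 = ogf.estimate_copy_numbers(doubled, profs,
                                         sim.truth.single_copy_og_ids)
        for og in est:
            assert est2[og].copy_number == pytest.approx(est[og].copy_number)

    def test_ambiguous_reads_contribute_to_neither(self):
        profs = {"A": ogf.ConsensusProfile("A", "ACGT" * 50),
                 "B": ogf.ConsensusProfile("B", "TGCA" * 50)}
        cols = ["qseqid", "sseqid", "sstart", "send", "bitscore"]
        hits = pd.DataFrame([
            ("r1", "A", 1, 100, 200.0), ("r1", "B", 1, 100, 200.0),  # tie
            ("r2", "A", 1, 100, 200.0), ("r2", "B", 1, 100, 150.0),  # unique
        ], columns=cols)
        est = ogf.estimate_copy_numbers(hits, profs, ["A", "B"])
        assert est["A"].raw_depth == pytest.approx(100 / 200)
        assert est["B"].raw_depth == 0.0

    def test_masked_positions_excluded_from_depth(self):
        profs = {"A": ogf.ConsensusProfile("A", "ACGT" * 50, [(0, 100)]),
                 "B": ogf.ConsensusProfile("B", "TGCA" * 50)}
        cols = ["qseqid", "sseqid", "sstart", "send", "bitscore"]
        hits = pd.DataFrame([("r1", "A", 51, 150, 200.0),
                             ("r2", "B", 1, 100, 200.0)], columns=cols)
        est = ogf.estimate_copy_numbers(hits, profs, ["B"])
        # only 50 of 100 aligned bases fall on unmasked positions (100 left)
        assert est["A"].raw_depth == pytest.approx(50 / 100)

    def test_empty_single_copy_set_rejected(self):
        profs = {"A": ogf.ConsensusProfile("A", "ACGT" * 50)}
        hits = pd.DataFrame(columns=["qseqid", "sseqid", "sstart", "send",
                                     "bitscore"])
        with pytest.raises(ValueError):
            ogf.estimate_copy_numbers(hits, profs, [])


class TestBinomialScreen:
    def test_expected_share_gives_pvalue_one(self):
        # 3-vs-1 species groups: p0 = 0.75; x/n = 33/44 sits exactly at p0
        res = ogf.amplification_screen(
            pd.DataFrame({"a1": [11], "a2": [11], "a3": [11], "b1": [11]},
                         index=["og"]),
            ["a1", "a2", "a3"], ["b1"])
        assert res[0].p_value == pytest.approx(1.0, abs=1e-9)
        assert res[0].call == "none"

    def test_minlike_pvalue_matches_exact_oracles(self):
        rng = random.Random(6)
        p0 = 11 / 14
        for _ in range(60):
            n = rng.randint(1, 200)
            x = rng.randint(0, n)
            mine = ogf.binomial_pvalue(x, n, p0)
            # oracle 1: scipy's exact test
            assert mine == pytest.approx(
                stats.binomtest(x, n, p0).pvalue, abs=1e-12)
            # oracle 2: exhaustive summation with math.comb
            pmf = [math.comb(n, k) * p0 ** k * (1 - p0) ** (n - k)
                   for k in range(n + 1)]
            want = min(1.0, sum(p for p in pmf if p <= pmf[x] * (1 + 1e-7)))
            assert mine == pytest.approx(want, abs=1e-12)

    def test_planted_amplifications_called_in_right_direction(self):
        p = sd.SimulationParams(seed=32, og_count=400, n_amplified=12,
                                amplification_fold=8.0)
        cn = sd.simulate_copy_number_data(p)
        cols = list(cn.count_matrix.columns)
        res = ogf.amplification_screen(
            cn.count_matrix, [c for c in cols if c.startswith("spA")],
            [c for c in cols if c.startswith("spB")])
        called = {r.og_id for r in res if r.call == "amplified_A"}
        planted = set(cn.truth.amplified_og_ids["A"])
        assert called and called <= planted | called
        assert len(called & planted) / len(planted) >= 0.9
        assert not any(r.call == "amplified_B" for r in res)

    def test_null_simulation_controls_false_discoveries(self):
        p = sd.SimulationParams(seed=33, og_count=2000, n_amplified=0)
        cn = sd.simulate_copy_number_data(p)
        cols = list(cn.count_matrix.columns)
        res = ogf.amplification_screen(
            cn.count_matrix, [c for c in cols if c.startswith("spA")],
            [c for c in cols if c.startswith("spB")])
        assert sum(r.call != "none" for r in res) / len(res) <= 0.001

    def test_adjusted_p_never_below_raw(self):
        p = sd.SimulationParams(seed=34, og_count=100, n_amplified=5,
                                amplification_fold=6.0)
        cn = sd.simulate_copy_number_data(p)
        cols = list(cn.count_matrix.columns)
        res = ogf.amplification_screen(
            cn.count_matrix, [c for c in cols if c.startswith("spA")],
            [c for c in cols if c.startswith("spB")])
        assert all(r.p_adjusted >= r.p_value - 1e-15 for r in res)

    def test_overlapping_groups_rejected(self):
        m = pd.DataFrame({"a": [1], "b": [1]}, index=["og"])
        with pytest.raises(ValueError, match="overlap"):
            ogf.amplification_screen(m, ["a"], ["a", "b"])


class TestDomainClassification:
    TABLE = ogf.OrthogroupTable({
        "og_tir": {"sp1": [f"t{i}" for i in range(10)],
                   "sp2": [f"t{i}" for i in range(10, 20)]},
        "og_nacht": {"sp1": [f"n{i}" for i in range(25)]},
        "og_none": {"sp1": ["x1", "x2"]},
    })
    RULES = [("TLR-like", {"IPR000157", "IPR035897"}, 0.20),
             ("NLR-like", {"IPR007111"}, 0.05)]

    def test_prevalence_thresholds(self):
        domains = {f"t{i}": ["IPR000157"] for i in range(6)}        # 6/20 = 30%
        domains.update({"n0": ["IPR007111"]})                       # 1/25 = 4%
        labels = ogf.classify_og_by_domain(self.TABLE, domains, self.RULES)
        assert labels["og_tir"] == ["TLR-like"]
        assert labels["og_nacht"] == []
        assert labels["og_none"] == []

    def test_unknown_gene_warns(self, caplog):
        with caplog.at_level("WARNING"):
            ogf.classify_og_by_domain(self.TABLE, {"ghost": ["IPR000157"]},
                                      self.RULES)
        assert "ghost" in caplog.text
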