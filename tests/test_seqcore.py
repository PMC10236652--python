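import itertools
import math
import random

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from coraldup import seqcore
from coraldup.io_formats import GeneModel
from coraldup.seqcore import (Scoring, align_local, compare_structures,
                              ng86_ds, realign_protein_to_dna)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
NON_STOP = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
            if c not in seqcore.STOP_CODONS]


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def gotoh_local_score(a, b, matrix, open_cost=11, extend_cost=1):
    """Naive O(nm) affine-gap local alignment (gap of length L costs
    open_cost + L * extend_cost), written independently of the library path."""
    neg = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost - extend_cost,
                          E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost - extend_cost,
                          F[i - 1][j] - extend_cost)
            diag = H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def oracle_ng86(cds_a, cds_b):
    """Brute-force NG86 site/path enumerator (translation via Biopython)."""

    def translate(codon):
        return "*" if codon in seqcore.STOP_CODONS else str(Seq(codon).translate())

    def syn_sites(codon):
        aa = translate(codon)
        syn = 0.0
        for pos, orig in enumerate(codon):
            for base in "ACGT":
                if base == orig:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if translate(alt) != "*" and translate(alt) == aa:
                    syn += 1 / 3
        return syn

    S = N = Sd = Nd = 0.0
    for k in range(0, len(cds_a), 3):
        ca, cb = cds_a[k:k + 3], cds_b[k:k + 3]
        sa, sb = syn_sites(ca), syn_sites(cb)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
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
        usable = [s for blocked, s in paths if not blocked] or [s for _, s in paths]
        sd = nd = 0.0
        for steps in usable:
            for cur, nxt in steps:
                if translate(cur) != "*" and translate(nxt) != "*" and \
                        translate(cur) == translate(nxt):
                    sd += 1
                else:
                    nd += 1
        Sd += sd / len(usable)
        Nd += nd / len(usable)
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Local protein alignment
# ---------------------------------------------------------------------------

class TestAlignLocal:
    def test_identical_sequences_score_sum_of_diagonal(self):
        rng = random.Random(0)
        seq = "".join(rng.choice(AA20) for _ in range(50))
        matrix = Scoring().matrix
        res = align_local(seq, seq)
        assert res.identity_pct == 100.0
        assert res.score == sum(matrix[a, a] for a in seq)

    def test_disjoint_alphabets_give_empty_alignment(self):
        res = align_local("K" * 30, "D" * 30)
        assert res.score == 0.0 and res.is_empty

    def test_matches_naive_dp_oracle_on_random_pairs(self):
        rng = random.Random(42)
        matrix = Scoring().matrix
        for _ in range(300):
            a = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 25)))
            b = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 25)))
            assert align_local(a, b).score == pytest.approx(
                gotoh_local_score(a, b, matrix))

    def test_invalid_residue_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            align_local("AC1DE", "ACDE")


class TestRealign:
    def setup_method(self):
        rng = random.Random(7)
        self.cds = "".join(rng.choice(NON_STOP) for _ in range(60))
        self.protein = str(Seq(self.cds).translate())

    def test_exact_back_translation_full_length_forward(self):
        res = realign_protein_to_dna(self.protein, self.cds)
        assert res.strand == "+" and res.frame == 0
        assert res.query_span() == (0, len(self.protein))
        assert res.target_span() == (0, len(self.cds))

    def test_reverse_complement_same_score_minus_strand(self):
        fwd = realign_protein_to_dna(self.protein, self.cds)
        rc = str(Seq(self.cds).reverse_complement())
        rev = realign_protein_to_dna(self.protein, rc)
        assert rev.score == fwd.score and rev.strand == "-"
        assert rev.target_span() == (0, len(self.cds))

    def test_insert_breaks_frame_alignment_covers_longer_side(self):
        rng = random.Random(8)
        insert = "".join(rng.choice("ACGT") for _ in range(50))  # not 3n
        window = self.cds[:120] + insert + self.cds[120:]
        res = realign_protein_to_dna(self.protein, window)
        qs, qe = res.query_span()
        assert qs == 0 and 35 <= qe <= 45  # the 40-codon side wins

    def test_window_shorter_than_codon_rejected(self):
        with pytest.raises(ValueError):
            realign_protein_to_dna(self.protein, "AC")


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

class TestNg86:
    def test_identical_sequences_have_zero_rates(self):
        cds = "ATGGCTAAGGCT"
        est = ng86_ds(cds, cds)
        assert est.dS == 0.0 and est.dN == 0.0
        assert est.Sd == 0.0 and est.Nd == 0.0

    def test_single_synonymous_change(self):
        est = ng86_ds("TTT", "TTC")  # Phe -> Phe
        assert est.Sd == 1.0 and est.Nd == 0.0
        assert est.dS > 0.0 and est.dN == 0.0

    def test_sites_sum_to_three_per_codon(self):
        rng = random.Random(3)
        cds = "".join(rng.choice(NON_STOP) for _ in range(40))
        est = ng86_ds(cds, cds)
        assert est.S + est.N == pytest.approx(3 * est.n_codons)

    def test_matches_bruteforce_enumerator_on_random_pairs(self):
        rng = random.Random(123)
        for _ in range(100):
            a = "".join(rng.choice(NON_STOP) for _ in range(100))
            b_codons = []
            for k in range(0, 300, 3):
                codon = a[k:k + 3]
                if rng.random() < 0.3:  # mutate one site, avoid stops
                    for _ in range(10):
                        p = rng.randrange(3)
                        alt = codon[:p] + rng.choice("ACGT") + codon[p + 1:]
                        if alt not in seqcore.STOP_CODONS:
                            codon = alt
                            break
                b_codons.append(codon)
            b = "".join(b_codons)
            est = ng86_ds(a, b)
            S, N, Sd, Nd = oracle_ng86(a, b)
            assert est.S == pytest.approx(S, abs=1e-9)
            assert est.N == pytest.approx(N, abs=1e-9)
            assert est.Sd == pytest.approx(Sd, abs=1e-9)
            assert est.Nd == pytest.approx(Nd, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(NON_STOP), min_size=5, max_size=30),
           st.randoms(use_true_random=False))
    def test_symmetric_in_arguments(self, codons, rnd):
        a = "".join(codons)
        b = "".join(rnd.choice(NON_STOP) for _ in codons)
        ea, eb = ng86_ds(a, b), ng86_ds(b, a)
        assert ea.S == pytest.approx(eb.S) and ea.Sd == pytest.approx(eb.Sd)
        assert ea.N == pytest.approx(eb.N) and ea.Nd == pytest.approx(eb.Nd)

    def test_gap_codons_skipped_pairwise(self):
        est = ng86_ds("TTT---GGG", "TTC---GGG")
        assert est.n_codons == 2 and est.Sd == 1.0

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            ng86_ds("TTT", "TTTGGG")
        with pytest.raises(ValueError, match="multiple of 3"):
            ng86_ds("TTTA", "TTTA")
        with pytest.raises(ValueError, match="codon 0"):
            ng86_ds("TAAGGG", "TTTGGG")


# ---------------------------------------------------------------------------
# Structure comparison
# ---------------------------------------------------------------------------

def _gene(gid, exons, strand="+", contig="c"):
    return GeneModel(gid, contig, exons[0][0], exons[-1][1], strand,
                     exons, cds_length=sum(e - s for s, e in exons))


class TestCompareStructures:
    def test_exact_copy_fully_conserved(self):
        a = _gene("a", [(0, 300), (500, 800)])
        b = _gene("b", [(10_000, 10_300), (10_500, 10_800)])
        assert compare_structures(a, b).conservation_class == "fully_conserved"

    def test_intron_drift_only_is_exons_conserved(self):
        a = _gene("a", [(0, 300), (1500, 1800)])      # intron 1200
        b = _gene("b", [(0, 300), (1800, 2100)])      # intron 1500
        cmp = compare_structures(a, b)
        assert cmp.conservation_class == "exons_conserved"
        assert cmp.exon_lengths_equal and not cmp.intron_lengths_equal

    def test_different_exon_counts_divergent(self):
        a = _gene("a", [(0, 300)])
        b = _gene("b", [(0, 150), (400, 550)])
        assert compare_structures(a, b).conservation_class == "divergent"

    def test_opposite_strands_compared_5prime_to_3prime(self):
        # exon lengths (300, 100) read 5'->3' on both strands
        a = _gene("a", [(0, 300), (500, 600)], strand="+")
        b = _gene("b", [(0, 100), (300, 600)], strand="-")
        assert compare_structures(a, b).exon_lengths_equal

    def test_gene_without_exons_rejected(self):
        a = _gene("a", [(0, 300)])
        bad = GeneModel("b", "c", 0, 10, "+", [])
        with pytest.raises(ValueError, match="no exons"):
            compare_structures(a, bad)
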