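"""Duplicate pairing, codon alignment, NG86 Ka/Ks, and divergence dating."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import ng86_differences_oracle, ng86_oracle, ng86_sites_oracle
from zfscan import synthetic_data
from zfscan.evolution import (
    STOP_CODONS,
    codon_align,
    codon_differences,
    codon_sites,
    divergence_time,
    find_duplicate_pairs,
    kaks_ng86,
    selection_call,
    translate_codon,
)
from zfscan.io_formats import SequenceRecord
from zfscan.phylogeny import DistanceMatrix

SENSE_CODONS = sorted(
    c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in STOP_CODONS
)

codon_strategy = st.sampled_from(SENSE_CODONS)


class TestDuplicatePairs:
    def test_two_tight_pairs(self):
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 0.1, 0.9, 0.8],
             [0.1, 0, 0.85, 0.9],
             [0.9, 0.85, 0, 0.05],
             [0.8, 0.9, 0.05, 0]]
        )
        assert find_duplicate_pairs(DistanceMatrix(labels, d)) == [("a", "b"), ("c", "d")]

    def test_chain_returns_only_mutual_pair(self):
        # b is nearest to both a and c; only the mutual (a, b) pair survives
        d = np.array([[0, 0.1, 0.5], [0.1, 0, 0.2], [0.5, 0.2, 0]])
        assert find_duplicate_pairs(DistanceMatrix(["a", "b", "c"], d)) == [("a", "b")]

    def test_single_gene_empty(self):
        assert find_duplicate_pairs(DistanceMatrix(["a"], np.zeros((1, 1)))) == []


class TestCodonAlign:
    def test_identical_gapless(self):
        cds = "ATGAAATTT"
        prot = "MKF"
        a, b = codon_align(prot, prot, cds, cds)
        assert a == b == cds

    def test_gap_becomes_triplet(self):
        a, b = codon_align("MKF", "M-F", "ATGAAATTT", "ATGTTT")
        assert b == "ATG---TTT"

    def test_terminal_stop_tolerated(self):
        a, _ = codon_align("MK", "MK", "ATGAAATAA", "ATGAAA")
        assert a == "ATGAAA"

    def test_length_not_multiple_of_three_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_align("MK", "MK", "ATGAAAT", "ATGAAA")

    def test_translation_mismatch_names_codon(self):
        with pytest.raises(ValueError, match="codon 2"):
            codon_align("MM", "MK", "ATGAAA", "ATGAAA")


class TestNG86:
    def test_identical_sequences_zero(self):
        assert kaks_ng86("ATGAAATTT", "ATGAAATTT") == (0.0, 0.0)

    def test_single_synonymous_change(self):
        a = "ATGGCTGCTGCTGCT"
        b = "ATGGCCGCTGCTGCT"  # GCT->GCC, Ala->Ala
        ka, ks = kaks_ng86(a, b)
        assert ka == 0.0 and ks > 0.0

    def test_sites_match_oracle_all_codons(self):
        for codon in SENSE_CODONS:
            assert codon_sites(codon) == pytest.approx(ng86_sites_oracle(codon), abs=1e-12)

    def test_site_sum_is_three_without_stop_neighbours(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            stop_neighbours = sum(
                1
                for pos in range(3)
                for bch in "ACGT"
                if bch != codon[pos]
                and codon[:pos] + bch + codon[pos + 1 :] in STOP_CODONS
            )
            assert s + n == pytest.approx(3 - stop_neighbours / 3, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=codon_strategy, b=codon_strategy)
    def test_pathway_averaging_matches_oracle(self, a, b):
        assert codon_differences(a, b) == pytest.approx(
            ng86_differences_oracle(a, b), abs=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(codon_strategy, codon_strategy), min_size=3, max_size=20))
    def test_symmetry(self, pairs):
        a = "".join(p[0] for p in pairs)
        b = "".join(p[1] for p in pairs)
        assert kaks_ng86(a, b) == pytest.approx(kaks_ng86(b, a), nan_ok=True)

    def test_whole_alignment_matches_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            codons_a, codons_b = [], []
            for _ in range(30):
                ca = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
                cb = list(ca)
                for pos in rng.choice(3, size=rng.integers(0, 3), replace=False):
                    cb[pos] = "ACGT"[rng.integers(4)]
                cb = "".join(cb)
                if cb in STOP_CODONS:
                    cb = ca
                codons_a.append(ca)
                codons_b.append(cb)
            got = kaks_ng86("".join(codons_a), "".join(codons_b))
            want = ng86_oracle(codons_a, codons_b)
            assert got == pytest.approx(want, abs=1e-12, nan_ok=True)

    def test_gapped_codons_skipped(self):
        ka, ks = kaks_ng86("ATG---GCT", "ATGAAAGCT")
        assert (ka, ks) == (0.0, 0.0)

    def test_all_gaps_raise(self):
        with pytest.raises(ValueError):
            kaks_ng86("---", "ATG")


class TestDivergenceTime:
    def test_formula_example(self):
        assert divergence_time(0.13) == pytest.approx(10.0)

    def test_zero(self):
        assert divergence_time(0.0) == 0.0

    def test_linearity_and_lambda_scaling(self):
        for ks in np.linspace(0.0, 1.0, 11):
            assert divergence_time(2 * ks) == pytest.approx(2 * divergence_time(ks))
            assert divergence_time(ks, 1.3e-8) == pytest.approx(divergence_time(ks) / 2)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            divergence_time(-0.1)


class TestSelectionCall:
    @pytest.mark.parametrize(
        "ka,ks,expected",
        [
            (0.1, 0.5, "purifying"),
            (0.5, 0.5, "neutral"),
            (0.9, 0.5, "positive"),
            (0.2, 0.0, "undefined"),
            (float("nan"), 0.5, "undefined"),
        ],
    )
    def test_calls(self, ka, ks, expected):
        assert selection_call(ka, ks) == expected


class TestTargetRecovery:
    def test_generator_targets_recovered_over_seeds(self):
        """Mean NG86 estimates across seeded replicates sit within 3 SE of
        the generator's Ks/Ka targets; all pairs read as purifying."""
        kss, kas = [], []
        for seed in range(20):
            a, b, _ = synthetic_data.generate_cds_pair(0.1, 0.02, 300, seed=seed)
            ka, ks = kaks_ng86(a.residues, b.residues)
            assert selection_call(ka, ks) == "purifying"
            kss.append(ks)
            kas.append(ka)
        for vals, target in ((kss, 0.1), (kas, 0.02)):
            arr = np.array(vals)
            se = arr.std(ddof=1) / math.sqrt(len(arr))
            assert abs(arr.mean() - target) <= 3 * se
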