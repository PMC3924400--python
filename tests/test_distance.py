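"""Hamming primitives: plain, packed, pair mask, consensus distance."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pms8 import DNA, PROTEIN, Instance, generate_planted_instance
from pms8.distance import (
    LmerRef,
    consensus_string,
    consensus_total_distance,
    cross_distance_matrix,
    cross_distance_matrix_direct,
    hamming_distance,
    pack_all_lmers,
    packed_distance,
    precompute_pair_flags,
    window_matrix,
)

dna_strings = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestHamming:
    @pytest.mark.parametrize(
        "u,v,expected",
        [("ACGT", "ACGT", 0), ("AAAA", "TTTT", 4), ("ACGT", "ACGA", 1)],
    )
    def test_examples(self, u, v, expected):
        assert hamming_distance(u, v) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance("AC", "ACG")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(dna_strings, dna_strings, dna_strings)
    def test_metric_axioms(self, a, b, c):
        n = min(len(a), len(b), len(c))
        a, b, c = a[:n], b[:n], c[:n]
        assert hamming_distance(a, a) == 0
        assert hamming_distance(a, b) == hamming_distance(b, a)
        assert hamming_distance(a, c) <= hamming_distance(a, b) + hamming_distance(b, c)


class TestPackedTable:
    def test_single_window(self):
        table = pack_all_lmers(Instance(["ACGT"]), 4)
        assert table.n_windows(0) == 1
        assert DNA.decode(table.unpack(LmerRef(0, 0))) == "ACGT"

    def test_overlapping_windows_unpack(self):
        table = pack_all_lmers(Instance(["ACGTA"]), 4)
        assert table.n_windows(0) == 2
        assert DNA.decode(table.unpack(LmerRef(0, 0))) == "ACGT"
        assert DNA.decode(table.unpack(LmerRef(0, 1))) == "CGTA"

    def test_storage_is_linear_not_quadratic(self):
        inst, _ = generate_planted_instance(2, 300, 13, 4, seed=0)
        table = pack_all_lmers(inst, 13)
        assert sum(len(p) for p in table.packed) == 2 * 300

    @pytest.mark.parametrize("alphabet,l", [(DNA, 13), (PROTEIN, 7)])
    def test_packed_distance_equals_plain(self, alphabet, l):
        inst, _ = generate_planted_instance(5, 80, l, 2, alphabet=alphabet, seed=9)
        table = pack_all_lmers(inst, l)
        rng = np.random.default_rng(0)
        for _ in range(1000):
            i, j = rng.integers(0, 5, size=2)
            oi = int(rng.integers(0, 80 - l + 1))
            oj = int(rng.integers(0, 80 - l + 1))
            a, b = LmerRef(int(i), oi), LmerRef(int(j), oj)
            expected = hamming_distance(
                inst.sequences[a.seq_index][oi : oi + l],
                inst.sequences[b.seq_index][oj : oj + l],
            )
            assert packed_distance(table, a, b) == expected

    def test_cross_matrix_packed_equals_direct(self):
        inst, _ = generate_planted_instance(3, 60, 11, 3, seed=4)
        table = pack_all_lmers(inst, 11)
        codes = inst.encoded()
        for i, j in [(0, 1), (1, 2)]:
            packed = cross_distance_matrix(table, i, j)
            direct = cross_distance_matrix_direct(
                window_matrix(codes[i], 11), window_matrix(codes[j], 11)
            )
            assert np.array_equal(packed, direct)

    def test_l_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            pack_all_lmers(Instance(["ACG"]), 4)

    def test_out_of_range_ref_rejected(self):
        table = pack_all_lmers(Instance(["ACGT"]), 4)
        with pytest.raises(IndexError):
            packed_distance(table, LmerRef(0, 0), LmerRef(0, 1))


class TestPairFlags:
    def test_threshold_l_is_all_true(self):
        inst, _ = generate_planted_instance(3, 20, 5, 1, seed=1)
        mask = precompute_pair_flags(pack_all_lmers(inst, 5), 5)
        assert all(m.all() for m in mask.masks.values())

    def test_threshold_zero_marks_identical_windows(self):
        inst = Instance(["ACGTT", "ACGAA"])
        mask = precompute_pair_flags(pack_all_lmers(inst, 4), 0)
        assert mask.get(LmerRef(0, 0), LmerRef(1, 0)) is False
        inst2 = Instance(["ACGT", "ACGT"])
        mask2 = precompute_pair_flags(pack_all_lmers(inst2, 4), 0)
        assert mask2.get(LmerRef(0, 0), LmerRef(1, 0)) is True

    def test_agrees_with_direct_evaluation_everywhere(self):
        inst, _ = generate_planted_instance(5, 20, 6, 2, seed=3)
        mask = precompute_pair_flags(pack_all_lmers(inst, 6), 4)
        for i in range(5):
            for j in range(i + 1, 5):
                for oi in range(15):
                    for oj in range(15):
                        expected = (
                            hamming_distance(
                                inst.sequences[i][oi : oi + 6],
                                inst.sequences[j][oj : oj + 6],
                            )
                            <= 4
                        )
                        assert mask.get(LmerRef(i, oi), LmerRef(j, oj)) == expected

    def test_symmetry_of_lookup(self):
        inst, _ = generate_planted_instance(3, 15, 5, 1, seed=8)
        mask = precompute_pair_flags(pack_all_lmers(inst, 5), 2)
        a, b = LmerRef(0, 3), LmerRef(2, 7)
        assert mask.get(a, b) == mask.get(b, a)

    def test_same_sequence_pairs_not_stored(self):
        inst, _ = generate_planted_instance(3, 15, 5, 1, seed=8)
        mask = precompute_pair_flags(pack_all_lmers(inst, 5), 2)
        with pytest.raises(ValueError):
            mask.get(LmerRef(1, 0), LmerRef(1, 1))


class TestConsensus:
    def test_identical_strings_have_zero_distance(self):
        assert consensus_total_distance(["AC", "AC", "AC"]) == 0

    def test_pair_consensus_equals_hamming(self):
        # C(A,B) = H(A,B) for any pair
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = DNA.decode(rng.integers(0, 4, 8))
            b = DNA.decode(rng.integers(0, 4, 8))
            assert consensus_total_distance([a, b]) == hamming_distance(a, b)

    def test_three_string_example(self):
        T = ["AAA", "AAC", "ACC"]
        # exhaustive minimum of total distance over all 64 DNA 3-mers
        best = min(
            sum(hamming_distance("".join(m), t) for t in T)
            for m in product("ACGT", repeat=3)
        )
        assert best == 2
        assert consensus_total_distance(T) == 2

    def test_consensus_string_achieves_the_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            T = [DNA.decode(rng.integers(0, 4, 5)) for _ in range(4)]
            cs = consensus_string(T)
            total = sum(hamming_distance(cs, t) for t in T)
            assert total == consensus_total_distance(T)

    def test_consensus_is_a_lower_bound_over_all_strings(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            T = [DNA.decode(rng.integers(0, 4, 4)) for _ in range(3)]
            cd = consensus_total_distance(T)
            for m in product("ACGT", repeat=4):
                assert cd <= sum(hamming_distance("".join(m), t) for t in T)

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            consensus_total_distance(["AC", "ACG"])
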