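"""The exact search: oracle equivalence, invariances, heuristics."""

import numpy as np
import pytest

from pms8 import (
    DNA,
    Instance,
    SearchParams,
    generate_common_neighborhood,
    generate_planted_instance,
    pms8_search,
    verify_motif,
)
from pms8.oracle import brute_force_search
from pms8.search import (
    CandidateMatrix,
    choose_n_prime,
    choose_threshold_t,
    filter_row,
    sort_rows_by_size,
)
from conftest import TOY5


class TestSearchCorrectness:
    def test_planted_motif_is_reported(self, small_planted):
        instance, record = small_planted
        result = pms8_search(instance, 7, 2)
        assert record.motif in result.motifs

    def test_single_sequence_is_the_neighborhood(self):
        inst = Instance(["ACGT"])
        result = pms8_search(inst, 4, 1)
        assert result.motifs == generate_common_neighborhood(["ACGT"], [1])

    def test_equals_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(12):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(20, 50))
            l = int(rng.integers(4, 8))
            d = int(rng.integers(0, 3))
            inst, _ = generate_planted_instance(n, m, l, d, seed=1000 + trial)
            assert pms8_search(inst, l, d).motifs == brute_force_search(inst, l, d)

    def test_equals_brute_force_on_toy5_alphabet(self):
        inst, _ = generate_planted_instance(5, 30, 5, 1, alphabet=TOY5, seed=3)
        assert pms8_search(inst, 5, 1).motifs == brute_force_search(inst, 5, 1)

    def test_d_zero_is_exact_common_substring(self):
        inst, rec = generate_planted_instance(5, 40, 6, 0, seed=4)
        result = pms8_search(inst, 6, 0)
        assert rec.motif in result.motifs
        for m in result.motifs:
            assert all(m in s for s in inst.sequences)

    def test_unequal_sequence_lengths_accepted(self):
        inst = Instance(["ACGTACGTAA", "CGTAC", "TACGT"])
        assert pms8_search(inst, 5, 1).motifs == brute_force_search(inst, 5, 1)

    def test_invalid_parameters_rejected(self):
        inst = Instance(["ACGT", "ACG"])
        with pytest.raises(ValueError):
            pms8_search(inst, 4, 1)  # l > shortest sequence
        with pytest.raises(ValueError):
            pms8_search(Instance(["ACGT"]), 3, 4)  # d > l

    def test_positions_are_valid_witnesses(self, small_planted):
        instance, _ = small_planted
        result = pms8_search(instance, 7, 2, with_positions=True)
        for m, offsets in result.positions.items():
            for i, j in enumerate(offsets):
                window = instance.sequences[i][j : j + 7]
                assert sum(a != b for a, b in zip(m, window)) <= 2

    def test_debug_checks_pass(self, small_planted):
        instance, record = small_planted
        result = pms8_search(instance, 7, 2, SearchParams(debug_checks=True))
        assert record.motif in result.motifs


class TestConfigurationInvariance:
    def test_speedup_toggles_do_not_change_output(self, small_planted):
        instance, _ = small_planted
        base = pms8_search(instance, 7, 2).motifs
        import itertools

        for sr, pt, pk, mf in itertools.product([False, True], repeat=4):
            params = SearchParams(sort_rows=sr, pair_table=pt, packing=pk,
                                  minimal_filter=mf)
            assert pms8_search(instance, 7, 2, params).motifs == base

    def test_threshold_sweep(self, small_planted):
        instance, _ = small_planted
        base = pms8_search(instance, 7, 2).motifs
        for t in (2, 3, 4):
            params = SearchParams(threshold_t=t)
            assert pms8_search(instance, 7, 2, params).motifs == base

    def test_n_prime_sweep(self, small_planted):
        instance, _ = small_planted
        base = pms8_search(instance, 7, 2).motifs
        for np_ in range(2, instance.n + 1):
            params = SearchParams(threshold_t=2, n_prime=np_)
            assert pms8_search(instance, 7, 2, params).motifs == base


class TestHeuristics:
    def test_threshold_floor_is_two(self):
        # tiny d and huge m push the formula below 2
        assert choose_threshold_t(10**6, 0, 4) == 2

    def test_threshold_monotone_in_d(self):
        for d in range(6):
            assert choose_threshold_t(600, d + 1, 4) >= choose_threshold_t(600, d, 4)

    def test_threshold_antitone_in_m(self):
        for m in (100, 300, 600):
            assert choose_threshold_t(2 * m, 4, 4) <= choose_threshold_t(m, 4, 4)

    def test_n_prime_standard_value(self):
        assert choose_n_prime(20, 2) == 6  # floor(2 + 5 - ln 2)

    def test_n_prime_clamps(self):
        assert choose_n_prime(3, 5) == 3
        assert choose_n_prime(100, 2) >= 2


class TestRowFiltering:
    def test_2d_filter_removes_distant_lmers(self):
        # H("AAAAA", "TTTTT") = 5 > 2d = 4
        kept = filter_row(["AAAAA", "TTTTT", "AAATT"], "AAAAA", [], 2)
        assert kept == ["AAAAA", "AAATT"]

    def test_exact_copy_always_kept(self):
        kept = filter_row(["ACGTA"], "ACGTA", ["ACGTT"], 1)
        assert kept == ["ACGTA"]

    def test_filtering_never_removes_motif_witnesses(self):
        # removing the filter entirely must not change the final output
        inst, _ = generate_planted_instance(6, 35, 6, 2, seed=9)
        strong = pms8_search(inst, 6, 2, SearchParams(minimal_filter=False))
        minimal = pms8_search(inst, 6, 2, SearchParams(minimal_filter=True))
        assert strong.motifs == minimal.motifs


class TestCandidateMatrix:
    def test_sort_by_size_example(self):
        mat = CandidateMatrix([5, 2, 9])
        assert sort_rows_by_size(mat) == [1, 0, 2]

    def test_sort_is_stable_on_ties(self):
        mat = CandidateMatrix([4, 4, 4])
        assert sort_rows_by_size(mat) == [0, 1, 2]

    def test_pop_restores_row_contents_as_sets(self):
        mat = CandidateMatrix([6])
        before = set(mat.active(0).tolist())
        mat.push_snapshot()
        keep = np.array([True, False, True, False, True, False])
        mat.apply_keep(0, keep)
        assert set(mat.active(0).tolist()) == {0, 2, 4}
        mat.pop_snapshot()
        assert set(mat.active(0).tolist()) == before

    def test_nested_push_pop(self):
        mat = CandidateMatrix([4])
        mat.push_snapshot()
        mat.apply_keep(0, np.array([True, True, False, False]))
        mat.push_snapshot()
        mat.apply_keep(0, np.array([True, False]))
        assert mat.sizes[0] == 1
        mat.pop_snapshot()
        assert mat.sizes[0] == 2
        mat.pop_snapshot()
        assert mat.sizes[0] == 4


class TestVerifyMotif:
    def test_planted_motif_verifies(self, small_planted):
        instance, record = small_planted
        assert verify_motif(record.motif, instance, 7, 2)

    def test_distant_motif_rejected(self):
        inst = Instance(["AAAAA", "AAAAA"])
        assert verify_motif("TTTTT", inst, 5, 2) is False

    def test_from_row_skips_earlier_sequences(self):
        inst = Instance(["TTTTT", "AAAAT"])
        assert verify_motif("AAAAA", inst, 5, 1, from_row=1) is True
        assert verify_motif("AAAAA", inst, 5, 1, from_row=0) is False

    def test_agrees_with_direct_scan(self):
        rng = np.random.default_rng(12)
        inst, _ = generate_planted_instance(4, 25, 5, 1, seed=13)
        for _ in range(50):
            M = DNA.decode(rng.integers(0, 4, 5))
            direct = all(
                min(
                    sum(a != b for a, b in zip(M, s[j : j + 5]))
                    for j in range(len(s) - 4)
                ) <= 1
                for s in inst.sequences
            )
            assert verify_motif(M, inst, 5, 1) == direct
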