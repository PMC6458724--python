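import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rowlcs.core_lcs import lcs_length, lcs_table
from rowlcs.rowpar import (
    ExecutionPolicy,
    build_occurrence_table,
    lcs_length_rowwise,
    partition,
    row_update_v1,
    row_update_v2,
)
from rowlcs.seqio import build_alphabet

from conftest import random_pair

dna = st.text(alphabet="ACGT", max_size=30)


def brute_last_occurrence(b: str, ch: str, j: int) -> int:
    """Largest 1-based p <= j with b[p] == ch, else 0 (independent oracle)."""
    for p in range(j, 0, -1):
        if b[p - 1] == ch:
            return p
    return 0


class TestExecutionPolicy:
    def test_defaults(self):
        policy = ExecutionPolicy()
        assert policy.workers >= 1 and policy.workers <= 16
        assert policy.schedule == "static" and policy.chunk == "auto"

    @pytest.mark.parametrize("kwargs", [
        {"workers": 0},
        {"workers": -2},
        {"schedule": "roundrobin"},
        {"chunk": 0},
        {"chunk": "biggest"},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ExecutionPolicy(**kwargs)


class TestOccurrenceTable:
    def test_v2_direct_known_row(self):
        alpha = build_alphabet("ACGT", "AGT")
        table = build_occurrence_table("AGT", alpha, "v2_direct")
        assert table.row(alpha.rank["G"]).tolist() == [0, 0, 2, 2]

    def test_v1_offset_known_row(self):
        alpha = build_alphabet("ACGT", "AGT")
        table = build_occurrence_table("AGT", alpha, "v1_offset")
        assert table.row(alpha.rank["G"]).tolist() == [-1, -1, 1, 1]

    @given(dna)
    def test_column_zero_base_case(self, b):
        alpha = build_alphabet(b, "ACGT")
        direct = build_occurrence_table(b, alpha, "v2_direct")
        offset = build_occurrence_table(b, alpha, "v1_offset")
        assert (direct.values[:, 0] == 0).all()
        assert (offset.values[:, 0] == -1).all()

    def test_character_missing_from_alphabet(self):
        with pytest.raises(ValueError):
            build_occurrence_table("ACGN", build_alphabet("ACGT", ""), "v2_direct")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            build_occurrence_table("ACGT", build_alphabet("ACGT", ""), "v3")

    @given(dna)
    @settings(max_examples=100)
    def test_matches_brute_force_scan(self, b):
        alpha = build_alphabet(b, "ACGT")
        direct = build_occurrence_table(b, alpha, "v2_direct")
        offset = build_occurrence_table(b, alpha, "v1_offset")
        for c, ch in enumerate(alpha.symbols, start=1):
            for j in range(len(b) + 1):
                occ = brute_last_occurrence(b, ch, j)
                assert direct.values[c - 1, j] == occ
                assert offset.values[c - 1, j] == occ - 1

    @given(dna)
    def test_v2_rows_nondecreasing_and_bounded(self, b):
        alpha = build_alphabet(b, "ACGT")
        values = build_occurrence_table(b, alpha, "v2_direct").values
        assert (np.diff(values, axis=1) >= 0).all()
        assert (values >= 0).all()
        assert (values <= np.arange(len(b) + 1)).all()


class TestRowUpdates:
    def setup_method(self):
        self.a, self.b = "ACGT", "AGT"
        self.alpha = build_alphabet(self.a, self.b)
        self.p1 = build_occurrence_table(self.b, self.alpha, "v1_offset")
        self.p2 = build_occurrence_table(self.b, self.alpha, "v2_direct")

    def test_v1_first_row(self):
        out = row_update_v1(np.zeros(4, dtype=int), 1, self.a, self.b, self.alpha, self.p1)
        assert out.tolist() == [0, 1, 1, 1]

    def test_v2_first_row(self):
        out = row_update_v2(np.zeros(4, dtype=int), self.alpha.rank["A"], self.p2)
        assert out.tolist() == [0, 1, 1, 1]

    def test_v1_character_absent_from_b_carries_prev(self):
        # row 2 of A is 'C', absent from B: pure carry-down branch
        prev = np.array([0, 1, 1, 1])
        out = row_update_v1(prev, 2, self.a, self.b, self.alpha, self.p1)
        assert out.tolist() == prev.tolist()

    def test_v2_all_zero_p_row_carries_prev(self):
        prev = np.array([0, 1, 1, 1])
        out = row_update_v2(prev, self.alpha.rank["C"], self.p2)
        assert out.tolist() == prev.tolist()

    def test_v2_known_last_row(self):
        out = row_update_v2(np.array([0, 1, 2, 2]), self.alpha.rank["T"], self.p2)
        assert out.tolist() == [0, 1, 2, 3]

    def test_v1_full_iteration_reaches_lcs(self):
        row = np.zeros(4, dtype=int)
        for i in range(1, 5):
            row = row_update_v1(row, i, self.a, self.b, self.alpha, self.p1)
        assert row[-1] == 3

    def test_v1_rejects_wrong_prev_length(self):
        with pytest.raises(ValueError):
            row_update_v1(np.zeros(7), 1, self.a, self.b, self.alpha, self.p1)

    def test_v2_rejects_rank_out_of_range(self):
        with pytest.raises(ValueError):
            row_update_v2(np.zeros(4), 5, self.p2)

    def test_variant_mismatch(self):
        with pytest.raises(ValueError):
            row_update_v1(np.zeros(4), 1, self.a, self.b, self.alpha, self.p2)
        with pytest.raises(ValueError):
            row_update_v2(np.zeros(4), 1, self.p1)

    @given(dna, dna)
    @settings(max_examples=60)
    def test_rows_match_classical_table(self, a, b):
        table = lcs_table(a, b)
        alpha = build_alphabet(a, b)
        p1 = build_occurrence_table(b, alpha, "v1_offset")
        p2 = build_occurrence_table(b, alpha, "v2_direct")
        for i in range(1, len(a) + 1):
            prev = table[i - 1]
            expected = table[i].tolist()
            assert row_update_v1(prev, i, a, b, alpha, p1).tolist() == expected
            assert row_update_v2(prev, alpha.rank[a[i - 1]], p2).tolist() == expected


class TestPartition:
    def test_static_fixed_chunks(self):
        policy = ExecutionPolicy(workers=3, schedule="static", chunk=4)
        assert partition(10, policy) == [(1, 4), (5, 8), (9, 10)]

    def test_empty(self):
        assert partition(0, ExecutionPolicy(workers=4, schedule="dynamic")) == []

    def test_static_auto_is_ceiling_division(self):
        policy = ExecutionPolicy(workers=2, schedule="static", chunk="auto")
        assert partition(7, policy) == [(1, 4), (5, 7)]

    def test_guided_shrinks_with_floor(self):
        policy = ExecutionPolicy(workers=2, schedule="guided", chunk=2)
        ranges = partition(10, policy)
        sizes = [hi - lo + 1 for lo, hi in ranges]
        assert sizes == sorted(sizes, reverse=True)
        assert min(sizes[:-1] or sizes) >= 2

    @given(st.integers(0, 200), st.integers(1, 9),
           st.sampled_from(["static", "dynamic", "guided"]),
           st.sampled_from([1, 3, 16, "auto"]))
    def test_disjoint_exact_cover(self, n, workers, schedule, chunk):
        policy = ExecutionPolicy(workers=workers, schedule=schedule, chunk=chunk)
        ranges = partition(n, policy)
        covered = [j for lo, hi in ranges for j in range(lo, hi + 1)]
        assert covered == list(range(1, n + 1))


class TestLcsLengthRowwise:
    def test_known_v2(self, serial_policy):
        assert lcs_length_rowwise("ACGT", "AGT", "v2", serial_policy) == 3

    def test_known_v1_parallel_policy(self):
        policy = ExecutionPolicy(workers=4, schedule="static", chunk=2)
        assert lcs_length_rowwise("AGCAT", "GAC", "v1", policy) == 2

    @pytest.mark.parametrize("version", ["v1", "v2"])
    def test_empty(self, version):
        assert lcs_length_rowwise("", "ACGT", version) == 0
        assert lcs_length_rowwise("ACGT", "", version) == 0

    def test_invalid_version(self):
        with pytest.raises(ValueError):
            lcs_length_rowwise("A", "A", "v3")

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            lcs_length_rowwise("A", "A", "v2", policy="static")

    @given(dna, dna)
    @settings(max_examples=60, deadline=None)
    def test_equivalence_with_classical(self, a, b):
        expected = lcs_length(a, b)
        assert lcs_length_rowwise(a, b, "v1") == expected
        assert lcs_length_rowwise(a, b, "v2") == expected

    def test_policy_invariance_sample(self, rng):
        for _ in range(5):
            a, b = random_pair(rng, max_len=80)
            expected = lcs_length(a, b)
            for workers in (1, 2, 4):
                for schedule in ("static", "dynamic", "guided"):
                    for chunk in (1, 16, "auto"):
                        policy = ExecutionPolicy(workers=workers, schedule=schedule,
                                                 chunk=chunk)
                        for version in ("v1", "v2"):
                            assert lcs_length_rowwise(a, b, version, policy) == expected

    def test_threaded_path_matches_serial(self):
        # long enough to cross the thread-pool threshold
        rng = np.random.Generator(np.random.PCG64(7))
        a = "".join(rng.choice(list("ACGT"), size=64))
        b = "".join(rng.choice(list("ACGT"), size=9000))
        expected = lcs_length_rowwise(a, b, "v2", ExecutionPolicy(workers=1))
        for schedule in ("static", "dynamic", "guided"):
            policy = ExecutionPolicy(workers=4, schedule=schedule, chunk=512)
            assert lcs_length_rowwise(a, b, "v2", policy) == expected
            assert lcs_length_rowwise(a, b, "v1", policy) == expected
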