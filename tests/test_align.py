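"""Alignment engine vs an independent brute-force DP oracle, plus alignment
statistics, e-values, progressive MSA, and conserved-block trimming."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    enumerate_short_local_alignments,
    global_score_oracle,
    local_score_oracle,
    random_protein,
    surviving_columns_oracle,
)
from sterolscan.align import (
    AlignmentResult,
    EvalueParams,
    MultipleAlignment,
    SubstitutionMatrix,
    estimate_evalue,
    global_align,
    local_align,
    progressive_msa,
    read_msa,
    trim_conserved_blocks,
    write_msa,
)
from sterolscan.core_io import ProteinRecord


def rec(rid, seq):
    return ProteinRecord(id=rid, sequence=seq)


class TestPairwiseVsOracle:
    def test_textbook_peptides_blosum50(self):
        # classic pair with BLOSUM50, gap open 10 / extend 1
        b50 = SubstitutionMatrix.load("BLOSUM50")
        a, b = "HEAGAWGHEE", "PAWHEAE"
        oracle = local_score_oracle(a, b, b50, 10, 1)
        result = local_align(rec("a", a), rec("b", b), b50, 10, 1)
        assert result.raw_score == oracle == 25.0

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_random_instances_match_oracle(self, blosum62, mode):
        rng = np.random.default_rng(20240917)
        align = local_align if mode == "local" else global_align
        oracle = local_score_oracle if mode == "local" else global_score_oracle
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(10, 61)))
            b = random_protein(rng, int(rng.integers(10, 61)))
            expected = oracle(a, b, blosum62, 11, 1)
            got = align(rec("a", a), rec("b", b), blosum62, 11, 1).raw_score
            assert got == pytest.approx(expected, abs=1e-9)

    def test_local_score_dominates_short_subalignments(self, blosum62):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = random_protein(rng, 25)
            b = random_protein(rng, 25)
            score = local_align(rec("a", a), rec("b", b), blosum62).raw_score
            assert score >= 0
            assert score >= enumerate_short_local_alignments(a, b, blosum62, max_len=3)

    def test_self_alignment_scores_diagonal_sum(self, blosum62):
        rng = np.random.default_rng(7)
        seq = random_protein(rng, 50)
        result = local_align(rec("a", seq), rec("b", seq), blosum62)
        assert result.percent_identity == 100.0
        assert result.raw_score == sum(blosum62.score(c, c) for c in seq)


class TestPairwiseStatistics:
    def test_identity_is_100_on_self_and_symmetric(self, blosum62):
        rng = np.random.default_rng(11)
        a = random_protein(rng, 40)
        b = random_protein(rng, 35)
        assert global_align(rec("a", a), rec("a2", a), blosum62).percent_identity == 100.0
        ab = global_align(rec("a", a), rec("b", b), blosum62).percent_identity
        ba = global_align(rec("b", b), rec("a", a), blosum62).percent_identity
        assert ab == pytest.approx(ba)

    def test_identity_bounded_by_similarity(self, blosum62):
        rng = np.random.default_rng(13)
        for _ in range(5):
            a = random_protein(rng, 30)
            b = random_protein(rng, 30)
            r = global_align(rec("a", a), rec("b", b), blosum62)
            assert 0 <= r.percent_identity <= r.percent_similarity <= 100

    def test_global_identical_sequences_have_no_gap_columns(self, blosum62):
        r = global_align(rec("a", "MKLVWNAG"), rec("b", "MKLVWNAG"), blosum62)
        assert r.alignment_length == 8 == len(r.aligned_pairs)

    def test_global_length_difference_yields_one_gap_column(self, blosum62):
        r = global_align(rec("a", "AAA"), rec("b", "AA"), blosum62)
        assert r.alignment_length == 3
        assert len(r.aligned_pairs) == 2

    def test_aligned_pairs_strictly_increasing(self, blosum62):
        rng = np.random.default_rng(17)
        a, b = random_protein(rng, 45), random_protein(rng, 40)
        r = local_align(rec("a", a), rec("b", b), blosum62)
        qs = [q for q, _ in r.aligned_pairs]
        ss = [s for _, s in r.aligned_pairs]
        assert qs == sorted(set(qs)) and ss == sorted(set(ss))

    def test_empty_sequence_is_precondition_error(self, blosum62):
        good = rec("a", "MKLV")
        with pytest.raises(Exception):
            ProteinRecord(id="b", sequence="")  # cannot even be constructed
        with pytest.raises(ValueError):
            local_align(good, good.__class__(id="b", sequence="M"), blosum62, -1, -1)


class TestEvalue:
    def _result(self, score):
        return AlignmentResult(
            query_id="q",
            subject_id="s",
            aligned_pairs=(),
            raw_score=score,
            percent_identity=0.0,
            percent_similarity=0.0,
            alignment_length=0,
        )

    def test_zero_score_gives_K_times_search_space(self):
        params = EvalueParams(search_space=1e6)
        assert estimate_evalue(self._result(0), params) == pytest.approx(0.041 * 1e6)

    def test_linear_in_search_space(self):
        r = self._result(50)
        e1 = estimate_evalue(r, EvalueParams(search_space=1e5))
        e2 = estimate_evalue(r, EvalueParams(search_space=2e5))
        assert e2 == pytest.approx(2 * e1)

    def test_strictly_decreasing_in_score(self):
        params = EvalueParams(search_space=1e6)
        evalues = [estimate_evalue(self._result(s), params) for s in range(0, 500, 25)]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EvalueParams(lam=-1)
        with pytest.raises(ValueError):
            EvalueParams(search_space=0.5)


class TestProgressiveMsa:
    def test_identical_sequences_align_gap_free(self, blosum62):
        seq = "MKLVWNAGHE"
        msa = progressive_msa([rec(f"s{i}", seq) for i in range(3)], blosum62)
        assert msa.rows == (seq, seq, seq)

    def test_degapping_reproduces_inputs(self, blosum62):
        rng = np.random.default_rng(23)
        base = random_protein(rng, 60)
        records = [
            rec("full", base),
            rec("del", base[:20] + base[30:]),
            rec("frag", base[10:50]),
            rec("mut", base[:30] + random_protein(rng, 5) + base[35:]),
        ]
        msa = progressive_msa(records, blosum62)
        for r in records:
            assert msa.row(r.id).replace("-", "") == r.sequence

    def test_two_records_reduce_to_global_alignment(self, blosum62):
        rng = np.random.default_rng(29)
        a = rec("a", random_protein(rng, 40))
        b = rec("b", a.sequence[:15] + a.sequence[22:])
        msa = progressive_msa([a, b], blosum62)
        pairwise = global_align(a, b, blosum62)
        # column count of the MSA equals the pairwise alignment length
        assert msa.n_columns == pairwise.alignment_length

    def test_single_record_is_precondition_error(self, blosum62):
        with pytest.raises(ValueError):
            progressive_msa([rec("a", "MKLV")], blosum62)

    def test_msa_fasta_round_trip(self, blosum62, tmp_path):
        msa = progressive_msa([rec("a", "MKLVWNAG"), rec("b", "MKLWNAG")], blosum62)
        path = write_msa(msa, tmp_path / "aln.afa")
        assert read_msa(path) == msa


class TestTrimConservedBlocks:
    def test_gap_free_alignment_unchanged(self):
        msa = MultipleAlignment(ids=("a", "b"), rows=("MKLV", "MKLW"))
        assert trim_conserved_blocks(msa, 0.0, 1) == msa

    def test_majority_gap_column_removed(self):
        # middle column 60% gapped, threshold 0.5
        rows = ("A-A", "A-A", "A-A", "AAA", "AAA")
        msa = MultipleAlignment(ids=tuple("abcde"), rows=rows)
        trimmed = trim_conserved_blocks(msa, 0.5, 1)
        assert trimmed.rows == ("AA", "AA", "AA", "AA", "AA")

    def test_short_blocks_dropped(self):
        rows = ("AA-AAAA", "AA-AAAA")
        msa = MultipleAlignment(ids=("a", "b"), rows=rows)
        trimmed = trim_conserved_blocks(msa, 0.0, 3)
        assert trimmed.rows == ("AAAA", "AAAA")  # leading 2-column block dropped

    def test_all_columns_removed_is_empty_not_error(self):
        msa = MultipleAlignment(ids=("a", "b"), rows=("A-", "-A"))
        trimmed = trim_conserved_blocks(msa, 0.0, 1)
        assert trimmed.n_columns == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        data=st.data(),
        max_gap_fraction=st.floats(0, 1),
        min_block=st.integers(1, 4),
    )
    def test_matches_per_column_oracle(self, data, max_gap_fraction, min_block):
        n_rows = data.draw(st.integers(2, 5))
        n_cols = data.draw(st.integers(1, 12))
        rows = tuple(
            "".join(data.draw(st.sampled_from("A-")) for _ in range(n_cols))
            for _ in range(n_rows)
        )
        msa = MultipleAlignment(ids=tuple(f"r{i}" for i in range(n_rows)), rows=rows)
        keep = surviving_columns_oracle(list(rows), max_gap_fraction, min_block)
        expected = tuple("".join(r[j] for j in keep) for r in rows)
        assert trim_conserved_blocks(msa, max_gap_fraction, min_block).rows == expected
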