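"""Aligner correctness against independent oracles, and hit filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synmod import (
    ScoringScheme,
    SimConfig,
    all_vs_all_proteins,
    simulate_module_pair,
    smith_waterman,
    translated_genome_compare,
)
from synmod.align import ALPHABET, read_hits_tsv, write_hits_tsv
from synmod.genome_io import GenomeRecord, reverse_complement

from _oracles import oracle_local_align
from conftest import random_peptide, random_peptide_pairs


class TestSmithWaterman:
    def test_self_alignment_is_perfect(self):
        hit = smith_waterman("MKVLAW", "MKVLAW")
        assert hit.pct_identity == 100.0
        assert hit.pct_similarity == 100.0
        assert hit.aln_len == 6

    def test_all_negative_pair_returns_none(self, scheme):
        # verify from the matrix that no M/K/V vs W substitution is positive
        S = scheme.substitution_matrix()
        for x in "MKV":
            assert S[ALPHABET.index(x), ALPHABET.index("W")] <= 0
        assert smith_waterman("MKV", "WWW") is None

    def test_matches_bruteforce_oracle(self, scheme):
        for a, b in random_peptide_pairs(60, seed=101):
            hit = smith_waterman(a, b, scheme)
            ref = oracle_local_align(a, b, scheme.gap_open, scheme.gap_extend)
            if ref is None:
                assert hit is None
            else:
                assert hit is not None
                assert (hit.score, hit.identities, hit.positives, hit.aln_len) == (
                    ref["score"],
                    ref["identities"],
                    ref["positives"],
                    ref["aln_len"],
                )
                assert (hit.q_end, hit.s_end) == (ref["q_end"], ref["s_end"])

    def test_score_matches_biopython_aligner(self, scheme):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        for a, b in random_peptide_pairs(40, max_len=30, seed=7):
            hit = smith_waterman(a, b, scheme)
            score = aligner.score(a, b)
            assert (hit.score if hit else 0) == max(0, int(score))

    def test_score_symmetry(self, scheme):
        for a, b in random_peptide_pairs(30, max_len=20, seed=3):
            ha = smith_waterman(a, b, scheme)
            hb = smith_waterman(b, a, scheme)
            assert (ha.score if ha else 0) == (hb.score if hb else 0)

    def test_similarity_never_below_identity(self, scheme):
        for a, b in random_peptide_pairs(40, max_len=25, seed=9):
            hit = smith_waterman(a, b, scheme)
            if hit is not None:
                assert hit.pct_similarity >= hit.pct_identity
                assert hit.identities <= hit.positives <= hit.aln_len
                assert hit.gaps <= hit.aln_len

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=15),
    )
    def test_alignment_invariants_for_arbitrary_peptides(self, a, b):
        hit = smith_waterman(a, b)
        rev = smith_waterman(b, a)
        assert (hit.score if hit else 0) == (rev.score if rev else 0)
        if hit is not None:
            assert hit.score > 0
            assert hit.identities <= hit.positives <= hit.aln_len
            assert hit.pct_similarity >= hit.pct_identity
            assert 1 <= hit.q_start <= hit.q_end <= len(a)
            assert 1 <= hit.s_start <= hit.s_end <= len(b)

    def test_invalid_residue_error_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            smith_waterman("MK7V", "MKV")

    def test_gap_cost_convention(self, scheme):
        # one internal gap of length 1 costs open + extend = 12
        hit = smith_waterman("MKVLAWQERTYIP", "MKVLAWERTYIP", scheme)
        assert hit.gaps == 1
        no_gap = sum(
            int(scheme.substitution_matrix()[ALPHABET.index(x), ALPHABET.index(x)])
            for x in "MKVLAWERTYIP"
        )
        # the Q aligns to a gap column: 12 identity columns minus one
        # length-1 gap costing open + extend
        assert hit.score == no_gap - (scheme.gap_open + scheme.gap_extend)


class TestScoringScheme:
    def test_gap_penalty_ordering_enforced(self):
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=1, gap_extend=2)

    def test_matrix_symmetric_over_alphabet(self, scheme):
        S = scheme.substitution_matrix()
        assert (S == S.T).all()


class TestAllVsAll:
    def test_recovers_shared_genes_and_only_those(self, small_sim):
        A, B, truth = small_sim
        hits = all_vs_all_proteins(A, B)
        hit_pairs = {(h.query_id, h.subject_id) for h in hits}
        for pair in truth.orthology:
            assert pair in hit_pairs
        assert hits == sorted(hits, key=lambda h: (h.q_rank, h.s_rank))

    def test_full_similarity_filter_empties_diverged_hits(self, small_sim):
        A, B, truth = small_sim
        # planted module is diverged (~60%), so demanding 100% leaves nothing
        assert all_vs_all_proteins(A, B, min_similarity=100.0) == []

    def test_threshold_monotonicity(self, small_sim):
        A, B, _ = small_sim
        loose = {
            (h.query_id, h.subject_id)
            for h in all_vs_all_proteins(A, B, min_similarity=20, min_score=0)
        }
        for stricter in (
            dict(min_similarity=50, min_score=0),
            dict(min_similarity=20, min_score=100),
            dict(min_similarity=20, min_score=0, min_aln_len=100),
        ):
            strict = {
                (h.query_id, h.subject_id) for h in all_vs_all_proteins(A, B, **stricter)
            }
            assert strict <= loose

    def test_hit_table_round_trip(self, small_sim, tmp_path):
        A, B, _ = small_sim
        hits = all_vs_all_proteins(A, B)
        write_hits_tsv(hits, tmp_path / "hits.tsv")
        back = read_hits_tsv(tmp_path / "hits.tsv")
        assert [
            (h.query_id, h.subject_id, h.score, h.q_start, h.q_end, h.positives)
            for h in back
        ] == [
            (h.query_id, h.subject_id, h.score, h.q_start, h.q_end, h.positives)
            for h in hits
        ]


class TestTranslatedGenomeCompare:
    def test_self_comparison_has_full_length_frame_hits(self, small_sim):
        A, _, _ = small_sim
        hits = translated_genome_compare(A, A, min_similarity=30, min_aln_len_bp=100)
        same_frame = [
            h
            for h in hits
            if h.frame_q == h.frame_s and h.pct_similarity == 100.0 and h.q_start == h.s_start
        ]
        frames_covered = {h.frame_q for h in same_frame}
        assert frames_covered == {1, 2, 3, -1, -2, -3}

    def test_hits_confined_to_planted_module(self):
        for seed in range(3):
            A, B, truth = simulate_module_pair(
                SimConfig(seed=seed, n_background_a=6, n_background_b=6)
            )
            hits = translated_genome_compare(
                A, B, min_similarity=30, min_aln_len_bp=100, min_score=60
            )
            assert hits, "expected module-region hits"
            sa, sb = truth.module_span_a, truth.module_span_b
            for h in hits:
                assert h.q_start - 1 < sa[1] and h.q_end > sa[0]
                assert h.s_start - 1 < sb[1] and h.s_end > sb[0]

    def test_reverse_complement_maps_subject_coordinates(self, small_sim):
        A, B, _ = small_sim
        hits = translated_genome_compare(A, B, min_similarity=30, min_aln_len_bp=100,
                                         min_score=60)
        B_rc = GenomeRecord(id=B.id, sequence=reverse_complement(B.sequence))
        hits_rc = translated_genome_compare(A, B_rc, min_similarity=30,
                                            min_aln_len_bp=100, min_score=60)
        L = B.length
        fwd = {(h.q_start, h.q_end, h.s_start, h.s_end, h.frame_s) for h in hits}
        rc = {
            (h.q_start, h.q_end, L - h.s_end + 1, L - h.s_start + 1, -h.frame_s)
            for h in hits_rc
        }
        assert fwd == rc
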