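"""Genome I/O: GenBank/FASTA-pair parsing, coordinates, translation, GC."""

import numpy as np
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from synmod import (
    GeneFeature,
    GenomeRecord,
    gc_content,
    read_fasta_pair,
    read_genbank,
    six_frame_translate,
    write_fasta_pair,
)
from synmod.genome_io import (
    genbank_to_internal,
    internal_to_genbank,
    reverse_complement,
    translate_cds,
)

from conftest import random_peptide


def _write_genbank(path, sequence, cds_specs):
    """cds_specs: list of (start0, end0, strand, qualifiers)."""
    rec = SeqRecord(
        Seq(sequence),
        id="TESTREC",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for start, end, strand, quals in cds_specs:
        rec.features.append(
            SeqFeature(
                SimpleLocation(start, end, strand=strand), type="CDS", qualifiers=quals
            )
        )
    with open(path, "w") as fh:
        SeqIO.write(rec, fh, "genbank")
    return path


class TestReadGenbank:
    def test_coordinate_convention_and_translation(self, tmp_path):
        # GenBank 1..9 (+) encoding MA* -> internal [0, 9), protein "MA"
        path = _write_genbank(
            tmp_path / "a.gb", "ATGGCATAACCCC", [(0, 9, 1, {"locus_tag": ["gpA"]})]
        )
        rec = read_genbank(path)
        f = rec.features[0]
        assert (f.start, f.end, f.strand, f.protein) == (0, 9, "+", "MA")

    def test_minus_strand_translation_matches_hand_derivation(self, tmp_path):
        # complement of [3, 12) of this sequence is TTATGCCAT -> L C H
        seq = "CCCATGGCATAAGG"
        path = _write_genbank(tmp_path / "b.gb", seq, [(3, 12, -1, {})])
        rec = read_genbank(path)
        assert rec.features[0].protein == translate_cds(reverse_complement(seq[3:12]))
        assert rec.features[0].protein == "LCH"

    def test_translation_qualifier_used_verbatim(self, tmp_path):
        path = _write_genbank(
            tmp_path / "c.gb",
            "ATGGCATAACCCC",
            [(0, 9, 1, {"translation": ["MXQQQ"], "locus_tag": ["gpA"]})],
        )
        rec = read_genbank(path)
        assert rec.features[0].protein == "MXQQQ"

    def test_zero_cds_error_names_file(self, tmp_path):
        path = _write_genbank(tmp_path / "empty.gb", "ATGGCATAA", [])
        with pytest.raises(ValueError, match="no genes.*empty.gb"):
            read_genbank(path)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_genbank(tmp_path / "nope.gb")

    def test_compound_location_rejected(self, tmp_path):
        rec = SeqRecord(
            Seq("ATGGCATAACCATGGCATAA"),
            id="J",
            annotations={"molecule_type": "DNA"},
        )
        loc = SimpleLocation(0, 6, strand=1) + SimpleLocation(11, 20, strand=1)
        rec.features.append(SeqFeature(loc, type="CDS"))
        path = tmp_path / "join.gb"
        with open(path, "w") as fh:
            SeqIO.write(rec, fh, "genbank")
        with pytest.raises(ValueError, match="join"):
            read_genbank(path)


class TestFastaPair:
    def test_single_feature(self, tmp_path):
        (tmp_path / "g.fna").write_text(">g\n" + "ATGGCA" * 5 + "\n")
        (tmp_path / "g.faa").write_text(">gpA|0|30|+\nMAMAMAMAM\n")
        rec = read_fasta_pair(tmp_path / "g.fna", tmp_path / "g.faa")
        assert rec.n_genes == 1
        assert rec.features[0].locus_id == "gpA"

    def test_unparseable_header_names_header(self, tmp_path):
        (tmp_path / "g.fna").write_text(">g\nATGGCA\n")
        (tmp_path / "g.faa").write_text(">gpA_0_30\nMA\n")
        with pytest.raises(ValueError, match="gpA_0_30"):
            read_fasta_pair(tmp_path / "g.fna", tmp_path / "g.faa")

    def test_out_of_range_coordinates_rejected(self, tmp_path):
        (tmp_path / "g.fna").write_text(">g\nATGGCA\n")
        (tmp_path / "g.faa").write_text(">gpA|0|30|+\nMA\n")
        with pytest.raises(ValueError, match="outside"):
            read_fasta_pair(tmp_path / "g.fna", tmp_path / "g.faa")

    def test_round_trip_identity_on_random_records(self, tmp_path):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n_genes = int(rng.integers(1, 6))
            genes = []
            pos = int(rng.integers(0, 10))
            for g in range(n_genes):
                plen = int(rng.integers(3, 40))
                genes.append(
                    GeneFeature(
                        rank=g,
                        locus_id=f"g{g}",
                        start=pos,
                        end=pos + 3 * (plen + 1),
                        strand="+" if rng.integers(2) else "-",
                        product_label="hypothetical protein",
                        protein=random_peptide(rng, plen),
                    )
                )
                pos += 3 * (plen + 1) + int(rng.integers(0, 20))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=pos + 5))
            rec = GenomeRecord(id=f"r{trial}", sequence=seq, features=genes)
            write_fasta_pair(rec, tmp_path / "t.fna", tmp_path / "t.faa")
            back = read_fasta_pair(tmp_path / "t.fna", tmp_path / "t.faa")
            assert back.id == rec.id
            assert back.sequence == rec.sequence
            assert [
                (f.rank, f.locus_id, f.start, f.end, f.strand, f.protein, f.product_label)
                for f in back.features
            ] == [
                (f.rank, f.locus_id, f.start, f.end, f.strand, f.protein, f.product_label)
                for f in rec.features
            ]


class TestCoordinates:
    def test_genbank_round_trip_is_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = int(rng.integers(1, 10_000))
            e = s + int(rng.integers(1, 5_000))
            assert internal_to_genbank(*genbank_to_internal(s, e)) == (s, e)

    def test_feature_invariants_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            GeneFeature(rank=0, locus_id="x", start=10, end=5, strand="+")
        with pytest.raises(ValueError, match="span"):
            GenomeRecord(
                id="g",
                sequence="ATG",
                features=[GeneFeature(0, "x", 0, 9, "+")],
            )


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 100.0), ("ATAT", 0.0)])
    def test_pure_sequences(self, seq, expected):
        assert gc_content(seq) == expected

    def test_ambiguous_bases_count_only_in_denominator(self):
        assert gc_content("GCNN") == pytest.approx(50.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    def test_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 300))))
            assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


class TestSixFrameTranslate:
    def test_known_frames(self):
        frames = six_frame_translate("ATGGCA")
        assert frames[0] == "MA"  # +1
        assert frames[3] == "CH"  # -1: translation of TGCCAT

    def test_partial_codon_rule_length_seven(self):
        frames = six_frame_translate("ATGGCAT")
        assert len(frames[1]) == 2 and len(frames[4]) == 2  # +2 / -2
        assert len(frames[2]) == 1 and len(frames[5]) == 1  # +3 / -3

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")

    def test_reverse_complement_permutes_frames(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(3, 200))))
            fwd = six_frame_translate(seq)
            rev = six_frame_translate(reverse_complement(seq))
            assert rev[:3] == fwd[3:]  # rc's +k is the original's -k
            assert rev[3:] == fwd[:3]
            assert sorted(fwd) == sorted(rev)
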