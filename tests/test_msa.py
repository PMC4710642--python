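"""Alignment construction, codon back-translation, consensus, intron
overlay, trimming and concatenation."""

import pytest
from Bio import Align as BioAlign
from Bio.Align import substitution_matrices

from odb.msa import (
    Alignment,
    AlignmentError,
    backtranslate_to_codon,
    concatenate_alignments,
    consensus,
    overlay_intron_phases,
    progressive_align,
    read_fasta,
    render,
    trim_low_conservation,
    write_fasta,
)
from odb.seqdb import Database, GeneModel, SeqType
from odb.simsearch import protein_scheme


def _records(seqs, seq_type=SeqType.PROTEIN):
    db = Database()
    return [
        db.add_record(f"s{i}", "spA", seq_type, s) for i, s in enumerate(seqs)
    ]


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        recs = _records(["MKVLAT"] * 3)
        aln = progressive_align(recs, "protein")
        assert aln.column_count == 6
        assert all("-" not in s for _, s in aln.rows)

    def test_single_sequence_rejected(self):
        recs = _records(["MKVLAT"])
        with pytest.raises(AlignmentError):
            progressive_align(recs, "protein")

    def test_columns_at_least_longest_input(self):
        recs = _records(["MKVLATQQW", "MKVAT", "MKWLATQQ"])
        aln = progressive_align(recs, "protein")
        assert aln.column_count >= 9
        for rec in recs:
            assert aln.degapped(rec.internal_id) == rec.sequence

    def test_two_sequences_match_pairwise_global_optimum(self):
        """Profile-profile DP on two single sequences must equal the NW
        optimum computed by an independent aligner."""
        scheme = protein_scheme()
        aligner = BioAlign.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        import random

        rng = random.Random(11)
        for _ in range(20):
            s1 = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(8, 20)))
            s2 = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(8, 20)))
            recs = _records([s1, s2])
            aln = progressive_align(recs, "protein")
            idx = {c: i for i, c in enumerate(scheme.alphabet)}
            score, in_gap1, in_gap2 = 0.0, False, False
            for x, y in zip(aln.rows[0][1], aln.rows[1][1]):
                if x == "-":
                    score -= scheme.gap_extend + (0 if in_gap1 else scheme.gap_open)
                    in_gap1, in_gap2 = True, False
                elif y == "-":
                    score -= scheme.gap_extend + (0 if in_gap2 else scheme.gap_open)
                    in_gap1, in_gap2 = False, True
                else:
                    score += scheme.matrix[idx[x], idx[y]]
                    in_gap1 = in_gap2 = False
            assert score == pytest.approx(aligner.score(s1, s2))


class TestBacktranslate:
    def test_gap_becomes_triple_gap(self):
        aln = Alignment(rows=[("r1", "M-A"), ("r2", "MQA")], kind="protein")
        codon = backtranslate_to_codon(
            aln, {"r1": "ATGGCT", "r2": "ATGCAAGCC"}
        )
        assert codon.row("r1") == "ATG---GCT"
        assert codon.row("r2") == "ATGCAAGCC"

    def test_trailing_stop_stripped(self):
        aln = Alignment(rows=[("r1", "MA"), ("r2", "MA")], kind="protein")
        codon = backtranslate_to_codon(
            aln, {"r1": "ATGGCTTAA", "r2": "ATGGCC"}
        )
        assert codon.row("r1") == "ATGGCT"

    def test_mismatch_names_row_and_column(self):
        aln = Alignment(rows=[("r1", "MV"), ("r2", "MV")], kind="protein")
        with pytest.raises(AlignmentError, match="r1.*column 1"):
            backtranslate_to_codon(aln, {"r1": "ATGGCT", "r2": "ATGGTT"})

    def test_round_trip_on_simulated_family(
        self, family_protein_alignment, family_cds_by_internal_id
    ):
        codon = backtranslate_to_codon(
            family_protein_alignment, family_cds_by_internal_id
        )
        for rid, _ in codon.rows:
            assert codon.degapped(rid) == family_cds_by_internal_id[rid]


class TestConsensus:
    @pytest.mark.parametrize(
        "rows,mode,expected",
        [
            (["AAA", "AAA", "AAA"], "strict", "AAA"),
            (["AGT", "GGT"], "strict", "NGT"),
            (["AGT", "GGT"], "iupac", "RGT"),
            (["AG-", "AGT", "AGT"], "strict", "AGN"),
            (["A--", "A--"], "strict", "A--"),
            (["AAG", "AAT", "ACT"], "majority", "AAT"),
            (["AG", "AA"], "majority", "AR"),
        ],
    )
    def test_modes(self, rows, mode, expected):
        aln = Alignment(
            rows=[(f"r{i}", s) for i, s in enumerate(rows)], kind="nucleotide"
        )
        assert consensus(aln, mode) == expected

    def test_protein_unsupported(self):
        aln = Alignment(rows=[("a", "MA"), ("b", "MA")], kind="protein")
        with pytest.raises(AlignmentError):
            consensus(aln)


class TestIntronOverlay:
    def test_protein_marks(self):
        model = GeneModel(cds_id="g", exon_lengths=(100, 20))
        row = "M" * 40
        aln = Alignment(rows=[("g", row)], kind="protein")
        out = overlay_intron_phases(aln, {"g": model})
        # offset 100 -> residue 33 (0-based), phase 1
        assert out.intron_marks["g"] == [(33, 1)]

    def test_phase0_attaches_to_following_residue(self):
        model = GeneModel(cds_id="g", exon_lengths=(99, 21))
        aln = Alignment(rows=[("g", "M" * 40)], kind="protein")
        out = overlay_intron_phases(aln, {"g": model})
        assert out.intron_marks["g"] == [(33, 0)]

    def test_leading_gaps_shift_protein_column(self):
        model = GeneModel(cds_id="g", exon_lengths=(100, 20))
        aln = Alignment(
            rows=[("g", "-" * 10 + "M" * 40), ("o", "M" * 50)], kind="protein"
        )
        out = overlay_intron_phases(aln, {"g": model})
        assert out.intron_marks["g"] == [(43, 1)]

    def test_nucleotide_marks_ungapped_position(self):
        model = GeneModel(cds_id="g", exon_lengths=(6, 6))
        aln = Alignment(
            rows=[("g", "ATG---ATTGCAGCA"), ("o", "ATGCCCATTGCAGCA")],
            kind="nucleotide",
        )
        out = overlay_intron_phases(aln, {"g": model})
        # ungapped position 6 sits at alignment column 9
        assert out.intron_marks["g"] == [(9, 0)]

    def test_offset_beyond_cds_is_error(self):
        model = GeneModel(cds_id="g", exon_lengths=(100, 20))
        aln = Alignment(rows=[("g", "M" * 10)], kind="protein")
        with pytest.raises(AlignmentError):
            overlay_intron_phases(aln, {"g": model})

    def test_marks_match_offset_mod_three_on_family(
        self, family, family_protein_alignment
    ):
        models = {
            rid: family.gene_model for rid, _ in family_protein_alignment.rows
        }
        out = overlay_intron_phases(family_protein_alignment, models)
        expected_phases = [i.phase for i in family.gene_model.introns]
        for rid, marks in out.intron_marks.items():
            assert [p for _, p in marks] == expected_phases
            assert all(
                p == o % 3
                for (_, p), o in zip(
                    marks, (i.coding_offset for i in family.gene_model.introns)
                )
            )


class TestTrim:
    def test_gappy_column_removed(self):
        aln = Alignment(
            rows=[("a", "A-G"), ("b", "A-G"), ("c", "A-G"), ("d", "AAG")],
            kind="nucleotide",
        )
        trimmed, removed = trim_low_conservation(aln, max_gap_fraction=0.2)
        assert removed == [1]
        assert trimmed.row("a") == "AG"

    def test_fully_conserved_untouched(self):
        aln = Alignment(rows=[("a", "ACGT"), ("b", "ACGT")], kind="nucleotide")
        trimmed, removed = trim_low_conservation(aln)
        assert removed == []
        assert trimmed.rows == aln.rows

    def test_codon_triple_removed_together(self):
        aln = Alignment(
            rows=[("a", "ATGAAA"), ("b", "ATGAAA"), ("c", "ATGCAA"), ("d", "ATGGAA")],
            kind="codon",
        )
        trimmed, removed = trim_low_conservation(aln, min_conservation=0.9)
        assert removed == [3, 4, 5]
        assert trimmed.column_count == 3

    def test_manual_columns(self):
        aln = Alignment(rows=[("a", "ACGT"), ("b", "ACGT")], kind="nucleotide")
        trimmed, removed = trim_low_conservation(aln, columns=[0, 3])
        assert trimmed.row("a") == "CG"

    def test_all_columns_removed_is_error(self):
        aln = Alignment(rows=[("a", "AC"), ("b", "GT")], kind="nucleotide")
        with pytest.raises(AlignmentError):
            trim_low_conservation(aln, columns=[0, 1])

    def test_idempotent(self, family_nt_alignment):
        once, removed1 = trim_low_conservation(family_nt_alignment)
        twice, removed2 = trim_low_conservation(once)
        assert removed2 == []
        assert twice.rows == once.rows


class TestConcatenate:
    def test_lengths_add(self):
        a = Alignment(rows=[("x", "ACGACGACG"), ("y", "ACGACGACG")], kind="nucleotide")
        b = Alignment(rows=[("y", "TTTTTTTTTTTT"), ("x", "GGGGGGGGGGGG")], kind="nucleotide")
        out = concatenate_alignments([a, b])
        assert out.column_count == 21
        assert out.row_ids == ["x", "y"]
        assert out.row("x") == "ACGACGACG" + "GGGGGGGGGGGG"

    def test_single_input_identity(self):
        a = Alignment(rows=[("x", "ACG")], kind="nucleotide")
        assert concatenate_alignments([a]).rows == a.rows

    def test_mismatched_ids_error_lists_difference(self):
        a = Alignment(rows=[("x", "ACG")], kind="nucleotide")
        b = Alignment(rows=[("z", "ACG")], kind="nucleotide")
        with pytest.raises(AlignmentError, match="x.*z|z.*x"):
            concatenate_alignments([a, b])


class TestIO:
    def test_fasta_round_trip(self, tmp_path, family_protein_alignment):
        path = tmp_path / "aln.fa"
        write_fasta(family_protein_alignment, path)
        back = read_fasta(path, "protein")
        assert back.rows == family_protein_alignment.rows

    def test_render_shows_consensus_and_marks(self):
        model = GeneModel(cds_id="g", exon_lengths=(6, 6))
        aln = Alignment(
            rows=[("g", "ATGCCCATTGCA"), ("o", "ATGCCCATTGCA")], kind="nucleotide"
        )
        out = overlay_intron_phases(aln, {"g": model})
        text = render(out)
        assert "consensus" in text
        assert "^" in text
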