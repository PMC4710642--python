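"""Database loading, searching, single-copy filtering and persistence."""

import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odb.seqdb import (
    Database,
    DuplicateIdError,
    GeneModel,
    InvalidAlphabetError,
    NotFoundError,
    ParseError,
    SeqType,
    ValidationError,
    translate_cds,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


@pytest.fixture
def db(tmp_path):
    db = Database()
    fasta = _write(
        tmp_path,
        "a.cds.fa",
        """\
        >g1 some description
        ATGGCTTGA
        >g2
        ATGAAATAA
        """,
    )
    db.load_sequences(fasta, "spA", SeqType.CDS)
    return db


class TestLoadSequences:
    def test_counts_and_ids(self, db):
        assert len(db.records) == 2
        rec = db.find_by_original_id("g1")[0]
        assert rec.species == "spA"
        assert rec.sequence == "ATGGCTTGA"

    def test_duplicate_header_rejected(self, db, tmp_path):
        dup = _write(tmp_path, "dup.fa", ">g1\nATG\n")
        with pytest.raises(DuplicateIdError):
            db.load_sequences(dup, "spA", SeqType.CDS)

    def test_same_id_other_species_ok(self, db, tmp_path):
        other = _write(tmp_path, "b.fa", ">g1\nATGTAA\n")
        assert db.load_sequences(other, "spB", SeqType.CDS) == 1

    def test_invalid_protein_alphabet_names_record(self, tmp_path):
        bad = _write(tmp_path, "bad.faa", ">p1\nMJQ\n")
        with pytest.raises(InvalidAlphabetError, match="p1"):
            Database().load_sequences(bad, "spA", SeqType.PROTEIN)

    def test_not_fasta_reports_line(self, tmp_path):
        bad = _write(tmp_path, "bad.fa", "ATG\n>g1\nATG\n")
        with pytest.raises(ParseError, match="line 1"):
            Database().load_sequences(bad, "spA", SeqType.CDS)

    def test_empty_file_is_error(self, tmp_path):
        empty = _write(tmp_path, "empty.fa", "")
        with pytest.raises(ParseError):
            Database().load_sequences(empty, "spA", SeqType.CDS)


class TestGeneModels:
    def test_intron_offsets_and_phases(self):
        model = GeneModel(cds_id="x", exon_lengths=(100, 50))
        assert [(i.coding_offset, i.phase) for i in model.introns] == [(100, 1)]
        model = GeneModel(cds_id="x", exon_lengths=(99, 60, 30))
        assert [(i.coding_offset, i.phase) for i in model.introns] == [
            (99, 0),
            (159, 0),
        ]

    def test_single_exon_has_no_introns(self):
        assert GeneModel(cds_id="x", exon_lengths=(300,)).introns == ()

    def _gff(self, tmp_path, body):
        return _write(tmp_path, "g.gff3", "##gff-version 3\n" + body)

    def test_gff_load_plus_and_minus(self, tmp_path):
        db = Database()
        cds = _write(tmp_path, "c.fa", ">g1\n" + "A" * 9 + "\n>g2\n" + "C" * 9 + "\n")
        db.load_sequences(cds, "spA", SeqType.CDS)
        gff = self._gff(
            tmp_path,
            "s1\t.\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=g1\n"
            "s1\t.\tCDS\t100\t102\t.\t+\t0\tID=c2;Parent=g1\n"
            "s2\t.\tCDS\t1\t3\t.\t-\t0\tID=c3;Parent=g2\n"
            "s2\t.\tCDS\t100\t105\t.\t-\t0\tID=c4;Parent=g2\n",
        )
        assert db.load_gene_structures(gff) == 2
        plus = db.gene_models["spA|CDS|g1"]
        assert plus.exon_lengths == (6, 3)
        # minus strand: transcription runs right-to-left in genome coordinates
        minus = db.gene_models["spA|CDS|g2"]
        assert minus.exon_lengths == (6, 3)

    def test_unknown_parent_is_error(self, tmp_path):
        gff = self._gff(tmp_path, "s1\t.\tCDS\t1\t6\t.\t+\t0\tID=c;Parent=nope\n")
        with pytest.raises(NotFoundError):
            Database().load_gene_structures(gff)

    def test_overlapping_segments_are_error(self, tmp_path, db):
        gff = self._gff(
            tmp_path,
            "s1\t.\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=g1\n"
            "s1\t.\tCDS\t4\t6\t.\t+\t0\tID=c2;Parent=g1\n",
        )
        with pytest.raises(ValidationError, match="overlap"):
            db.load_gene_structures(gff)


class TestAnnotations:
    HEADER = "seq_id\tdescription\tgo\tpfam\n"

    def test_attach_and_search(self, db, tmp_path):
        tsv = _write(
            tmp_path,
            "a.tsv",
            self.HEADER + "g1\tlaccase\tGO:0046274\tPF02797:PKS\n",
        )
        assert db.load_annotations(tsv) == (1, 0)
        hits = db.text_search("laccase", fields={"description"})
        assert [h.original_id for h in hits] == ["g1"]
        assert [h.original_id for h in db.text_search("GO:0046274", fields={"go"})] == ["g1"]
        assert [h.original_id for h in db.text_search("PF02797", fields={"pfam"})] == ["g1"]

    def test_unknown_id_skipped_with_warning_count(self, db, tmp_path):
        tsv = _write(tmp_path, "a.tsv", self.HEADER + "nope\tx\t\t\n")
        assert db.load_annotations(tsv) == (0, 1)

    def test_malformed_go_rejected(self, db, tmp_path):
        tsv = _write(tmp_path, "a.tsv", self.HEADER + "g1\tx\t0046274\t\n")
        with pytest.raises(ValidationError):
            db.load_annotations(tsv)

    def test_missing_column_is_error(self, db, tmp_path):
        tsv = _write(tmp_path, "a.tsv", "seq_id\tdescription\n" + "g1\tx\n")
        with pytest.raises(ParseError, match="go"):
            db.load_annotations(tsv)


class TestClusters:
    def test_load_and_lookup(self, db, tmp_path):
        groups = _write(tmp_path, "g.txt", "CL1: spA|g1 spA|g2\n")
        assert db.load_clusters(groups) == 1
        assert len(db.get_cluster("CL1").members) == 2
        assert db.clusters_of("spA", "g1") == ["CL1"]

    def test_unknown_cluster_raises(self, db):
        with pytest.raises(NotFoundError):
            db.get_cluster("CLX")

    def test_missing_colon_reports_line(self, db, tmp_path):
        groups = _write(tmp_path, "g.txt", "CL1 spA|g1\n")
        with pytest.raises(ParseError, match="line 1"):
            db.load_clusters(groups)

    def test_unknown_member_warn_skip_vs_strict(self, db, tmp_path):
        groups = _write(tmp_path, "g.txt", "CL1: spA|g1 spZ|nope\n")
        db.load_clusters(groups)
        assert len(db.get_cluster("CL1").members) == 1
        with pytest.raises(NotFoundError):
            db.load_clusters(groups, strict=True)

    def test_member_in_two_clusters(self, db, tmp_path):
        groups = _write(tmp_path, "g.txt", "CL1: spA|g1\nCL2: spA|g1 spA|g2\n")
        db.load_clusters(groups)
        assert db.clusters_of("spA", "g1") == ["CL1", "CL2"]


class TestTextSearch:
    def test_empty_result_allowed(self, db):
        assert db.text_search("zzz") == []

    def test_empty_query_rejected(self, db):
        with pytest.raises(ValueError):
            db.text_search("")

    @settings(derandomize=True, max_examples=25)
    @given(st.text(alphabet="g1laccase", min_size=2, max_size=6))
    def test_longer_query_never_finds_more(self, query):
        db = Database()
        db.add_record("g1laccase", "spA", SeqType.CDS, "ATG")
        db.add_record("g2", "spA", SeqType.CDS, "ATG")
        full = {r.internal_id for r in db.text_search(query, fields={"id"})}
        prefix = {r.internal_id for r in db.text_search(query[:1], fields={"id"})}
        assert full <= prefix


class TestSingleCopyFilter:
    def _db_with_clusters(self, spec):
        """spec: {cluster_id: {species: n_members}}"""
        db = Database()
        lines = []
        for cid, counts in spec.items():
            members = []
            for sp, n in counts.items():
                for k in range(n):
                    oid = f"{cid}_{sp}_{k}"
                    db.add_record(oid, sp, SeqType.PROTEIN, "MA")
                    members.append(f"{sp}|{oid}")
            lines.append(f"{cid}: {' '.join(members)}")
        import tempfile

        tmp = tempfile.NamedTemporaryFile("w", suffix=".txt", delete=False)
        tmp.write("\n".join(lines) + "\n")
        tmp.close()
        db.load_clusters(tmp.name)
        return db

    def test_exactly_one_per_required_species(self):
        db = self._db_with_clusters(
            {
                "CL1": {"A": 1, "B": 1},
                "CL2": {"A": 2, "B": 1},
                "CL3": {"A": 1},
            }
        )
        assert db.filter_single_copy_clusters({"A", "B"}) == ["CL1"]

    def test_extra_species_flag(self):
        db = self._db_with_clusters({"CL1": {"A": 1, "B": 1, "C": 1}})
        assert db.filter_single_copy_clusters({"A", "B"}) == []
        assert db.filter_single_copy_clusters({"A", "B"}, allow_extra_species=True) == [
            "CL1"
        ]

    def test_empty_species_set_is_error(self):
        db = self._db_with_clusters({"CL1": {"A": 1}})
        with pytest.raises(ValueError):
            db.filter_single_copy_clusters(set())


class TestTranslationAndRoundTrip:
    def test_translate_ambiguous_codon_to_x(self):
        assert translate_cds("ATGNNNTAA") == "MX"

    def test_translation_consistency_flags_exact_mismatches(self):
        db = Database()
        db.add_record("ok", "spA", SeqType.CDS, "ATGGCT")
        db.add_record("ok", "spA", SeqType.PROTEIN, "MA")
        db.add_record("bad", "spA", SeqType.CDS, "ATGGCT")
        db.add_record("bad", "spA", SeqType.PROTEIN, "MV")
        assert db.check_translations() == [("spA|CDS|bad", "spA|protein|bad")]

    def test_save_load_round_trip(self, family, tmp_path):
        from odb.seqdb import AnnotationSet

        db = family.as_database()
        db.annotations["sp1_g1"] = AnnotationSet(
            seq_id="sp1_g1",
            description="laccase-like",
            go_terms={"GO:0046274"},
            pfam_domains={("PF02797", "PKS")},
        )
        groups = tmp_path / "groups.txt"
        groups.write_text(
            "FAM1: " + " ".join(f"{db.records[k].species}|{db.records[k].original_id}"
                                 for k in sorted(db.records) if "CDS" in k) + "\n"
        )
        db.load_clusters(groups)
        out = tmp_path / "db"
        db.save(out)
        loaded = Database.load(out)
        assert set(loaded.records) == set(db.records)
        for k, rec in db.records.items():
            assert loaded.records[k] == rec
        assert {k: m.exon_lengths for k, m in loaded.gene_models.items()} == {
            k: m.exon_lengths for k, m in db.gene_models.items()
        }
        assert loaded.annotations.keys() == db.annotations.keys()
        a, b = loaded.annotations["sp1_g1"], db.annotations["sp1_g1"]
        assert (a.description, a.go_terms, a.pfam_domains) == (
            b.description,
            b.go_terms,
            b.pfam_domains,
        )
        assert {c: loaded.clusters[c].members for c in loaded.clusters} == {
            c: db.clusters[c].members for c in db.clusters
        }
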