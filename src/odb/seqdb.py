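"""Flat-file multi-species sequence database.

Holds mRNA/CDS/protein records for any number of species together with
gene structures (exon/intron layout of each CDS), free-text + GO/PFAM
annotations and precomputed homolog clusters (OrthoMCL-style groups).
Everything lives in plain text files (FASTA, GFF3, TSV, groups) so a
database can be built, saved and reloaded without any server.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted on load and on write.  Minus-strand gene structures are
flipped into transcript orientation on load, so all downstream code is
strand-free.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gffutils
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

GO_PATTERN = re.compile(r"^GO:\d{7}$")
PFAM_PATTERN = re.compile(r"^PF\d{5}$")


class SeqType(str, Enum):
    MRNA = "mRNA"
    CDS = "CDS"
    PROTEIN = "protein"


class DatabaseError(Exception):
    """Base class for database loading/lookup problems."""


class ParseError(DatabaseError):
    """Malformed input file; message carries the offending line number."""


class DuplicateIdError(DatabaseError):
    pass


class InvalidAlphabetError(DatabaseError):
    pass


class NotFoundError(DatabaseError):
    pass


class ValidationError(DatabaseError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its species of origin and original identifier."""

    internal_id: str
    original_id: str
    species: str
    seq_type: SeqType
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Intron:
    """An intron position inside a CDS.

    ``coding_offset`` is the number of coding nucleotides upstream of the
    intron (0-based); ``phase`` is ``coding_offset mod 3``: 0 = between
    codons, 1 = after the first, 2 = after the second nucleotide of a codon.
    """

    coding_offset: int
    phase: int


@dataclass(frozen=True)
class GeneModel:
    """Exon/intron layout of a CDS, in transcription order."""

    cds_id: str
    exon_lengths: tuple[int, ...]

    def __post_init__(self):
        if not self.exon_lengths or any(x <= 0 for x in self.exon_lengths):
            raise ValidationError(
                f"gene model {self.cds_id}: exon lengths must be positive"
            )

    @property
    def coding_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def introns(self) -> tuple[Intron, ...]:
        offsets, acc = [], 0
        for length in self.exon_lengths[:-1]:
            acc += length
            offsets.append(Intron(coding_offset=acc, phase=acc % 3))
        return tuple(offsets)


@dataclass
class AnnotationSet:
    seq_id: str
    description: str = ""
    go_terms: set[str] = field(default_factory=set)
    pfam_domains: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        for go in self.go_terms:
            if not GO_PATTERN.match(go):
                raise ValidationError(f"{self.seq_id}: malformed GO term {go!r}")
        for pf, _desc in self.pfam_domains:
            if not PFAM_PATTERN.match(pf):
                raise ValidationError(f"{self.seq_id}: malformed PFAM id {pf!r}")


@dataclass(frozen=True)
class HomologCluster:
    cluster_id: str
    members: tuple[tuple[str, str], ...]  # (species, original seq id)

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sp, _ in self.members:
            counts[sp] = counts.get(sp, 0) + 1
        return counts


def _validate_alphabet(seq: str, seq_type: SeqType, rec_id: str) -> str:
    seq = seq.upper()
    if seq_type is SeqType.PROTEIN:
        seq = seq.rstrip("*")  # trailing stop symbol tolerated, not stored
        bad = set(seq) - PROTEIN_ALPHABET
    else:
        bad = set(seq) - DNA_ALPHABET
    if not seq:
        raise InvalidAlphabetError(f"record {rec_id}: empty sequence")
    if bad:
        raise InvalidAlphabetError(
            f"record {rec_id}: invalid {seq_type.value} characters "
            f"{''.join(sorted(bad))!r}"
        )
    return seq


def translate_cds(cds: str) -> str:
    """Standard-code translation; ambiguous codons become X, trailing stop dropped."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(trimmed).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


class Database:
    """In-memory multi-species sequence database with flat-file persistence."""

    def __init__(self) -> None:
        self.records: dict[str, SequenceRecord] = {}
        self.gene_models: dict[str, GeneModel] = {}  # keyed by CDS internal_id
        self.annotations: dict[str, AnnotationSet] = {}  # keyed by original_id
        self.clusters: dict[str, HomologCluster] = {}
        self._by_original: dict[tuple[str, SeqType, str], str] = {}
        self._cluster_membership: dict[tuple[str, str], list[str]] = {}

    # ------------------------------------------------------------------ #
    # loading                                                            #
    # ------------------------------------------------------------------ #

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records.values()})

    @staticmethod
    def _internal_id(species: str, seq_type: SeqType, original_id: str) -> str:
        return f"{species}|{seq_type.value}|{original_id}"

    def add_record(
        self, original_id: str, species: str, seq_type: SeqType, sequence: str
    ) -> SequenceRecord:
        key = (species, seq_type, original_id)
        if key in self._by_original:
            raise DuplicateIdError(
                f"duplicate id {original_id!r} for ({species}, {seq_type.value})"
            )
        seq = _validate_alphabet(sequence, seq_type, original_id)
        rec = SequenceRecord(
            internal_id=self._internal_id(species, seq_type, original_id),
            original_id=original_id,
            species=species,
            seq_type=seq_type,
            sequence=seq,
        )
        self.records[rec.internal_id] = rec
        self._by_original[key] = rec.internal_id
        return rec

    def load_sequences(self, path: str | Path, species: str, seq_type: SeqType | str) -> int:
        """Load a FASTA file of one sequence type for one species.

        The first whitespace-delimited header token becomes ``original_id``.
        """
        seq_type = SeqType(seq_type)
        path = Path(path)
        if not path.exists():
            raise DatabaseError(f"no such file: {path}")
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    if not line.startswith(">"):
                        raise ParseError(
                            f"{path}: line {lineno}: expected FASTA header '>'"
                        )
                    break
            else:
                raise ParseError(f"{path}: empty FASTA file")
        n = 0
        for bio_rec in SeqIO.parse(str(path), "fasta"):
            if not str(bio_rec.seq):
                raise ParseError(f"{path}: record {bio_rec.id} has empty sequence")
            self.add_record(bio_rec.id, species, seq_type, str(bio_rec.seq))
            n += 1
        if n == 0:
            raise ParseError(f"{path}: empty FASTA file")
        logger.info("loaded %d %s records for %s from %s", n, seq_type.value, species, path)
        return n

    def find_by_original_id(
        self, original_id: str, seq_type: SeqType | None = None
    ) -> list[SequenceRecord]:
        out = [
            r
            for r in self.records.values()
            if r.original_id == original_id
            and (seq_type is None or r.seq_type == seq_type)
        ]
        return sorted(out, key=lambda r: r.internal_id)

    def get(self, internal_id: str) -> SequenceRecord:
        try:
            return self.records[internal_id]
        except KeyError:
            raise NotFoundError(f"no record with internal id {internal_id!r}") from None

    def load_gene_structures(self, path: str | Path) -> int:
        """Load CDS exon layouts from GFF3 (1-based inclusive coordinates).

        CDS features are grouped by their ``Parent`` attribute (falling back
        to ``ID``); minus-strand features are reversed into transcription
        order.  Intron offsets/phases are derived, not read from the file.
        """
        path = Path(path)
        if not path.exists():
            raise DatabaseError(f"no such file: {path}")
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        groups: dict[str, list] = {}
        for feat in db.features_of_type("CDS"):
            parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
            if not parents:
                raise ParseError(f"{path}: CDS feature without Parent/ID attribute")
            groups.setdefault(parents[0], []).append(feat)
        n = 0
        for parent, feats in groups.items():
            strand = feats[0].strand
            feats.sort(key=lambda f: f.start)
            for prev, cur in zip(feats, feats[1:]):
                if cur.start <= prev.end:
                    raise ValidationError(
                        f"{path}: overlapping CDS segments for {parent}"
                    )
            if strand == "-":
                feats = feats[::-1]  # transcription order
            exon_lengths = tuple(f.end - f.start + 1 for f in feats)
            cds_recs = self.find_by_original_id(parent, SeqType.CDS)
            if not cds_recs:
                raise NotFoundError(
                    f"{path}: CDS parent {parent!r} not found in database"
                )
            model = GeneModel(cds_id=parent, exon_lengths=exon_lengths)
            for rec in cds_recs:
                if model.coding_length != len(rec.sequence):
                    raise ValidationError(
                        f"{path}: exon lengths for {parent} sum to "
                        f"{model.coding_length}, CDS is {len(rec.sequence)} nt"
                    )
                self.gene_models[rec.internal_id] = model
            n += 1
        logger.info("loaded %d gene models from %s", n, path)
        return n

    def load_annotations(self, path: str | Path) -> tuple[int, int]:
        """Load a TSV of ``seq_id, description, go, pfam`` annotations.

        GO and PFAM columns are ';'-separated; a PFAM token may carry a
        description after ':'.  Returns (rows attached, rows skipped because
        the id is unknown).
        """
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"seq_id", "description", "go", "pfam"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(
                f"{path}: missing mandatory column(s) {sorted(missing)}"
            )
        attached = skipped = 0
        for _, row in df.iterrows():
            seq_id = row["seq_id"]
            if not self.find_by_original_id(seq_id):
                logger.warning("annotation for unknown id %r skipped", seq_id)
                skipped += 1
                continue
            go = {tok.strip() for tok in row["go"].split(";") if tok.strip()}
            pfam = set()
            for tok in row["pfam"].split(";"):
                tok = tok.strip()
                if not tok:
                    continue
                pf, _, desc = tok.partition(":")
                pfam.add((pf, desc))
            self.annotations[seq_id] = AnnotationSet(
                seq_id=seq_id,
                description=row["description"],
                go_terms=go,
                pfam_domains=pfam,
            )
            attached += 1
        logger.info("attached %d annotations (%d unknown ids skipped)", attached, skipped)
        return attached, skipped

    def load_clusters(self, path: str | Path, strict: bool = False) -> int:
        """Load an OrthoMCL-style groups file (``CL1: spA|g1 spB|g2 ...``).

        Members absent from the database are skipped with a warning by
        default; ``strict=True`` turns them into errors.
        """
        n = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if ":" not in line:
                    raise ParseError(f"{path}: line {lineno}: missing ':' separator")
                cluster_id, _, rest = line.partition(":")
                cluster_id = cluster_id.strip()
                members = []
                for tok in rest.split():
                    if "|" not in tok:
                        raise ParseError(
                            f"{path}: line {lineno}: member {tok!r} is not 'species|id'"
                        )
                    sp, _, sid = tok.partition("|")
                    known = any(
                        r.species == sp and r.original_id == sid
                        for r in self.records.values()
                    )
                    if not known:
                        if strict:
                            raise NotFoundError(
                                f"{path}: line {lineno}: member {tok!r} not in database"
                            )
                        logger.warning("cluster %s: unknown member %r skipped", cluster_id, tok)
                        continue
                    members.append((sp, sid))
                if not members:
                    logger.warning("cluster %s has no resolvable members; skipped", cluster_id)
                    continue
                cluster = HomologCluster(cluster_id=cluster_id, members=tuple(members))
                self.clusters[cluster_id] = cluster
                for member in members:
                    self._cluster_membership.setdefault(member, []).append(cluster_id)
                n += 1
        logger.info("loaded %d clusters from %s", n, path)
        return n

    # ------------------------------------------------------------------ #
    # queries                                                            #
    # ------------------------------------------------------------------ #

    def text_search(
        self,
        query: str,
        fields: set[str] | None = None,
        species_filter: set[str] | None = None,
    ) -> list[SequenceRecord]:
        """Case-insensitive search over ids/descriptions; exact GO/PFAM match.

        ``fields`` is a subset of {"id", "description", "go", "pfam"}
        (default: all).  Results are sorted by internal id.
        """
        if not query:
            raise ValueError("query must be non-empty")
        fields = fields or {"id", "description", "go", "pfam"}
        unknown = fields - {"id", "description", "go", "pfam"}
        if unknown:
            raise ValueError(f"unknown search fields {sorted(unknown)}")
        q = query.lower()
        hits = []
        for rec in self.records.values():
            if species_filter and rec.species not in species_filter:
                continue
            ann = self.annotations.get(rec.original_id)
            match = False
            if "id" in fields and (q in rec.original_id.lower() or q in rec.internal_id.lower()):
                match = True
            if not match and ann is not None:
                if "description" in fields and q in ann.description.lower():
                    match = True
                elif "go" in fields and query.upper() in ann.go_terms:
                    match = True
                elif "pfam" in fields and query.upper() in {pf for pf, _ in ann.pfam_domains}:
                    match = True
            if match:
                hits.append(rec)
        return sorted(hits, key=lambda r: r.internal_id)

    def get_cluster(self, cluster_id: str) -> HomologCluster:
        try:
            return self.clusters[cluster_id]
        except KeyError:
            raise NotFoundError(f"no cluster with id {cluster_id!r}") from None

    def clusters_of(self, species: str, original_id: str) -> list[str]:
        """Reverse lookup: cluster ids containing (species, original_id)."""
        return list(self._cluster_membership.get((species, original_id), []))

    def filter_single_copy_clusters(
        self, required_species: set[str], allow_extra_species: bool = False
    ) -> list[str]:
        """Cluster ids in which every required species occurs exactly once.

        By default clusters containing members of any other species are
        dropped too; ``allow_extra_species=True`` ignores extra species.
        """
        if not required_species:
            raise ValueError("required_species must be non-empty")
        unknown = set(required_species) - set(self.species)
        if unknown:
            raise ValueError(f"species not in database: {sorted(unknown)}")
        kept = []
        for cid in sorted(self.clusters):
            counts = self.clusters[cid].species_counts()
            if any(counts.get(sp, 0) != 1 for sp in required_species):
                continue
            if not allow_extra_species and set(counts) - set(required_species):
                continue
            kept.append(cid)
        return kept

    def check_translations(self) -> list[tuple[str, str]]:
        """Internal-id pairs (CDS, protein) whose translation disagrees.

        A CDS is linked to the protein with the same species and original id.
        Trailing stop codons are tolerated; ambiguous codons translate to X.
        """
        bad = []
        for rec in self.records.values():
            if rec.seq_type is not SeqType.CDS:
                continue
            prots = self.find_by_original_id(rec.original_id, SeqType.PROTEIN)
            prots = [p for p in prots if p.species == rec.species]
            for prot in prots:
                if translate_cds(rec.sequence) != prot.sequence:
                    bad.append((rec.internal_id, prot.internal_id))
        return sorted(bad)

    # ------------------------------------------------------------------ #
    # persistence                                                        #
    # ------------------------------------------------------------------ #

    def save(self, outdir: str | Path) -> None:
        """Write the database as FASTA/GFF3/TSV/groups files plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"sequences": []}
        by_file: dict[tuple[str, SeqType], list[SequenceRecord]] = {}
        for rec in sorted(self.records.values(), key=lambda r: r.internal_id):
            by_file.setdefault((rec.species, rec.seq_type), []).append(rec)
        for (species, seq_type), recs in sorted(by_file.items()):
            fname = f"{species}.{seq_type.value}.fasta"
            bio = [
                _BioSeqRecord(Seq(r.sequence), id=r.original_id, description="")
                for r in recs
            ]
            SeqIO.write(bio, str(outdir / fname), "fasta")  # wraps at 60 cols
            manifest["sequences"].append(
                {"file": fname, "species": species, "seq_type": seq_type.value}
            )
        if self.gene_models:
            self._write_gff3(outdir / "genes.gff3")
            manifest["gene_structures"] = "genes.gff3"
        if self.annotations:
            self._write_annotations(outdir / "annotations.tsv")
            manifest["annotations"] = "annotations.tsv"
        if self.clusters:
            with open(outdir / "clusters.txt", "w") as fh:
                for cid in sorted(self.clusters):
                    members = " ".join(
                        f"{sp}|{sid}" for sp, sid in self.clusters[cid].members
                    )
                    fh.write(f"{cid}: {members}\n")
            manifest["clusters"] = "clusters.txt"
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)

    def _write_gff3(self, path: Path) -> None:
        # Genomic coordinates are not stored, so each model is written on a
        # pseudo-scaffold with fixed 120-nt introns, plus strand.
        seen: dict[str, GeneModel] = {}
        for model in self.gene_models.values():
            seen[model.cds_id] = model
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for cds_id in sorted(seen):
                model = seen[cds_id]
                scaffold = f"{cds_id}_locus"
                total = model.coding_length + 120 * (len(model.exon_lengths) - 1)
                fh.write(
                    f"{scaffold}\todb\tmRNA\t1\t{total}\t.\t+\t.\tID={cds_id}.m\n"
                )
                pos = 1
                for i, length in enumerate(model.exon_lengths):
                    fh.write(
                        f"{scaffold}\todb\tCDS\t{pos}\t{pos + length - 1}\t.\t+\t"
                        f"{(3 - (sum(model.exon_lengths[:i]) % 3)) % 3}\t"
                        f"ID=cds_{cds_id}.{i};Parent={cds_id}\n"
                    )
                    pos += length + 120
        logger.info("wrote %d gene models to %s", len(seen), path)

    def _write_annotations(self, path: Path) -> None:
        rows = []
        for seq_id in sorted(self.annotations):
            ann = self.annotations[seq_id]
            rows.append(
                {
                    "seq_id": seq_id,
                    "description": ann.description,
                    "go": ";".join(sorted(ann.go_terms)),
                    "pfam": ";".join(
                        f"{pf}:{desc}" if desc else pf
                        for pf, desc in sorted(ann.pfam_domains)
                    ),
                }
            )
        pd.DataFrame(rows, columns=["seq_id", "description", "go", "pfam"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def load(cls, indir: str | Path) -> "Database":
        indir = Path(indir)
        with open(indir / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        db = cls()
        for entry in manifest["sequences"]:
            db.load_sequences(
                indir / entry["file"], entry["species"], SeqType(entry["seq_type"])
            )
        if manifest.get("gene_structures"):
            db.load_gene_structures(indir / manifest["gene_structures"])
        if manifest.get("annotations"):
            db.load_annotations(indir / manifest["annotations"])
        if manifest.get("clusters"):
            db.load_clusters(indir / manifest["clusters"])
        return db
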