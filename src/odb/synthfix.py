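"""Deterministic synthetic fixtures: simulated gene families with known
truth, and templates with planted primer sites.

The family simulator emulates a set of orthologous/paralogous coding
sequences across species: one ancestral CDS evolves along a recorded
random bifurcating tree under uniform (Jukes-Cantor style) nucleotide
substitution.  In-frame stop codons are rejected during mutation so
every CDS/protein pair satisfies the database translation invariant,
and designated "conserved windows" are held invariant across the whole
family, giving degenerate/consensus primer design something to find.
All members share one exon plan, so intron phases are conserved too.

Every output is reproducible byte-for-byte from the seed.  What the
simulator does NOT emulate: indels, codon-level selection, rate
heterogeneity, assembly artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .primerdesign import ThermoParams, dimer_score, gc_fraction, tm_melting
from .seqdb import Database, GeneModel, SeqType

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


class SynthError(Exception):
    pass


@dataclass(frozen=True)
class ConservedWindow:
    """A window held invariant family-wide; ``role`` marks whether a
    forward- or reverse-orientation primer must be designable inside it."""

    start: int
    length: int
    role: str | None = None  # "forward" | "reverse" | None


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for one simulated gene family."""

    n_species: int = 4
    n_paralogs: int = 2
    cds_length: int = 300                  # nt, multiple of 3
    exon_lengths: tuple[int, ...] = (97, 140, 63)
    substitution_rate: float = 0.02        # per site per branch
    conserved_windows: tuple[ConservedWindow, ...] = (
        ConservedWindow(21, 33, "forward"),
        ConservedWindow(234, 33, "reverse"),
    )
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.cds_length % 3:
            raise SynthError("cds_length must be a multiple of 3")
        if sum(self.exon_lengths) != self.cds_length:
            raise SynthError("exon lengths must sum to cds_length")
        if not 0 <= self.substitution_rate < 0.75:
            raise SynthError("substitution rate must lie in [0, 0.75)")
        for w in self.conserved_windows:
            if w.start + w.length > self.cds_length:
                raise SynthError("conserved window extends past the CDS")


@dataclass
class SimulatedFamily:
    spec: FamilySpec
    members: dict[str, str]              # member id -> CDS (no stop codon)
    species_of: dict[str, str]
    decoys: dict[str, str]
    tree_newick: str                     # recorded birth tree over members
    gene_model: GeneModel

    @property
    def proteins(self) -> dict[str, str]:
        return {mid: str(Seq(cds).translate(table=1)) for mid, cds in self.members.items()}

    def conserved_coords(self) -> list[tuple[int, int]]:
        return [(w.start, w.start + w.length) for w in self.spec.conserved_windows]

    # ------------------------------------------------------------------ #
    # file output                                                        #
    # ------------------------------------------------------------------ #

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write CDS/protein FASTA per species, GFF3, groups and truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        by_species: dict[str, list[str]] = {}
        for mid in sorted(self.members):
            by_species.setdefault(self.species_of[mid], []).append(mid)
        proteins = self.proteins
        for sp, mids in sorted(by_species.items()):
            cds_path = outdir / f"{sp}.cds.fasta"
            prot_path = outdir / f"{sp}.protein.fasta"
            with open(cds_path, "w") as cf, open(prot_path, "w") as pf:
                for mid in mids:
                    cf.write(_fasta(mid, self.members[mid]))
                    pf.write(_fasta(mid, proteins[mid]))
            paths[f"{sp}.cds"] = cds_path
            paths[f"{sp}.protein"] = prot_path
        if self.decoys:
            decoy_path = outdir / "decoy.cds.fasta"
            with open(decoy_path, "w") as fh:
                for did in sorted(self.decoys):
                    fh.write(_fasta(did, self.decoys[did]))
            paths["decoy.cds"] = decoy_path
        gff_path = outdir / "genes.gff3"
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, mid in enumerate(sorted(self.members)):
                strand = "+" if i % 2 == 0 else "-"
                fh.write(_gff_entry(mid, self.gene_model, strand))
        paths["gff3"] = gff_path
        groups_path = outdir / "groups.txt"
        with open(groups_path, "w") as fh:
            members = " ".join(
                f"{self.species_of[mid]}|{mid}" for mid in sorted(self.members)
            )
            fh.write(f"FAM1: {members}\n")
        paths["groups"] = groups_path
        truth_path = outdir / "truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("id\tkind\tspecies\twindows\n")
            windows = ";".join(f"{a}-{b}" for a, b in self.conserved_coords())
            for mid in sorted(self.members):
                fh.write(f"{mid}\tmember\t{self.species_of[mid]}\t{windows}\n")
            for did in sorted(self.decoys):
                fh.write(f"{did}\tdecoy\tdecoy\t\n")
        paths["truth"] = truth_path
        return paths

    def as_database(self, include_decoys: bool = True) -> Database:
        db = Database()
        proteins = self.proteins
        for mid in sorted(self.members):
            sp = self.species_of[mid]
            db.add_record(mid, sp, SeqType.CDS, self.members[mid])
            db.add_record(mid, sp, SeqType.PROTEIN, proteins[mid])
            db.gene_models[db._internal_id(sp, SeqType.CDS, mid)] = replace(
                self.gene_model, cds_id=mid
            )
        if include_decoys:
            for did in sorted(self.decoys):
                db.add_record(did, "decoy", SeqType.CDS, self.decoys[did])
                db.add_record(
                    did,
                    "decoy",
                    SeqType.PROTEIN,
                    str(Seq(self.decoys[did]).translate(table=1)),
                )
        return db


def _fasta(name: str, seq: str, width: int = 60) -> str:
    lines = [f">{name}"]
    for i in range(0, len(seq), width):
        lines.append(seq[i : i + width])
    return "\n".join(lines) + "\n"


def _gff_entry(mid: str, model: GeneModel, strand: str) -> str:
    scaffold = f"{mid}_locus"
    intron = 120
    total = model.coding_length + intron * (len(model.exon_lengths) - 1)
    lines = [f"{scaffold}\tsynth\tmRNA\t1\t{total}\t.\t{strand}\t.\tID={mid}.m"]
    # exon coordinates laid out left to right; minus strand lists them in
    # genomic order while transcription runs right to left
    lengths = (
        model.exon_lengths if strand == "+" else tuple(reversed(model.exon_lengths))
    )
    pos = 1
    for i, length in enumerate(lengths):
        lines.append(
            f"{scaffold}\tsynth\tCDS\t{pos}\t{pos + length - 1}\t.\t{strand}\t.\t"
            f"ID=cds_{mid}.{i};Parent={mid}"
        )
        pos += length + intron
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------------ #
# family simulation                                                  #
# ------------------------------------------------------------------ #

def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS with no stop codons anywhere in frame 1."""
    codons = []
    while 3 * len(codons) < length:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _window_supports_primer(
    window: str, role: str, params: ThermoParams
) -> bool:
    """True if some sub-oligo of the window passes the default filters."""
    probe = window if role == "forward" else str(Seq(window).reverse_complement())
    for length in range(params.size_min, min(params.size_max, len(probe)) + 1):
        for start in range(0, len(probe) - length + 1):
            oligo = probe[start : start + length]
            tm = tm_melting(oligo, params)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            gc = gc_fraction(oligo)
            if not params.gc_min <= gc <= params.gc_max:
                continue
            if dimer_score(oligo, oligo) > params.max_homodimer_score:
                continue
            return True
    return False


def _plant_windows(
    cds: str, spec: FamilySpec, rng: np.random.Generator, params: ThermoParams
) -> str:
    """Rewrite each conserved window until primer-feasible and stop-free."""
    seq = list(cds)
    for w in spec.conserved_windows:
        for _ in range(10000):
            codons = []
            while 3 * len(codons) < w.length + 4:  # margin to stay in frame
                codon = "".join(rng.choice(list(_BASES), size=3))
                if codon not in _STOPS:
                    codons.append(codon)
            frame_shift = w.start % 3
            candidate = "".join(codons)[frame_shift : frame_shift + w.length]
            trial = seq[:]
            trial[w.start : w.start + w.length] = candidate
            if _has_inframe_stop("".join(trial)):
                continue
            if w.role is None or _window_supports_primer(candidate, w.role, params):
                seq = trial
                break
        else:
            raise SynthError(f"could not plant feasible window at {w.start}")
    return "".join(seq)


def _has_inframe_stop(cds: str) -> bool:
    return any(cds[i : i + 3] in _STOPS for i in range(0, len(cds), 3))


def _random_topology(rng: np.random.Generator, tips: list[str]):
    """Random bifurcating tree as nested tuples over tip names."""
    nodes: list = list(tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = (nodes[i], nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _mutate(
    cds: str,
    rate: float,
    frozen: list[tuple[int, int]],
    rng: np.random.Generator,
) -> str:
    seq = list(cds)
    frozen_mask = [False] * len(seq)
    for a, b in frozen:
        for i in range(a, b):
            frozen_mask[i] = True
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        if frozen_mask[pos]:
            continue
        alternatives = [b for b in _BASES if b != seq[pos]]
        for _ in range(10):
            new = alternatives[int(rng.integers(len(alternatives)))]
            old = seq[pos]
            seq[pos] = new
            codon_start = 3 * (pos // 3)
            if "".join(seq[codon_start : codon_start + 3]) in _STOPS:
                seq[pos] = old  # resample: mutation would create a stop
                continue
            break
    return "".join(seq)


def simulate_family(spec: FamilySpec) -> SimulatedFamily:
    """Evolve one ancestral CDS into a labelled multi-species gene family."""
    rng = np.random.default_rng(spec.seed)
    params = ThermoParams()
    ancestor = _plant_windows(_random_cds(rng, spec.cds_length), spec, rng, params)
    frozen = [(w.start, w.start + w.length) for w in spec.conserved_windows]

    tips = [
        f"sp{i + 1}_g{j + 1}"
        for i in range(spec.n_species)
        for j in range(spec.n_paralogs)
    ]
    topology = _random_topology(rng, tips)

    members: dict[str, str] = {}

    def newick(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(newick(ch) for ch in node) + ")"

    def evolve(node, seq: str) -> None:
        seq = _mutate(seq, spec.substitution_rate, frozen, rng)
        if isinstance(node, str):
            members[node] = seq
            return
        for child in node:
            evolve(child, seq)

    evolve(topology, ancestor)

    species_of = {mid: mid.split("_")[0] for mid in members}
    decoys = {
        f"decoy{k + 1}": _random_cds(rng, spec.cds_length)
        for k in range(spec.n_decoys)
    }
    return SimulatedFamily(
        spec=spec,
        members=members,
        species_of=species_of,
        decoys=decoys,
        tree_newick=newick(topology) + ";",
        gene_model=GeneModel(cds_id="family", exon_lengths=spec.exon_lengths),
    )


# ------------------------------------------------------------------ #
# planted primer-site templates                                      #
# ------------------------------------------------------------------ #

def plant_primer_template(
    length: int,
    fwd_site: tuple[int, str],
    rev_site: tuple[int, str] | None,
    inverted_repeat: bool = False,
    seed: int = 0,
) -> tuple[str, dict]:
    """Random DNA template with exact planted primer sites.

    ``fwd_site`` is (plus-strand start, forward primer 5'->3'); the
    reverse primer of ``rev_site`` is planted as its reverse complement.
    With ``inverted_repeat`` the reverse complement of the *forward*
    primer is planted at the reverse position instead, producing a
    forward-only (single primer) product.  The background is
    rejection-sampled so neither primer occurs exactly anywhere else on
    either strand.  Returns (template, truth coordinates).
    """
    rng = np.random.default_rng(seed)
    fpos, fseq = fwd_site
    fseq = fseq.upper()
    planted = [(fpos, fseq)]
    rseq = None
    if inverted_repeat:
        if rev_site is None:
            raise SynthError("inverted_repeat needs a position in rev_site")
        rpos = rev_site[0] if isinstance(rev_site, tuple) else rev_site
        planted.append((rpos, str(Seq(fseq).reverse_complement())))
    elif rev_site is not None:
        rpos, rseq = rev_site
        rseq = rseq.upper()
        planted.append((rpos, str(Seq(rseq).reverse_complement())))
    intervals = sorted((p, p + len(s)) for p, s in planted)
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if b1 > a2:
            raise SynthError("planted sites overlap")
    if intervals[-1][1] > length:
        raise SynthError("planted site extends past template end")

    probes = {fseq, str(Seq(fseq).reverse_complement())}
    if rseq is not None:
        probes |= {rseq, str(Seq(rseq).reverse_complement())}

    for _ in range(1000):
        template = list("".join(rng.choice(list(_BASES), size=length)))
        for pos, s in planted:
            template[pos : pos + len(s)] = s
        text = "".join(template)
        planted_spans = [(p, p + len(s)) for p, s in planted]
        if not _accidental_hit(text, probes, planted_spans):
            truth = {
                "forward": (fpos, fpos + len(fseq)),
                "reverse": (planted[1][0], planted[1][0] + len(planted[1][1]))
                if len(planted) > 1
                else None,
                "inverted_repeat": inverted_repeat,
            }
            return text, truth
    raise SynthError("could not sample a clean background")


def _accidental_hit(text: str, probes: set[str], planted_spans) -> bool:
    for probe in probes:
        pos = text.find(probe)
        while pos != -1:
            span = (pos, pos + len(probe))
            if span not in planted_spans:
                return True
            pos = text.find(probe, pos + 1)
    return False
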