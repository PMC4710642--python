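"""Multiple sequence alignments: progressive alignment, codon
back-translation, consensus sequences, intron-phase overlay and
low-conservation trimming.

A codon alignment is never computed directly from nucleotides: it is the
protein alignment with every residue replaced by its codon and every gap
extended to three, which keeps the reading frame intact by construction.

Intron positions from gene models are drawn on top of alignments.  On a
protein alignment the mark is the intron phase digit placed on the
residue whose codon is preceded (phase 0) or interrupted (phase 1/2) by
the intron; on nucleotide/codon alignments the mark is a ``^`` placed
before the column of the first coding base after the intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from numba import njit

from . import phylo
from .seqdb import SequenceRecord, translate_cds
from .simsearch import ScoringScheme, dna_scheme, protein_scheme

GAP = "-"

# IUPAC nucleotide codes keyed by the sorted set of bases they stand for
IUPAC_FOR_SET: dict[frozenset, str] = {
    frozenset(v): k for k, v in ambiguous_dna_values.items() if k != "X"
}
SET_FOR_IUPAC: dict[str, frozenset] = {
    k: frozenset(v) for k, v in ambiguous_dna_values.items() if k != "X"
}


class AlignmentError(Exception):
    pass


@dataclass
class Alignment:
    """Equal-length gapped rows with an optional intron overlay.

    ``kind`` is "protein", "nucleotide" or "codon"; for codon alignments
    the column count and every gap run length are multiples of three.
    ``intron_marks`` maps a row id to ``(column, phase)`` tuples.
    """

    rows: list[tuple[str, str]]
    kind: str
    intron_marks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("protein", "nucleotide", "codon"):
            raise AlignmentError(f"unknown alignment kind {self.kind!r}")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("alignment rows differ in length")
        if self.kind == "codon" and self.rows:
            if self.column_count % 3:
                raise AlignmentError("codon alignment length not a multiple of 3")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def row_ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, row_id: str) -> str:
        for rid, seq in self.rows:
            if rid == row_id:
                return seq
        raise KeyError(row_id)

    def column(self, i: int) -> list[str]:
        return [seq[i] for _, seq in self.rows]

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")


# ------------------------------------------------------------------ #
# progressive alignment                                              #
# ------------------------------------------------------------------ #

def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def kmer_distance_matrix(seqs: list[str], k: int) -> np.ndarray:
    """1 - shared-kmer fraction, the usual quick guide-tree distance."""
    counts = [_kmer_counts(s, k) for s in seqs]
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum(
                min(c, counts[j].get(w, 0)) for w, c in counts[i].items()
            )
            denom = min(len(seqs[i]), len(seqs[j])) - k + 1
            d = 1.0 - shared / denom if denom > 0 else 1.0
            dm[i, j] = dm[j, i] = max(d, 0.0)
    return dm


@njit(cache=False)
def _nw_profile_fill(S, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = S.shape
    neg = -1e18
    first = gap_open + gap_extend
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -first - (i - 1) * gap_extend
        ptr_x[i, 0] = 1 if i == 1 else 2
    for j in range(1, m + 1):
        Iy[0, j] = -first - (j - 1) * gap_extend
        ptr_y[0, j] = 1 if j == 1 else 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            open_x = M[i - 1, j] - first
            ext_x = Ix[i - 1, j] - gap_extend
            if open_x >= ext_x:
                Ix[i, j] = open_x
                ptr_x[i, j] = 1
            else:
                Ix[i, j] = ext_x
                ptr_x[i, j] = 2
            open_y = M[i, j - 1] - first
            ext_y = Iy[i, j - 1] - gap_extend
            if open_y >= ext_y:
                Iy[i, j] = open_y
                ptr_y[i, j] = 1
            else:
                Iy[i, j] = ext_y
                ptr_y[i, j] = 3
            src, val = 1, M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > val:
                src, val = 2, Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > val:
                src, val = 3, Iy[i - 1, j - 1]
            M[i, j] = val + S[i - 1, j - 1]
            ptr_m[i, j] = src
    end_state, end_score = 1, M[n, m]
    if Ix[n, m] > end_score:
        end_state, end_score = 2, Ix[n, m]
    if Iy[n, m] > end_score:
        end_state, end_score = 3, Iy[n, m]
    return end_score, end_state, ptr_m, ptr_x, ptr_y


def _profile(rows: list[str], scheme: ScoringScheme) -> np.ndarray:
    """Per-column residue frequencies (gaps carry zero mass)."""
    idx = {c: i for i, c in enumerate(scheme.alphabet)}
    ncol = len(rows[0])
    freq = np.zeros((ncol, len(scheme.alphabet)))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                freq[j, idx[c]] += 1.0
    return freq / len(rows)


def _merge(
    rows_a: list[tuple[str, str]],
    rows_b: list[tuple[str, str]],
    scheme: ScoringScheme,
) -> list[tuple[str, str]]:
    fa = _profile([s for _, s in rows_a], scheme)
    fb = _profile([s for _, s in rows_b], scheme)
    S = fa @ scheme.matrix.astype(float) @ fb.T
    _, state, ptr_m, ptr_x, ptr_y = _nw_profile_fill(
        S, float(scheme.gap_open), float(scheme.gap_extend)
    )
    i, j = S.shape
    keep_a: list[int] = []  # -1 denotes an all-gap column for that side
    keep_b: list[int] = []
    while i > 0 or j > 0:
        if state == 1:
            keep_a.append(i - 1)
            keep_b.append(j - 1)
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
        elif state == 2:
            keep_a.append(i - 1)
            keep_b.append(-1)
            state = ptr_x[i, j]
            i -= 1
        else:
            keep_a.append(-1)
            keep_b.append(j - 1)
            state = ptr_y[i, j]
            j -= 1
    keep_a.reverse()
    keep_b.reverse()

    def expand(rows, keep):
        return [
            (rid, "".join(seq[k] if k >= 0 else GAP for k in keep))
            for rid, seq in rows
        ]

    return expand(rows_a, keep_a) + expand(rows_b, keep_b)


def progressive_align(
    seqs: list[SequenceRecord],
    kind: str,
    scheme: ScoringScheme | None = None,
) -> Alignment:
    """Progressive profile alignment along an NJ guide tree.

    k-mer distances (k=3 protein, k=4 nucleotide) feed a neighbor-joining
    guide tree; profiles are merged by global affine-gap alignment of
    expected-substitution-score columns.  Deterministic for a given input
    order.
    """
    if len(seqs) < 2:
        raise AlignmentError("progressive alignment needs at least two sequences")
    if kind not in ("protein", "nucleotide"):
        raise AlignmentError(f"cannot align kind {kind!r} directly")
    if scheme is None:
        scheme = protein_scheme() if kind == "protein" else dna_scheme()
    ids = [s.internal_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids in alignment input")
    raw = {s.internal_id: s.sequence.upper() for s in seqs}
    if len(seqs) == 2:
        merged = _merge(
            [(ids[0], raw[ids[0]])], [(ids[1], raw[ids[1]])], scheme
        )
        return Alignment(rows=merged, kind=kind)

    k = 3 if kind == "protein" else 4
    dm = kmer_distance_matrix([raw[i] for i in ids], k)
    guide = phylo.nj_tree(phylo.DistanceMatrix(labels=list(ids), matrix=dm))

    def build(node) -> list[tuple[str, str]]:
        if node.is_leaf():
            return [(node.label, raw[node.label])]
        parts = [build(child) for child, _ in node.children]
        acc = parts[0]
        for part in parts[1:]:
            acc = _merge(acc, part, scheme)
        return acc

    rows = build(guide.root)
    order = {rid: pos for pos, rid in enumerate(ids)}
    rows.sort(key=lambda r: order[r[0]])
    return Alignment(rows=rows, kind=kind)


# ------------------------------------------------------------------ #
# codon back-translation                                             #
# ------------------------------------------------------------------ #

_STOPS = {"TAA", "TAG", "TGA"}


def backtranslate_to_codon(
    protein_aln: Alignment, cds_by_id: dict[str, str]
) -> Alignment:
    """Replace each aligned residue by its codon; each gap becomes ``---``.

    A trailing stop codon on the CDS is stripped first.  Every codon is
    checked against the residue it replaces; a mismatch is an error naming
    the row and alignment column.
    """
    if protein_aln.kind != "protein":
        raise AlignmentError("back-translation starts from a protein alignment")
    rows = []
    for rid, prow in protein_aln.rows:
        cds = cds_by_id[rid].upper()
        if len(cds) % 3:
            raise AlignmentError(f"row {rid}: CDS length not a multiple of 3")
        if cds[-3:] in _STOPS:
            cds = cds[:-3]
        plen = len(prow) - prow.count(GAP)
        if len(cds) != 3 * plen:
            raise AlignmentError(
                f"row {rid}: CDS has {len(cds)} nt but protein row needs {3 * plen}"
            )
        out = []
        pos = 0
        for col, aa in enumerate(prow):
            if aa == GAP:
                out.append(GAP * 3)
                continue
            codon = cds[3 * pos : 3 * pos + 3]
            trans = translate_cds(codon)
            if trans != aa and not (aa == "X" and trans in ("X", "")):
                raise AlignmentError(
                    f"row {rid}, column {col}: codon {codon} translates to "
                    f"{trans!r}, expected {aa!r}"
                )
            out.append(codon)
            pos += 1
        rows.append((rid, "".join(out)))
    return Alignment(rows=rows, kind="codon")


# ------------------------------------------------------------------ #
# consensus                                                          #
# ------------------------------------------------------------------ #

def consensus(aln: Alignment, mode: str = "strict") -> str:
    """Per-column consensus of a nucleotide or codon alignment.

    strict  -- the residue if every row agrees (a gap anywhere breaks
               agreement), else ``N``;
    majority -- most frequent non-gap residue, ties resolved to the IUPAC
               code of the tied set;
    iupac   -- IUPAC code covering all observed non-gap residues.
    All-gap columns give ``-`` in every mode.
    """
    if aln.kind == "protein":
        raise AlignmentError("consensus is defined for nucleotide/codon alignments")
    if len(aln.rows) < 2:
        raise AlignmentError("consensus needs at least two rows")
    if mode not in ("strict", "majority", "iupac"):
        raise AlignmentError(f"unknown consensus mode {mode!r}")
    out = []
    for i in range(aln.column_count):
        col = aln.column(i)
        residues = [c for c in col if c != GAP]
        if not residues:
            out.append(GAP)
            continue
        if mode == "strict":
            out.append(col[0] if len(set(col)) == 1 else "N")
        elif mode == "majority":
            counts: dict[str, int] = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            top = max(counts.values())
            tied = frozenset(c for c, n in counts.items() if n == top)
            out.append(next(iter(tied)) if len(tied) == 1 else _iupac(tied))
        else:
            out.append(_iupac(frozenset(residues)))
    return "".join(out)


def _iupac(residues: frozenset) -> str:
    expanded: set[str] = set()
    for r in residues:
        expanded |= set(SET_FOR_IUPAC.get(r, r))
    return IUPAC_FOR_SET[frozenset(expanded)]


# ------------------------------------------------------------------ #
# intron overlay                                                     #
# ------------------------------------------------------------------ #

def overlay_intron_phases(aln: Alignment, gene_models: dict) -> Alignment:
    """Attach intron marks from gene models to alignment rows.

    Protein rows: the mark sits on the column of residue ``offset // 3``
    (0-based), the residue whose codon is preceded or interrupted by the
    intron.  Nucleotide/codon rows: the mark sits before the column of
    ungapped position ``offset``.
    """
    marks: dict[str, list[tuple[int, int]]] = {}
    for rid, row in aln.rows:
        model = gene_models.get(rid)
        if model is None:
            continue
        degapped_len = len(row) - row.count(GAP)
        row_marks = []
        for intron in model.introns:
            o = intron.coding_offset
            if aln.kind == "protein":
                limit = 3 * degapped_len
                target = o // 3
            else:
                limit = degapped_len
                target = o
            if o > limit or (aln.kind == "protein" and target >= degapped_len):
                raise AlignmentError(
                    f"row {rid}: intron offset {o} beyond coding length"
                )
            col = _column_of_ungapped(row, target)
            row_marks.append((col, intron.phase))
        marks[rid] = row_marks
    return replace(aln, intron_marks=marks)


def _column_of_ungapped(row: str, target: int) -> int:
    seen = 0
    for col, c in enumerate(row):
        if c != GAP:
            if seen == target:
                return col
            seen += 1
    raise AlignmentError(f"ungapped position {target} beyond row length")


# ------------------------------------------------------------------ #
# trimming                                                           #
# ------------------------------------------------------------------ #

def trim_low_conservation(
    aln: Alignment,
    max_gap_fraction: float = 0.2,
    min_conservation: float = 0.5,
    columns: list[int] | None = None,
) -> tuple[Alignment, list[int]]:
    """Drop gappy / poorly conserved columns before tree building.

    A column fails if its gap fraction exceeds ``max_gap_fraction`` or the
    frequency of its most common non-gap residue (among non-gaps) is below
    ``min_conservation``.  Codon alignments drop whole codon triples when
    any member column fails.  ``columns`` switches to manual mode and
    removes exactly the listed columns.  Returns the trimmed alignment and
    the removed column indices; intron marks are not carried over.
    """
    if columns is not None:
        removed = sorted(set(columns))
        bad = [c for c in removed if not 0 <= c < aln.column_count]
        if bad:
            raise AlignmentError(f"columns out of range: {bad}")
    else:
        if not 0 <= max_gap_fraction <= 1 or not 0 <= min_conservation <= 1:
            raise AlignmentError("thresholds must lie in [0, 1]")
        failing = set()
        nrows = len(aln.rows)
        for i in range(aln.column_count):
            col = aln.column(i)
            gaps = col.count(GAP)
            if gaps / nrows > max_gap_fraction:
                failing.add(i)
                continue
            residues = [c for c in col if c != GAP]
            counts: dict[str, int] = {}
            for c in residues:
                counts[c] = counts.get(c, 0) + 1
            if not residues or max(counts.values()) / len(residues) < min_conservation:
                failing.add(i)
        if aln.kind == "codon":
            removed = sorted(
                {
                    3 * (i // 3) + k
                    for i in failing
                    for k in range(3)
                }
            )
        else:
            removed = sorted(failing)
    if len(removed) == aln.column_count and aln.column_count:
        raise AlignmentError("trimming would remove every column")
    removed_set = set(removed)
    rows = [
        (rid, "".join(c for i, c in enumerate(seq) if i not in removed_set))
        for rid, seq in aln.rows
    ]
    return Alignment(rows=rows, kind=aln.kind), removed


def concatenate_alignments(alns: list[Alignment]) -> Alignment:
    """Concatenate alignments sharing the same row-id set (supermatrix)."""
    if not alns:
        raise AlignmentError("nothing to concatenate")
    first = alns[0]
    ref_ids = set(first.row_ids)
    for a in alns[1:]:
        if a.kind != first.kind:
            raise AlignmentError("cannot concatenate alignments of different kinds")
        if set(a.row_ids) != ref_ids:
            missing = ref_ids ^ set(a.row_ids)
            raise AlignmentError(f"row-id mismatch: {sorted(missing)}")
    rows = []
    for rid in first.row_ids:
        rows.append((rid, "".join(a.row(rid) for a in alns)))
    marks: dict[str, list[tuple[int, int]]] = {}
    offset = 0
    for a in alns:
        for rid, row_marks in a.intron_marks.items():
            marks.setdefault(rid, []).extend(
                (col + offset, phase) for col, phase in row_marks
            )
        offset += a.column_count
    return Alignment(rows=rows, kind=first.kind, intron_marks=marks)


# ------------------------------------------------------------------ #
# I/O and rendering                                                  #
# ------------------------------------------------------------------ #

def write_fasta(aln: Alignment, path) -> None:
    records = [
        _BioSeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, kind: str) -> Alignment:
    rows = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return Alignment(rows=rows, kind=kind)


def render(aln: Alignment, consensus_mode: str | None = "strict", width: int = 60) -> str:
    """Plain-text report: rows in blocks, intron overlay, consensus at bottom."""
    cons = None
    if consensus_mode and aln.kind != "protein" and len(aln.rows) >= 2:
        cons = consensus(aln, consensus_mode)
    name_w = max(len(rid) for rid, _ in aln.rows) + 2
    out = []
    for start in range(0, aln.column_count, width):
        end = min(start + width, aln.column_count)
        for rid, seq in aln.rows:
            row_marks = {c: p for c, p in aln.intron_marks.get(rid, [])}
            if row_marks:
                overlay = "".join(
                    (str(row_marks[c]) if aln.kind == "protein" else "^")
                    if c in row_marks
                    else " "
                    for c in range(start, end)
                )
                if overlay.strip():
                    out.append(" " * name_w + overlay)
            out.append(rid.ljust(name_w) + seq[start:end])
        if cons:
            out.append("consensus".ljust(name_w) + cons[start:end])
        out.append("")
    return "\n".join(out)
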