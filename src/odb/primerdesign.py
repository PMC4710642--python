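"""Primer design: oligo melting temperature, GC content, dimer
screening, IUPAC degeneracy, and the three design modes -- specific
(one template), consensus (perfectly conserved alignment regions) and
degenerate (IUPAC primers covering every row of an alignment).

Melting temperatures come from the unified nearest-neighbour
parameters of SantaLucia (1998):

    Tm = 1000*dH / (dS + R*ln(C_T/4)) - 273.15 + 16.6*log10([Na+])

with dH in kcal/mol, dS in cal/(mol*K), R = 1.987 cal/(mol*K), total
oligo concentration C_T (default 50 nM) and monovalent salt in mol/L
(default 50 mM).  The NN table is at 1 M NaCl; the 16.6*log10 term
rescales to the working salt concentration.

Dimer propensity is the best local-alignment score of one primer
against the reverse complement of the other (match +1, mismatch -1,
gap -2) -- self against self for homodimers.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from .msa import GAP, Alignment, consensus as _consensus
from .simsearch import ScoringScheme, _dna_matrix, local_align

logger = logging.getLogger(__name__)

R_GAS = 1.987  # cal / (mol K)

# SantaLucia 1998 unified NN parameters: dH kcal/mol, dS cal/(mol K)
NN_TABLE: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation with a terminal G.C / A.T pair
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
SYMMETRY_DS = -1.4  # self-complementary duplexes

IUPAC_SETS: dict[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
IUPAC_CODES: dict[frozenset, str] = {v: k for k, v in IUPAC_SETS.items()}


class PrimerError(Exception):
    pass


@dataclass(frozen=True)
class ThermoParams:
    """All tunable thresholds for primer design, with units."""

    monovalent_mM: float = 50.0
    oligo_nM: float = 50.0
    tm_min: float = 50.0        # deg C; NN model at the salt above
    tm_max: float = 62.0
    gc_min: float = 0.30        # fraction
    gc_max: float = 0.70
    max_homodimer_score: int = 8
    max_heterodimer_score: int = 8
    size_min: int = 18
    size_max: int = 27
    product_min: int = 80
    product_max: int = 300
    max_degeneracy: int = 64
    max_tm_difference: float = 3.0  # deg C between pair mates
    max_pairs: int = 50             # ranked pairs returned (Primer3-style top N)

    def __post_init__(self):
        for lo, hi, what in (
            (self.tm_min, self.tm_max, "tm"),
            (self.gc_min, self.gc_max, "gc"),
            (self.size_min, self.size_max, "size"),
            (self.product_min, self.product_max, "product"),
        ):
            if lo > hi:
                raise PrimerError(f"{what}: min {lo} exceeds max {hi}")


# ------------------------------------------------------------------ #
# elementary oligo properties                                        #
# ------------------------------------------------------------------ #

def tm_melting(seq: str, params: ThermoParams = ThermoParams()) -> float:
    """Nearest-neighbour melting temperature (deg C) of a concrete oligo."""
    seq = seq.upper()
    if len(seq) < 8:
        raise PrimerError("Tm model needs at least 8 nt")
    if set(seq) - set("ACGT"):
        raise PrimerError(
            f"ambiguous bases in {seq!r}: expand the degenerate primer first"
        )
    dh, ds = 0.0, 0.0
    for a, b in ((seq[0], INIT_AT if seq[0] in "AT" else INIT_GC),
                 (seq[-1], INIT_AT if seq[-1] in "AT" else INIT_GC)):
        dh += b[0]
        ds += b[1]
    for i in range(len(seq) - 1):
        h, s = NN_TABLE[seq[i : i + 2]]
        dh += h
        ds += s
    selfcomp = seq == str(Seq(seq).reverse_complement())
    if selfcomp:
        ds += SYMMETRY_DS
        conc = params.oligo_nM * 1e-9 / 2.0
    else:
        conc = params.oligo_nM * 1e-9 / 4.0
    tm_1m = 1000.0 * dh / (ds + R_GAS * math.log(conc)) - 273.15
    return tm_1m + 16.6 * math.log10(params.monovalent_mM / 1000.0)


def gc_fraction(seq: str) -> float:
    """GC content of a concrete DNA sequence, as a fraction."""
    return _bio_gc_fraction(seq)


_DIMER_SCHEME = ScoringScheme(
    name="dimer",
    alphabet="ACGTN",
    matrix=_dna_matrix(1, -1),
    gap_open=0,
    gap_extend=2,  # linear gap cost of 2 per gapped position
)


@lru_cache(maxsize=1 << 18)
def _dimer_cached(s1: str, s2: str) -> int:
    rc2 = str(Seq(s2).reverse_complement())
    return local_align(s1, rc2, _DIMER_SCHEME).score


def dimer_score(s1: str, s2: str) -> int:
    """Cross-complementarity score of two oligos (higher = worse).

    Best local-alignment score of ``s1`` against the reverse complement of
    ``s2`` (match +1, mismatch -1, gap -2); symmetric in its arguments.
    ``dimer_score(s, s)`` scores homodimer formation.
    """
    a, b = sorted((s1.upper(), s2.upper()))
    return _dimer_cached(a, b)


def degeneracy(seq: str) -> int:
    """Number of concrete sequences a (possibly degenerate) oligo encodes."""
    out = 1
    for c in seq.upper():
        if c not in IUPAC_SETS:
            raise PrimerError(f"non-IUPAC character {c!r}")
        out *= len(IUPAC_SETS[c])
    return out


def expand_degenerate(seq: str) -> list[str]:
    """All concrete expansions of a degenerate oligo, lexicographic order."""
    pools = []
    for c in seq.upper():
        if c not in IUPAC_SETS:
            raise PrimerError(f"non-IUPAC character {c!r}")
        pools.append(sorted(IUPAC_SETS[c]))
    return ["".join(p) for p in itertools.product(*pools)]


def reverse_complement_degenerate(seq: str) -> str:
    out = []
    for c in reversed(seq.upper()):
        comp = frozenset(
            str(Seq(b).complement()) for b in IUPAC_SETS[c]
        )
        out.append(IUPAC_CODES[comp])
    return "".join(out)


# ------------------------------------------------------------------ #
# primer / pair containers                                           #
# ------------------------------------------------------------------ #

@dataclass(frozen=True)
class Primer:
    """A possibly degenerate oligo, written 5'->3' on its own strand.

    ``template_start`` is the 0-based plus-strand start of the binding
    window (alignment column for consensus/degenerate designs).
    """

    sequence: str
    strand: str
    template_start: int
    degeneracy: int
    tm_range: tuple[float, float]
    gc_range: tuple[float, float]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def five_prime(self) -> int:
        """0-based plus-strand coordinate of the 5' end."""
        return (
            self.template_start
            if self.strand == "+"
            else self.template_start + self.length - 1
        )


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_size: int
    penalty: float

    def __post_init__(self):
        if self.forward.five_prime >= self.reverse.five_prime:
            raise PrimerError("forward 5' must lie strictly upstream of reverse 5'")


@dataclass
class DesignResult:
    """Ranked primer pairs plus, on failure, which filter dominated."""

    pairs: list[PrimerPair]
    rejections: Counter = field(default_factory=Counter)

    @property
    def dominant_reason(self) -> str | None:
        if self.pairs or not self.rejections:
            return None
        return self.rejections.most_common(1)[0][0]


_PENALTY_WEIGHTS = {"tm": 1.0, "gc": 0.5, "size": 0.2}
_OPTIMUM = {"tm": 60.0, "gc": 0.5, "size": 20}


def _primer_penalty(tm: float, gc: float, size: int) -> float:
    return (
        _PENALTY_WEIGHTS["tm"] * abs(tm - _OPTIMUM["tm"])
        + _PENALTY_WEIGHTS["gc"] * abs(gc - _OPTIMUM["gc"])
        + _PENALTY_WEIGHTS["size"] * abs(size - _OPTIMUM["size"])
    )


@dataclass(frozen=True)
class _Candidate:
    primer: Primer
    tm_mid: float
    gc_mid: float
    expansions: tuple[str, ...]

    @property
    def penalty(self) -> float:
        return _primer_penalty(self.tm_mid, self.gc_mid, self.primer.length)


def _check_window(
    window: str,
    strand: str,
    start: int,
    params: ThermoParams,
    rejections: Counter,
) -> _Candidate | None:
    """Filter one candidate window; window is given 5'->3' on ``strand``."""
    try:
        deg = degeneracy(window)
    except PrimerError:
        rejections["alphabet"] += 1
        return None
    if deg > params.max_degeneracy:
        rejections["degeneracy"] += 1
        return None
    expansions = expand_degenerate(window)
    tms, gcs = [], []
    for e in expansions:
        tm = tm_melting(e, params)
        if not params.tm_min <= tm <= params.tm_max:
            rejections["tm"] += 1
            return None
        gc = gc_fraction(e)
        if not params.gc_min <= gc <= params.gc_max:
            rejections["gc"] += 1
            return None
        tms.append(tm)
        gcs.append(gc)
    for e in expansions:
        if dimer_score(e, e) > params.max_homodimer_score:
            rejections["homodimer"] += 1
            return None
    primer = Primer(
        sequence=window,
        strand=strand,
        template_start=start,
        degeneracy=deg,
        tm_range=(min(tms), max(tms)),
        gc_range=(min(gcs), max(gcs)),
    )
    return _Candidate(
        primer=primer,
        tm_mid=(min(tms) + max(tms)) / 2,
        gc_mid=(min(gcs) + max(gcs)) / 2,
        expansions=tuple(expansions),
    )


def _rank_pairs(
    forwards: list[_Candidate],
    reverses: list[_Candidate],
    params: ThermoParams,
    rejections: Counter,
) -> list[tuple[_Candidate, _Candidate, int]]:
    """Penalty-ranked (forward, reverse, product_size) passing the cheap
    geometric and Tm-difference filters; dimer screening comes later."""
    prelim = []
    for f in forwards:
        for r in reverses:
            if f.primer.five_prime >= r.primer.five_prime:
                continue
            if f.primer.template_start + f.primer.length > r.primer.template_start:
                continue  # overlapping binding windows
            size = r.primer.five_prime - f.primer.five_prime + 1
            if not params.product_min <= size <= params.product_max:
                rejections["product"] += 1
                continue
            if abs(f.tm_mid - r.tm_mid) > params.max_tm_difference:
                rejections["tm_difference"] += 1
                continue
            prelim.append((f, r, size))
    prelim.sort(
        key=lambda t: (
            t[0].penalty + t[1].penalty,
            t[0].primer.template_start,
            t[1].primer.template_start,
        )
    )
    return prelim


def _heterodimer_ok(
    f: _Candidate,
    r: _Candidate,
    params: ThermoParams,
    check_expansions: bool,
) -> bool:
    if check_expansions:
        return all(
            dimer_score(fe, re_) <= params.max_heterodimer_score
            for fe in f.expansions
            for re_ in r.expansions
        )
    return (
        dimer_score(f.primer.sequence, r.primer.sequence)
        <= params.max_heterodimer_score
    )


def _pair_candidates(
    forwards: list[_Candidate],
    reverses: list[_Candidate],
    params: ThermoParams,
    rejections: Counter,
    check_heterodimer_expansions: bool = False,
    accept=None,
) -> list[PrimerPair]:
    """Assemble ranked pairs, lazily screening heterodimers (and any extra
    ``accept`` predicate) in penalty order until ``max_pairs`` are kept."""
    pairs: list[PrimerPair] = []
    for f, r, size in _rank_pairs(forwards, reverses, params, rejections):
        if len(pairs) >= params.max_pairs:
            break
        if not _heterodimer_ok(f, r, params, check_heterodimer_expansions):
            rejections["heterodimer"] += 1
            continue
        pair = PrimerPair(
            forward=f.primer,
            reverse=r.primer,
            product_size=size,
            penalty=f.penalty + r.penalty,
        )
        if accept is not None and not accept(pair):
            rejections["verification"] += 1
            continue
        pairs.append(pair)
    return pairs


# ------------------------------------------------------------------ #
# design modes                                                       #
# ------------------------------------------------------------------ #

def _enumerate_windows(template: str, allowed, params, rejections):
    """Forward and reverse candidates over every window of allowed size."""
    forwards, reverses = [], []
    for length in range(params.size_min, params.size_max + 1):
        for start in range(0, len(template) - length + 1):
            if not allowed(start, start + length):
                rejections["region"] += 1
                continue
            window = template[start : start + length]
            f = _check_window(window, "+", start, params, rejections)
            if f is not None:
                forwards.append(f)
            rc = reverse_complement_degenerate(window)
            r = _check_window(rc, "-", start, params, rejections)
            if r is not None:
                reverses.append(r)
    return forwards, reverses


def design_specific(
    template: str,
    params: ThermoParams = ThermoParams(),
    included_region: tuple[int, int] | None = None,
    excluded_regions: list[tuple[int, int]] | None = None,
) -> DesignResult:
    """Design primer pairs on a single DNA template.

    ``included_region`` restricts both primers to a 0-based half-open
    interval; ``excluded_regions`` forbids any overlap.  Pairs are ranked
    by a penalty summing weighted deviations from Tm 60 deg C, GC 0.5 and
    length 20 over both mates.
    """
    template = template.upper()
    if set(template) - set("ACGTN"):
        raise PrimerError("template must be DNA")
    excluded = excluded_regions or []
    for lo, hi in ([included_region] if included_region else []) + list(excluded):
        if not (0 <= lo < hi <= len(template)):
            raise PrimerError(f"region ({lo}, {hi}) outside template bounds")

    def allowed(lo: int, hi: int) -> bool:
        if included_region and not (included_region[0] <= lo and hi <= included_region[1]):
            return False
        return all(hi <= xlo or lo >= xhi for xlo, xhi in excluded)

    rejections: Counter = Counter()
    forwards, reverses = _enumerate_windows(template, allowed, params, rejections)
    pairs = _pair_candidates(forwards, reverses, params, rejections)
    if not pairs:
        logger.info("no feasible pair; rejections: %s", dict(rejections))
    return DesignResult(pairs=pairs, rejections=rejections)


def design_consensus(
    aln: Alignment, params: ThermoParams = ThermoParams()
) -> DesignResult:
    """Design primers on perfectly conserved regions of an alignment.

    The strict consensus is computed; candidate windows may contain
    neither ``N`` (disagreement) nor gap columns, so every returned primer
    matches every row exactly.  Coordinates are alignment columns; use
    :func:`alignment_to_row_coordinate` for per-sequence positions.
    """
    if len(aln.rows) < 2:
        raise PrimerError("consensus design needs at least two rows")
    cons = _consensus(aln, mode="strict")
    rejections: Counter = Counter()

    def allowed(lo: int, hi: int) -> bool:
        window = cons[lo:hi]
        if "N" in window or GAP in window:
            rejections["conservation"] += 1
            return False
        return True

    forwards, reverses = _enumerate_windows(cons, allowed, params, rejections)
    # 'region' rejections here are really conservation failures
    pairs = _pair_candidates(forwards, reverses, params, rejections)
    return DesignResult(pairs=pairs, rejections=rejections)


def alignment_to_row_coordinate(aln: Alignment, row_id: str, column: int) -> int:
    """Ungapped position in ``row_id`` of an alignment column."""
    row = aln.row(row_id)
    if row[column] == GAP:
        raise PrimerError(f"column {column} is a gap in row {row_id}")
    return len(row[:column]) - row[:column].count(GAP)


def design_degenerate(
    aln: Alignment,
    params: ThermoParams = ThermoParams(),
    verify: bool = True,
) -> DesignResult:
    """Design degenerate primer pairs that amplify every row.

    Each gap-free alignment window yields a per-column IUPAC primer from
    the observed residues.  Windows over the degeneracy cap are dropped;
    every concrete expansion must pass the Tm, GC and homodimer filters;
    pairs are separated in alignment coordinates so the product is within
    bounds and no forward x reverse expansion forms a heterodimer.
    Finally each pair is verified by in-silico PCR to produce exactly one
    in-range product on every row (exact matching); only verified pairs
    are returned.
    """
    if len(aln.rows) < 2:
        raise PrimerError("degenerate design needs at least two rows")
    if params.max_degeneracy < 1:
        raise PrimerError("max_degeneracy must be >= 1")
    rejections: Counter = Counter()
    ncol = aln.column_count
    forwards, reverses = [], []
    for length in range(params.size_min, params.size_max + 1):
        for start in range(0, ncol - length + 1):
            cols = [aln.column(i) for i in range(start, start + length)]
            if any(GAP in col for col in cols):
                rejections["gap"] += 1
                continue
            window = "".join(_iupac_column(col) for col in cols)
            f = _check_window(window, "+", start, params, rejections)
            if f is not None:
                forwards.append(f)
            rc = reverse_complement_degenerate(window)
            r = _check_window(rc, "-", start, params, rejections)
            if r is not None:
                reverses.append(r)
    accept = None
    if verify:
        from .primermatch import predict_products

        templates = {rid: aln.degapped(rid) for rid, _ in aln.rows}

        def accept(pair: PrimerPair) -> bool:
            for rid, seq in templates.items():
                products = predict_products(
                    pair.forward.sequence,
                    pair.reverse.sequence,
                    {rid: seq},
                    product_min=params.product_min,
                    product_max=params.product_max,
                    max_mismatches=0,
                )
                if len(products) != 1:
                    return False
            return True

    pairs = _pair_candidates(
        forwards,
        reverses,
        params,
        rejections,
        check_heterodimer_expansions=True,
        accept=accept,
    )
    return DesignResult(pairs=pairs, rejections=rejections)


def _iupac_column(col: list[str]) -> str:
    observed: set[str] = set()
    for c in col:
        observed |= set(IUPAC_SETS[c])
    return IUPAC_CODES[frozenset(observed)]
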