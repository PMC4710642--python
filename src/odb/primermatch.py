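"""In-silico PCR: locate primer binding sites and enumerate amplifiable
products, including single-primer (inverted repeat) products.

Site finding is seed-based: for a mismatch budget k, the primer is cut
into k+1 non-overlapping exact seeds (pigeonhole: a gapless site with at
most k substitutions must contain one seed verbatim).  Every seed match
proposes a candidate window, which is refined with a small global
alignment (match +1, mismatch -1, gap -2, free template end gaps); the
site is kept when substitutions + gap columns stay within the budget and
(by default) the 3'-terminal base of the primer matches exactly.

Degenerate primers are expanded first; a site matches when at least one
expansion meets the budget, and that expansion is reported.

Product length is 5'-end to 5'-end, inclusive, the standard PCR
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .primerdesign import Primer, PrimerPair, expand_degenerate
from .seqdb import SequenceRecord

logger = logging.getLogger(__name__)


class MatchError(Exception):
    pass


@dataclass(frozen=True)
class BindingSite:
    """A primer binding site, always reported in plus-strand coordinates."""

    template_id: str
    strand: str            # strand the primer anneals to ('+': primer == template sense)
    start: int             # 0-based half-open interval on the plus strand
    end: int
    mismatches: int        # substitutions + gap columns in the refined alignment
    matched_expansion: str  # concrete primer sequence that matched

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    forward_site: BindingSite
    reverse_site: BindingSite
    product_length: int    # 5' to 5', inclusive
    kind: str              # "pair" | "forward-only" | "reverse-only"


def _primer_seq(primer: Primer | str) -> str:
    return (primer.sequence if isinstance(primer, Primer) else primer).upper()


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def refine_alignment(primer: str, window: str) -> tuple[int, int, int, int]:
    """Align the full primer to a window with free template end gaps.

    Scoring: match +1, mismatch -1, gap -2.  Returns (score, mismatches
    counted as substitutions + internal gap columns, window_start,
    window_end) of the best-scoring placement.
    """
    n, m = len(primer), len(window)
    NEG = -(10**9)
    # score[i][j]: best score aligning primer[:i] with window ending at j
    score = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]  # 1 diag, 2 up, 3 left
    cost = [[0] * (m + 1) for _ in range(n + 1)]  # mismatch count along best path
    for j in range(m + 1):
        score[0][j] = 0  # free leading template gap
    for i in range(1, n + 1):
        score[i][0] = -2 * i
        ptr[i][0] = 2
        cost[i][0] = i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = primer[i - 1] == window[j - 1]
            diag = score[i - 1][j - 1] + (1 if match else -1)
            up = score[i - 1][j] - 2
            left = score[i][j - 1] - 2
            best, which = diag, 1
            if up > best:
                best, which = up, 2
            if left > best:
                best, which = left, 3
            score[i][j] = best
            ptr[i][j] = which
            if which == 1:
                cost[i][j] = cost[i - 1][j - 1] + (0 if match else 1)
            elif which == 2:
                cost[i][j] = cost[i - 1][j] + 1
            else:
                cost[i][j] = cost[i][j - 1] + 1
    # free trailing template gap: best over last row
    bj = max(range(m + 1), key=lambda j: (score[n][j], -j))
    mism = cost[n][bj]
    # walk back to find window start of the aligned region
    i, j = n, bj
    while i > 0:
        which = ptr[i][j]
        if which == 1:
            i, j = i - 1, j - 1
        elif which == 2:
            i -= 1
        else:
            j -= 1
    return score[n][bj], mism, j, bj


def find_binding_sites(
    primer: Primer | str,
    template: SequenceRecord | str,
    template_id: str = "template",
    max_mismatches: int = 2,
    max_seed_hits: int = 1000,
    require_3prime_match: bool = True,
) -> list[BindingSite]:
    """Locate all binding sites of a (possibly degenerate) primer.

    Searches both strands; sites are reported on the plus strand, sorted
    by position, deduplicated to the best (fewest-mismatch) placement.
    """
    pseq = _primer_seq(primer)
    if isinstance(template, SequenceRecord):
        template_id, tseq = template.internal_id, template.sequence
    else:
        tseq = template.upper()
    L = len(pseq)
    seed_len = L // (max_mismatches + 1)
    if seed_len < 2:
        raise MatchError(
            f"primer of length {L} too short to seed with "
            f"{max_mismatches} mismatches (needs >= {2 * (max_mismatches + 1)} nt)"
        )
    expansions = expand_degenerate(pseq)
    pad = 2  # gap slack around the candidate window
    candidates: dict[tuple[str, int], list[str]] = {}
    n_candidates = 0
    for exp in expansions:
        for strand in ("+", "-"):
            probe = exp if strand == "+" else _revcomp(exp)
            for k in range(max_mismatches + 1):
                seed_start = k * seed_len
                seed = probe[seed_start : seed_start + seed_len]
                pos = tseq.find(seed)
                while pos != -1:
                    if n_candidates >= max_seed_hits:
                        break
                    window_start = pos - seed_start
                    key = (strand, window_start)
                    candidates.setdefault(key, [])
                    if exp not in candidates[key]:
                        candidates[key].append(exp)
                        n_candidates += 1
                    pos = tseq.find(seed, pos + 1)

    sites: dict[tuple[str, int, int], BindingSite] = {}
    for (strand, window_start), exps in sorted(candidates.items()):
        lo = max(0, window_start - pad)
        hi = min(len(tseq), window_start + L + pad)
        window = tseq[lo:hi]
        for exp in exps:
            probe = exp if strand == "+" else _revcomp(exp)
            _score, mism, wlo, whi = refine_alignment(probe, window)
            if mism > max_mismatches:
                continue
            start, end = lo + wlo, lo + whi
            if end <= start:
                continue
            if require_3prime_match:
                # primer 3' base: rightmost on '+', leftmost on '-'
                if strand == "+":
                    if end - 1 >= len(tseq) or tseq[end - 1] != probe[-1]:
                        continue
                else:
                    if tseq[start] != probe[0]:
                        continue
            key = (strand, start, end)
            site = BindingSite(
                template_id=template_id,
                strand=strand,
                start=start,
                end=end,
                mismatches=mism,
                matched_expansion=exp,
            )
            prev = sites.get(key)
            if prev is None or site.mismatches < prev.mismatches:
                sites[key] = site
    return sorted(sites.values(), key=lambda s: (s.start, s.end, s.strand))


def _templates_dict(templates) -> dict[str, str]:
    if isinstance(templates, dict):
        return {k: v.upper() for k, v in templates.items()}
    out = {}
    for rec in templates:
        out[rec.internal_id] = rec.sequence
    return out


def predict_products(
    forward: Primer | str,
    reverse: Primer | str,
    templates,
    product_min: int = 80,
    product_max: int = 3000,
    max_mismatches: int = 2,
    max_seed_hits: int = 1000,
    require_3prime_match: bool = True,
) -> list[Amplicon]:
    """Enumerate PCR products on a set of templates.

    Reports (i) pair products from convergent forward(+) / reverse(-)
    sites, (ii) forward-only products where the forward primer binds both
    strands convergently (inverted repeat), and (iii) reverse-only
    products likewise.  ``templates`` is a dict of id -> sequence or a
    list of sequence records.
    """
    tdict = _templates_dict(templates)
    fseq, rseq = _primer_seq(forward), _primer_seq(reverse)
    kwargs = dict(
        max_mismatches=max_mismatches,
        max_seed_hits=max_seed_hits,
        require_3prime_match=require_3prime_match,
    )
    out: list[Amplicon] = []
    for tid in sorted(tdict):
        tseq = tdict[tid]
        fsites = find_binding_sites(fseq, tseq, template_id=tid, **kwargs)
        rsites = find_binding_sites(rseq, tseq, template_id=tid, **kwargs)

        def convergent(a: BindingSite, b: BindingSite, kind: str):
            # a on '+', b on '-', a strictly upstream and non-overlapping
            if a.strand != "+" or b.strand != "-":
                return
            if a.end > b.start:
                return
            length = b.five_prime - a.five_prime + 1
            if product_min <= length <= product_max:
                out.append(
                    Amplicon(
                        template_id=tid,
                        forward_site=a,
                        reverse_site=b,
                        product_length=length,
                        kind=kind,
                    )
                )

        for fs in fsites:
            for rs in rsites:
                convergent(fs, rs, "pair")
        if fseq != rseq:
            for a in fsites:
                for b in fsites:
                    convergent(a, b, "forward-only")
            for a in rsites:
                for b in rsites:
                    convergent(a, b, "reverse-only")
    out.sort(key=lambda amp: (amp.template_id, amp.forward_site.start, amp.reverse_site.end))
    return out


@dataclass
class SpecificityReport:
    outcome: str            # "specific" | "non-specific" | "no product"
    intended_target_id: str
    amplicons: list[Amplicon]

    @property
    def off_target(self) -> list[Amplicon]:
        return [a for a in self.amplicons if a.template_id != self.intended_target_id]


def specificity_report(
    pair: PrimerPair | tuple,
    templates,
    intended_target_id: str,
    product_min: int = 80,
    product_max: int = 3000,
    max_mismatches: int = 2,
) -> SpecificityReport:
    """Screen a primer pair against a sequence set for off-target products.

    The pair is "specific" iff exactly one in-range product exists in the
    whole set and it lies on the intended target.
    """
    tdict = _templates_dict(templates)
    if intended_target_id not in tdict:
        raise MatchError(
            f"intended target {intended_target_id!r} absent from screened set"
        )
    if isinstance(pair, PrimerPair):
        fwd, rev = pair.forward.sequence, pair.reverse.sequence
    else:
        fwd, rev = pair
    amplicons = predict_products(
        fwd,
        rev,
        tdict,
        product_min=product_min,
        product_max=product_max,
        max_mismatches=max_mismatches,
    )
    if not amplicons:
        outcome = "no product"
    elif len(amplicons) == 1 and amplicons[0].template_id == intended_target_id:
        outcome = "specific"
    else:
        outcome = "non-specific"
    return SpecificityReport(
        outcome=outcome, intended_target_id=intended_target_id, amplicons=amplicons
    )
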