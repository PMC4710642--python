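# Methods

This note documents the models and algorithms behind `odb`, the
defaults that matter, the numerical choices, and what the synthetic
fixtures do and do not establish about real data.

## Sequence database

Sequences are held per (species, type) with the original FASTA
identifier preserved; internal ids are `species|type|original_id`.
Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) is converted on load and human-readable reports print
1-based positions.  Minus-strand gene structures are flipped into
transcript orientation on load, so downstream code never sees strands.
Only the standard genetic code (table 1) is supported; ambiguous codons
translate to `X`, and a trailing stop is tolerated when checking that a
CDS translates to its linked protein.  mRNA records are optional and no
operation requires them.

A gene model stores exon lengths in transcription order; intron
positions are derived as cumulative coding offsets with
`phase = offset mod 3` (0 between codons, 1 after the first, 2 after
the second base of a codon).  Saving a database writes synthesized GFF3
coordinates (pseudo-scaffold, fixed 120-nt introns) because genomic
coordinates are not retained — the exon-length structure, which is all
downstream logic uses, round-trips exactly.

Single-copy cluster filtering keeps clusters in which every required
species occurs exactly once; by default clusters containing any other
species are dropped (`allow_extra_species=True` relaxes this — the
stricter reading was chosen as default because it is the safer input
for species-tree concatenation).

## Similarity search

`local_align` is full Smith–Waterman with affine gaps; a gap of length
k costs `gap_open + k·gap_extend` (the BLAST convention, so the first
gapped position costs open+extend).  No heuristic seeding is used: at
the scale this tool targets (thousands of sequences) exact DP is
affordable, and the fill is JIT-compiled.  Traceback ties prefer
diagonal, then up, then left, making alignments deterministic.

Defaults: BLOSUM62 with gap open 11 / extend 1 for protein; match +2 /
mismatch −3 with open 5 / extend 2 for DNA (`N` never matches).
E-values use the ungapped Karlin–Altschul form `E = K·m·n·e^(−λS)` with
fixed constants (λ=0.318, K=0.13 for BLOSUM62; λ solved numerically
from the match/mismatch scores at uniform base composition, K=0.21, for
DNA).  These are documented as approximate for gapped scores — identity
and coverage are the primary gathering filters, with
`identity = matches / aligned columns` (gap columns count in the
denominator) and `coverage = aligned query residues / query length`.

`gather_related` unions filtered hits over all seeds, keeps each
subject's best e-value, ranks by e-value and applies the per-species
cap and total cap in that order; seeds are always included and do not
consume quota.  Because caps are applied after ranking, tightening any
threshold can only remove results (tested as a monotonicity property).

## Alignments

Progressive alignment: k-mer distances (k=3 protein, k=4 DNA;
`1 − shared/min-length` fraction) feed a neighbor-joining guide tree;
profiles are merged along it by global affine-gap DP over
expected-substitution-score columns (column score `f1ᵀ S f2`, gap mass
carrying zero score).  With two sequences this reduces exactly to
pairwise Needleman–Wunsch, which is the tested contract.  No iterative
refinement is attempted.

Codon alignments are obtained only by back-translation of a protein
alignment: each residue becomes its codon, each gap `---`, and a
trailing stop codon is stripped from the CDS first (protein rows carry
no stop symbol).  Every substituted codon is checked against the
residue; this keeps the codon invariants (length and every gap run a
multiple of 3) true by construction.

Strict consensus treats a gap as disagreement — deliberately, so that
consensus-mode primers can never span indel columns.  Intron marks on a
protein alignment sit on the residue whose codon is preceded
(phase 0) or interrupted (phase 1/2) by the intron, i.e. residue
`offset // 3`; when alignment gaps sit exactly at a phase-0 boundary
the mark attaches to the following residue.  On nucleotide/codon
alignments the mark precedes the column of coding position `offset`.

Trimming removes columns whose gap fraction exceeds 0.2 or whose
top-residue frequency among non-gaps is below 0.5 (defaults of this
package; configurable), whole codon triples at a time for codon
alignments, and is idempotent.  Manual column lists are supported.

## Trees

Distances: p-distance, JC69 `d = −¾·ln(1 − 4p/3)` (nucleotide) and
Poisson `d = −ln(1 − p)` (protein), with pairwise deletion by default.
Saturated entries (p ≥ 0.75 under JC69) are flagged and set to +inf;
neighbor joining refuses non-finite input, and bootstrap replicates
with saturated distances are dropped with the support denominator
adjusted.

`nj_tree` is Saitou–Nei NJ with the Q criterion; ties break toward the
smallest index pair in the current working order, so star-like inputs
resolve reproducibly.  Negative branch-length estimates are clamped to
zero and recorded on the tree.  On additive matrices NJ is exact: the
output tree reproduces the generating topology and path lengths to
1e−9, which the acceptance suite checks on random trees.

Bootstrap resamples alignment columns (codon triples for codon
alignments, preserving frame) with an explicit seed; support is the
percentage of replicates containing each internal bipartition of the
point-estimate tree, mapped back onto that tree (no majority-rule
consensus).  Supports are invariant under row reordering because
bipartitions are label sets and the resampling stream depends only on
the seed.

Newick serialization writes branch lengths and supports as internal
node labels; parsing is delegated to dendropy and converted, with
numeric internal labels read back as supports.  Only NJ is implemented;
minimum-evolution and maximum-likelihood engines are out of scope.

## Primer design

Melting temperature: unified nearest-neighbour ΔH/ΔS (SantaLucia 1998)
with terminal A·T / G·C initiation terms and the self-complementarity
entropy correction,

    Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log10([Na+])

with ΔH in kcal/mol, ΔS in cal/(mol·K), total oligo concentration
C_T = 50 nM and monovalent salt 50 mM by default.  The NN table is
anchored at 1 M NaCl; with the 16.6·log10 rescaling a typical 20-mer at
50 mM sits near 50–60 °C, hence the default acceptance window of
50–62 °C (optimum for ranking: 60 °C).  The implementation agrees with
an independent NN summation to well under 0.5 °C.

Dimer propensity is the best local-alignment score of one oligo against
the reverse complement of the other (match +1, mismatch −1, gap −2);
homodimer = self vs self.  Default thresholds: 8 for both homo- and
heterodimers (our defaults; conservative enough to reject palindromic
3'-complementary oligos while keeping most windows).  Hairpins and
3'-ΔG clamps are not modelled.

All three design modes share one pipeline: enumerate windows of
18–27 nt, require every concrete expansion within the Tm window, GC
0.30–0.70 and homodimer bound, pair windows whose 5'-to-5' separation
gives a product of 80–300 nt with mates within 3 °C, reject pairs with
any forward×reverse expansion heterodimer over the bound, and rank by
`1.0·|Tm−60| + 0.5·|GC−0.5| + 0.2·|len−20|` summed over both mates.
The table is truncated to the best `max_pairs` (default 50) after
ranking — a presentation cap, screened lazily in penalty order.

Mode specifics:

* **specific** — one concrete template; an included region restricts
  primers to it, excluded regions forbid overlap.  On failure the
  result carries a counter of which filter eliminated most candidates.
* **consensus** — windows on the strict consensus containing neither
  `N` nor a gap column, so primers match every row verbatim.
  Coordinates are alignment columns; per-row positions via
  `alignment_to_row_coordinate`.
* **degenerate** — per-column IUPAC codes over the observed residues of
  gap-free windows (a gap column has no IUPAC code and disqualifies the
  window); windows over the degeneracy cap (default 64) are dropped;
  the "all expansions in range" rule is applied rather than a mean-Tm
  rule, since each concrete oligo in the tube must work.  Pairs are
  first separated in alignment coordinates, then every returned pair is
  verified by in-silico PCR to yield exactly one in-range product on
  every row under exact matching — both coordinate systems therefore
  hold: filtered in alignment space, verified per sequence.

## In-silico PCR

Binding sites are found by pigeonhole seeding: with mismatch budget k,
the (expanded) primer is split into k+1 non-overlapping exact seeds of
length `⌊L/(k+1)⌋`; any gapless site with ≤ k substitutions must
contain one seed verbatim, so seeding is provably complete for that
class (checked exhaustively against a sliding-window matcher).  Each
candidate window (±2 nt slack) is refined by a small global alignment
with free template end gaps (match +1, mismatch −1, gap −2);
"mismatches" counts substitutions plus gap columns.  The refinement may
prefer a gapped placement overlapping a gapless site when it scores
better, shifting the reported interval by a base or two — the site is
still detected, at no more mismatches.  Sites with gaps are findable
only when one seed survives; that sensitivity limit is inherent to
seeded matching.  By default the primer's 3'-terminal base must match
exactly (polymerase-extension realism; configurable).  Degenerate
primers match if at least one expansion fits the budget; the matching
expansion is reported.

Products are 5'-end to 5'-end inclusive — the standard PCR length
convention.  Besides convergent forward(+)/reverse(−) pairs, the
enumeration reports forward-only and reverse-only products (one primer
binding both strands convergently, e.g. at an inverted repeat).
Specificity: a pair is "specific" for a target iff exactly one in-range
product exists in the screened set and it lies on that target.

## Synthetic fixtures

`simulate_family` evolves one ancestral CDS (default 300 nt, exons
97/140/63 so the two introns have phases 1 and 0) along a recorded
random bifurcating tree over `n_species × n_paralogs` members, applying
uniform per-site substitutions at 0.02 per branch by default.  That
rate keeps within-family protein identity roughly 0.75–0.9, i.e.
families of closely related species — the regime the gathering
defaults (identity ≥ 0.6, coverage ≥ 0.5) are meant for, and the one
the degenerate-design workflow targets.  Mutations that would create an
in-frame stop are resampled, so every CDS/protein pair satisfies the
database translation invariant.  Two conserved windows (33 nt at
offsets 21 and 234) are held invariant family-wide and rejection-
sampled until they contain at least one oligo passing the default
primer filters in the required orientation; their separation puts the
product near 200 nt, inside the default 80–300 bound.  Decoys are
independent random CDSs.  All outputs are byte-reproducible from the
seed.

What the simulator does **not** emulate: indels (so simulated families
align gap-free), codon-level selection, rate heterogeneity across sites
or branches, paralog-specific divergence, assembly artefacts and
sequencing error.  Green tests therefore demonstrate algorithmic
correctness under clean conditions, not robustness to fragmented or
chimeric transcripts.

`plant_primer_template` places exact primer sites (or an inverted
repeat of the forward site) on random backgrounds rejection-sampled to
contain no accidental exact occurrence of either primer on either
strand.

## Problem sizes and determinism

The shipped acceptance computations use 500 random instances per
alignment-kernel oracle (≤15 residues, ≤30-nt windows), 200 additive
6–10-taxon trees, 100 four-member families for codon/intron checks,
20 eight-member families for degenerate design, and 100 random 200-nt
templates for PCR completeness — sizes at which the independent oracles
(memoized brute-force DP, exhaustive sliding windows, set-logic
replays) are themselves fast and obviously correct.  Every stochastic
step takes an explicit seed; the CLI refuses to bootstrap without one.

## Known limitations

* E-value constants are ungapped approximations; do not compare them
  with BLAST output numerically.
* Progressive alignment has no refinement pass; deep or gappy families
  will align worse than dedicated MSA tools.
* Only NJ trees; supports apply to the point tree, not a consensus.
* Primer thermodynamics ignores divalent cations, dNTPs, hairpins and
  3' stability; thresholds are screening heuristics, not free-energy
  predictions.
* Gapped primer binding sites can be missed when no exact seed
  survives.
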