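# odb — a scriptable orphan-crop sequence browser

Many locally important crops ("orphan crops") have a de-novo assembled
transcriptome but no reference genome and little annotation.  The usual
route to a gene of interest is translational: find the gene in a
well-studied relative (maize, sorghum, sugarcane, rice), locate its
orthologues in the orphan transcriptome by sequence similarity and
phylogeny, then design PCR primers to confirm the transcript in the lab
— and, when the gene was missed by assembly or sequencing depth,
design *degenerate* primers from a cross-species alignment to fish for
it directly.

`odb` packages that whole workflow as a Python library plus a CLI, with
no web service, relational database or external alignment/primer
binaries:

1. **Database** (`odb.seqdb`) — flat-file multi-species store of
   mRNA/CDS/protein FASTA, GFF3 gene structures, TSV annotations
   (descriptions, GO terms, PFAM domains) and OrthoMCL-style homolog
   clusters; text/ID search; single-copy cluster filtering for
   species-tree work.
2. **Similarity search** (`odb.simsearch`) — full Smith–Waterman with
   affine gaps (BLOSUM62 11/1 for protein, +2/−3 5/2 for DNA),
   nucleotide / protein / six-frame translated modes, Karlin–Altschul
   e-values `E = K·m·n·e^(−λS)`, and related-sequence gathering with
   identity / coverage / e-value / per-species-cap filters.
3. **Alignments** (`odb.msa`) — progressive profile alignment on an NJ
   guide tree; codon alignments by back-translating the protein
   alignment (each residue → its codon, each gap → `---`); strict /
   majority / IUPAC consensus; intron-phase overlay from gene models
   (phase = coding offset mod 3); gap/conservation trimming;
   supermatrix concatenation.
4. **Trees** (`odb.phylo`) — p-distance / JC69 / Poisson distances,
   Saitou–Nei neighbor joining, column (or codon-triple) bootstrap with
   supports as percentages, Newick I/O with supports as internal labels.
5. **Primers** (`odb.primerdesign`, `odb.primermatch`) — SantaLucia-1998
   nearest-neighbour melting temperatures
   `Tm = ΔH / (ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log10[Na+]`,
   dimer screening by local alignment against the reverse complement,
   IUPAC degeneracy expansion, three design modes (specific template /
   strict-consensus / degenerate), and in-silico PCR: pigeonhole-seeded
   binding-site search with Needleman–Wunsch refinement, product
   enumeration including single-primer (inverted repeat) products, and
   specificity screening.
6. **Fixtures** (`odb.synthfix`) — a deterministic simulator of
   multi-species gene families with recorded truth (clades, conserved
   windows, exon structure), so everything above is testable offline.

## Worked example

Design degenerate primers for a simulated 8-member family (4 species ×
2 paralogs) and verify them by in-silico PCR against the family plus
two unrelated decoy sequences:

```python
from odb import (FamilySpec, simulate_family, Alignment,
                 design_degenerate, ThermoParams, predict_products)

fam = simulate_family(FamilySpec(seed=42, n_decoys=2))
rows = [(m, fam.members[m]) for m in sorted(fam.members)]
aln = Alignment(rows=rows, kind="nucleotide")
result = design_degenerate(aln, ThermoParams(max_pairs=5))
pair = result.pairs[0]
amps = predict_products(pair.forward.sequence, pair.reverse.sequence,
                        {**fam.members, **fam.decoys},
                        product_min=80, product_max=300, max_mismatches=0)
```

This prints (via the obvious f-strings):

```
members: 8  pairs returned: 5
forward : AGGCCTCTTCATGCGGTAGGTGCTCMT  (degeneracy 2, Tm 57.7-59.2 C)
reverse : CGACTCCCCATCAGSCGWTTKCCGCA  (degeneracy 8, Tm 58.6-61.0 C)
product : 97 nt   penalty 4.425
amplified templates: 8/10 (sp1_g1, sp1_g2, sp2_g1, ..., sp4_g2)
```

The forward primer carries one ambiguity code (`M` = A/C, degeneracy 2),
the reverse three (degeneracy 8); every concrete expansion passed the
melting-temperature, GC and dimer filters.  The pair amplifies exactly
one in-range product on all 8 family members and none on the decoys —
the defining contract of degenerate design here: only pairs verified to
amplify *every* row of the alignment are returned.

The same flow is available from the shell:

```sh
odb synth family --seed 42 --out fix/
odb build --species sp1 --cds fix/sp1.cds.fasta --protein fix/sp1.protein.fasta --out db/
odb blast --db db/ --mode p --query q.faa
odb align --in family.faa --kind protein --out family.aln.fa
odb tree --in family.aln.fa --kind protein --bootstrap 100 --seed 7 --out family.nwk
odb primer degenerate --aln family.aln.fa --tm 50:62 --product 80:300
odb primer-match --forward ACGT... --reverse TGCA... --db db/ --product 60:1500
```

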