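# Methods

This note documents the models, parameter choices, and numerical
conventions behind `lepihox`, and what the synthetic-genome validation
does and does not demonstrate about real assemblies.

## Translated homology scan

Candidate homeobox loci are detected by local alignment of homeodomain
protein queries against all six reading frames of each contig. The scan
is deliberately self-contained (no external aligner binary) so results
are bit-reproducible:

- **Seeding.** Exact amino-acid k-mers (default word size 5) shared
  between a query and a translated frame nominate alignment windows; a
  full affine-gap Smith–Waterman (BLOSUM62; a gap of length k costs
  11 + k) is run only on nominated windows, padded by 12 residues and
  merged when they overlap. `ScanParams(exhaustive=True)` disables
  seeding and aligns every frame in full; at word size 5 a planted domain
  retains an exact 5-mer with overwhelming probability up to at least
  ~20% amino-acid divergence (12 substitutions in 60 residues leave an
  expected maximum conserved run of ~10).
- **Statistics.** Raw scores S convert to bit scores
  S′ = (λS − ln K)/ln 2 with fixed gapped-BLOSUM62 constants λ = 0.267,
  K = 0.041, and E = (Σ contig lengths × query length) · 2^(−S′). The
  first pass keeps hits with E ≤ 1e−5; the flank re-scan (±1,000 bp
  around each locus, clamped at contig ends) relaxes to E ≤ 1e−3 and
  keeps the full-genome search space so E-values stay comparable. The
  constants are fixed rather than fitted; the E-value therefore acts as a
  deterministic rank cutoff whose raw-score equivalent is computable from
  the search space.
- **Overlap filtering.** Hits overlapping by ≥ 1 bp on either strand
  merge transitively into one locus. The *representative* hit (longest
  aligned genomic span; ties by score, then query id) fixes the locus
  interval and translated sequence — the "one sequence per gene, longest
  match" rule. Separately, the locus records its *best-scoring*
  supporting hit, because the longest alignment is occasionally a
  lower-identity cross-family match that escapes end-trimming while the
  true family's alignment loses a mutated terminal residue; family
  reciprocity (below) is judged against the best-scoring query's family.
  Strand is ignored during merging: two-strand overlaps are rare and
  represent a single locus.
- **Coordinates.** 0-based half-open internally and in TSV/BED outputs
  (declared in a header comment); GFF3 output is 1-based closed.

## Reciprocal classification

A locus is ASSIGNED to a family iff (i) the family of its best forward
query equals the family of its best reverse hit — the translated locus
re-aligned against the entire reference panel, best by score with ties
broken by reference id — and (ii) the reverse alignment identity is
strictly greater than 70%, computed over aligned residue columns only
(gap columns are not comparable). Reciprocity is defined at the family
level rather than the sequence level because the panel holds several
species per family. Ties at exactly 70.0% stay divergent. Divergent loci
are exported as protein FASTA with coordinate provenance for external
tree building; the census counts loci as detected, without adjudicating
functional gene vs partial gene vs pseudogene.

Lowering the identity threshold can only promote divergent loci to
ASSIGNED, never change an assigned family (the reverse best hit does not
depend on the threshold); the suite checks this monotonicity.

## Cluster architecture

Cluster membership is family identity plus modal contig (the contig with
most member loci); no distance gating is applied because lepidopteran
Hox clusters legitimately span up to several megabases. For the Hox
cluster the members are the 13 in-cluster Hox-derived families plus
*ro*; *lab* is internal only if it lies between *ro* and *Abd-B*,
otherwise it is reported as an external member and excluded from spans.
The main-cluster span is measured from *Abd-B* to *ro* inclusive of both
gene bodies and is invariant to coordinate shifts and mirror reflection.

Rearrangement detection collapses tandem runs of one family to a block
(keeping the first block if a family still recurs after collapsing),
contracts the canonical order to the families present, and reports
canonical neighbor pairs that are not adjacent in the observed order.
Orientation flips are genes on the minority strand; translocations are
member families found on a non-modal contig (same-contig displacement,
like *lab*, is "external", not translocated). No minimal inversion or
translocation scenario is inferred. The Shx region is strictly the
first-to-last Shx locus interval, regardless of any interleaved *zen*
copies.

## TE density and enrichment

Repeat annotations load from BED or RepeatMasker `.out`; the broad class
is the family-field prefix before `/` (`LINE/CR1` → LINE), anything
outside {LINE, SINE, LTR, DNA} is "other", and elements shorter than
50 bp are dropped at load. Density is fraction of bases covered (merged
union) per 5-kb window; windows tile each region from its own left edge,
and a terminal partial window is kept only when ≥ 2,500 bp wide, with
its actual width as denominator. A count-per-window mode is deliberately
not implemented; fraction-of-bases is the single convention.

Enrichment compares Shx-region windows against the remaining cluster
(the two flanking segments, tiled independently; *lab* never enters,
being external by construction) with a two-sided Wilcoxon rank-sum test:
exact null distribution when the pooled sample is ≤ 20 and tie-free,
otherwise normal approximation with tie and continuity corrections (via
scipy, which is also the reference implementation for this test in the
field). Bonferroni multiplicity is m = 4 — the four TE classes within
one species, matching per-species enriched/not-enriched calls — and an
"enriched" call additionally requires the Shx median to exceed the rest
median (the hypothesis is *increased* density, so a two-sided p is gated
by direction).

## Identity contrasts

Per family, pairwise identities of every focal×background species pair
are compared against every background×background pair (never
focal×focal) with the same rank-sum machinery, two-sided, α = 0.05.
Alignments are taken as input (equal-length, pre-aligned homeodomains);
identity is over columns where both sequences carry a residue. Pair
identities sharing a species are correlated, which mildly inflates the
test's type-I error above nominal; measured on zero-effect synthetic
alignments (5 focal / 10 background, 60 columns) the significance rate
is ≈ 0.055–0.07 — acceptable for a screening contrast but worth
remembering when p-values sit near the threshold.

## Synthetic genomes

The generator's defaults are the study conditions the analyses assume:

- **Hox chromosome.** Genes in the order *ro*, *pb*, ShxA–D, *zen*,
  *Dfd*, *Scr*, *Antp*, *ftz*, *Ubx*, *abd-A*, *Abd-B*; intergenic gaps
  lognormal (median 50 kb, σ = 1.0), giving a main cluster around a
  megabase — the magnitude typical of these genomes; *lab* planted 7 Mb
  beyond *Abd-B*. Tandem copies within one Shx family are spaced by a
  tighter lognormal (median 4 kb, σ = 0.3), emulating tandem arrays.
  An optional variant relocates *ro* between *Abd-B* and *lab*.
- **Other clusters.** The NK cluster (Tlx, 2×Msx, NK4, NK3, Lbx, NK1,
  Hmx, Emx; gaps median 50 kb — a deliberately compacted emulation of
  clusters that reach 2.4–10 Mb in real genomes) and the *hbn*–*Rx*–*otp*
  trio (gaps median 170 kb, σ = 0.25, centering the span near its
  ~350-kb scale; orientations random, as orientation varies in nature)
  on their own contigs.
- **Genes.** Each planted gene is a single-exon 180-bp homeodomain:
  a deterministic family prototype (the Antennapedia-type consensus
  diverged 40% with a seed derived from the family name) is diverged at
  the amino-acid level by the configured fraction — exactly
  round(fraction × 60) substitutions — then reverse-translated with
  synonymous codon choice weighted toward the target GC (default 0.35).
  The matching reference panel carries three species variants per family
  at 4% divergence, emulating a three-insect reference set. Family
  prototypes are pairwise < 65% identical, far outside the within-family
  divergences the generator plants, so classification is well-posed.
- **Repeats.** Per-class landscapes are homogeneous Poisson interval
  processes. Configured coverage c is converted to intensity
  λ = −ln(1 − c) so the *expected merged coverage* equals c, and element
  starts extend one element length left of the region so coverage is
  stationary at the edges. Element lengths are lognormal (median 400 bp,
  σ = 0.7, clipped to [60, 5000]). Default background coverages are
  LINE 0.05, SINE 0.02, LTR 0.02, DNA 0.03, with LINE tripled inside the
  Shx region (multipliers compose on the intensity scale). Optionally,
  one same-orientation LINE/CR1-style element is planted centrally in
  each gap of a tandem Shx array, emulating the interleaved-LINE pattern
  of extreme array expansions. Repeats are annotation-only (they do not
  alter the background sequence): the enrichment analysis consumes
  annotations, and homeodomain scanning is unaffected either way.

Everything is driven by one `numpy` generator seeded from the config, so
identical configs produce byte-identical FASTA/GFF3/BED.

**What the synthetic validation does not show.** Real homeobox genes are
multi-exon (the scan is homeodomain-level and needs no splice model, but
a homeodomain split by an intron would be found as a shorter or split
hit); real reference panels have heterogeneous within-family divergence
rather than a uniform 4%; real repeat landscapes are clustered and
autocorrelated, not Poisson; and real assemblies contain segmental
duplications and assembly artifacts absent here. Passing the synthetic
suite demonstrates the machinery is correct under its stated model, not
that locus counts on real genomes will match any particular published
census.

## Problem sizes and numerical conventions

The test suite and acceptance script size their simulations for a single
CPU: recovery runs use ~2.5-Mb genomes (cluster gaps median 20 kb, *lab*
displaced 1.4 Mb, divergence 10%), copy-number runs use arrays up to 51
copies on ~1.5-Mb contigs, full-scale architecture checks use the
default ~9-Mb chromosome, and the calibrations use 300–1,000 replicates
(enrichment) and 200–1,000 seeds (contrasts). Degenerate inputs are
errors, not silent results: empty reference sets, loci without
translated sequence, regions shorter than half a window, missing span
endpoints, and layouts exceeding a fixed contig length all raise with a
named cause. Tie-breaks are deterministic everywhere (score, then
lexicographic id; modal contig by count, then name), so every stage is
order-independent and re-runnable to identical bytes.
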