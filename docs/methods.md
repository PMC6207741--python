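# Methods

## Data model and coordinates

All features live on the forward strand as 0-based half-open intervals;
GenBank's 1-based inclusive `join()`/`complement()` convention is converted
only at the IO boundary.  Features spanning the origin of a circular record
are normalized by rotating the sequence so that no feature wraps; the
rotation offset is kept on the genome object.  This keeps every downstream
computation (gaps between exons, arm coordinates, GC counting) plain
interval arithmetic.  Introns are the gaps between consecutive exon
intervals of one feature, with ordinals counted 5'→3' in the gene's own
orientation; zero-length gaps (abutting exons) are not introns, and
overlapping exons are rejected as annotation errors.

Intron classes are assigned from length alone: group III in the inclusive
range [73, 119] nt, group II at ≥ 120 nt, `undetermined` below 73 nt.  The
bounds are parameters because the range is an empirical observation for
euglenid plastids, not a classifier with guarantees; sub-73-nt gaps are
more often annotation artefacts than introns, hence a neutral label rather
than an error.

## Inverted-repeat detection

A perfect IR pair corresponds to a maximal run along an anti-diagonal
`c = i + j` of positions satisfying `seq[i] == complement(seq[j])`, with
arms constrained not to overlap (they may abut; the spacer may be empty).
The production finder seeds candidate anti-diagonals with exact k-mer
matches (k = 21) between the sequence and its reverse complement, then
walks each seeded anti-diagonal once to extract maximal runs.  With the
default mismatch tolerance of 0 this is exact for arms ≥ k.  A small
mismatch budget (capped below 5%) is exposed for degraded IRs and extends
runs greedily past isolated mismatches; it is a heuristic and not used by
any default analysis, since the motivating systems show either identical
arms or none.  The default `min_arm` of 1,000 nt reflects that an
rDNA-bearing IR is always multi-kilobase.  The test suite checks the finder
against an independent exhaustive anti-diagonal scan (O(n²) over all
anti-diagonals, vectorized, with an exact blockwise all-match prefilter).

Architecture calls are annotation-aware: quadripartite requires an IR pair
whose both arms contain at least 2 of the 5 operon genes (tolerating
deposits that failed to annotate the short 5S); tandem-operon genomes are
recognized from ≥ 2 same-strand operon clusters (clusters split when a gene
repeats) without a qualifying IR; a single operon cluster is single-copy;
anything else, including genomes with no annotated rRNA, is unresolved.

## Per-genome statistics

Counting conventions reproduce the comparative-table style for euglenid
plastomes: protein-coding genes are distinct gene names (an IR-duplicated
gene counts once, and its introns count once), tRNA/rRNA genes count per
copy (a quadripartite genome lists its operon genes twice).  Average PCG
length spans outermost coordinates, i.e. includes intron space.  G+C is
computed over unambiguous bases only.  Derived ratios round
half-away-from-zero to the printed precision (introns/PCG 2 dp, percentages
1 dp); genomes without PCGs get `None` ratios rather than a division error.

The maturase–intron association uses Spearman's rank correlation with
average ranks for ties, chosen because the relation of interest is
monotone, the cohort is tiny, and intron counts are far from normal.  For
n ≤ 10 the two-sided p-value is computed by exact enumeration of all
permutations of one margin; beyond that the t approximation is used.
Cohorts whose maturase counts are all equal are rejected (the statistic is
undefined on a constant margin).

## Coding identity and homology threshold

Coding identity between two genomes is the length-weighted mean, over
shared gene names, of percent identical columns in a global alignment of
the spliced CDSs (match +1, mismatch −1, gap open −5, gap extend −1).  The
same aligner scores external introns against the reference set in the
twintron scan.  Note a property of this metric that matters for
thresholding: globally aligning two *unrelated* nucleotide sequences under
this scoring already yields ≈ 39–40% identical columns, because the
aligner freely spends cheap gaps to pair up chance matches.  A homology
cutoff of 40% would therefore sit exactly on the noise floor.  The default
`min_identity` for reference matching is 60%: measured on seeded
constructs, 20% substitution gives ≈ 79% identity (clearly homologous),
50% gives ≈ 53% and 80% gives ≈ 40% (both clearly rejected), so 60%
cleanly separates the regimes while staying far from the floor.

## Twintron calls

A site is called per (gene, intron ordinal).  If the gene lacks an intron
at the site the call is `—`; if no reference intron for that gene reaches
the identity threshold the call is `NH` and the intron is not scanned
(motif counts in a non-homologous intron would not be evidence of the same
nested element).  Otherwise `n3` counts 3'-motif matches whose window ends
before the final `terminal_exclusion` nt (default 20) — the external
intron's own 3' motif lives there and would otherwise give every
homologous intron a free `n3 ≥ 1` — and `n5` counts 5'-motif matches at
position p for which some counted 3' motif at p3 implies an internal
intron of `p3 + |motif3| − p ≥ min_internal` nt (default 73, the lower end
of the group III range).  `Y` requires both counts positive; external
introns shorter than `putative_below` (default 88 nt) downgrade to `Y*`.
Motif matching is IUPAC-aware on both sides (a position matches when the
base sets intersect) with a per-pattern mismatch budget; counts are
monotone non-increasing as the budget tightens.

The shipped `data/motifs.yaml` patterns (5' `GTGYG`, 3' `YRNYAG`, one
mismatch each) are illustrative transcriptions of the canonical group II/
III boundary descriptions, not a curated consensus; any real-data study
should supply its own patterns.  All tests use synthetic motifs so that
correctness never depends on the biological strings, and published bracket
numbers are not reproduction targets — they depend on the original,
unpublished motif definitions.  Only the call semantics and the
`Y[n5,n3]` serialization are contractual.

## Character evolution

Dollo parsimony with the root fixed to present models IR evolution: the
quadripartite architecture was inherited from the green-algal donor, and
regaining a lost IR de novo is considered far less likely than repeated
loss.  The minimum-loss reconstruction is computed in one postorder pass:
losses sit on the stems of the maximal clades whose tips are all 0/?
containing at least one observed 0, and this edge set is unique.  Tips
scored `?` (incomplete genomes) are unconstrained: they join a
neighbouring loss for free and never force one.  Fitch minimum change is
computed as a unit-cost Sankoff DP, generalizing to polytomies, with the
root state optionally constrained; reported gain/loss edges for Fitch are
one optimal labeling (ties resolved toward the parent state) — only the
count is unique.  Both models are verified against exhaustive enumeration
over all internal labelings on trees of ≤ 8 leaves.

The packaged Euglenophyta topology fixes the relationships the loss
mapping needs (Eutreptiales sister to Euglenales; Euglenaceae sister to
Phacaceae; Discoplastis branching first within Phacaceae; Lepocinclis and
Phacus sister clades).  The internal arrangement of the Euglenaceae clade
is not fully resolved in the source phylogeny; since every Euglenaceae tip
lacks the IR, any resolution yields the same single loss on the clade's
stem, and the packaged arrangement is one such resolution.  The tree is an
input, not an inference of this package.

## Synthetic genomes

The generator emulates exactly the structures the pipeline measures, under
defaults chosen to mirror a mid-sized euglenid plastome: 60 protein-coding
genes of 2–4 exons (150–600 nt each), Poisson(1.0) introns per gene with
70% group III (length uniform on [73, 119]) and the rest group II (uniform
on [200, 700]), G+C target 29%, maturases mat1+mat2, and a duplicated
rRNA operon as an IR across a 200-nt gene-free spacer (configurable to a
single copy or ≥ 2 tandem same-strand copies).  Planted twintrons place
the 5'/3' motif literals at stated offsets inside a group II external
intron, seat the external intron's own 3' motif inside the terminal
window, and scrub any spurious motif occurrence from the intron so the
planted counts are the ground truth.  Flanking bases at the IR boundaries
are adjusted so the planted arms are exactly maximal, making coordinate
recovery testable to the base.

All randomness derives from one integer seed; per-gene and per-purpose
sub-streams are obtained by stable hashing, so generation is reproducible
to the byte (GenBank output included, with a fixed record date).  What the
generator does not emulate — realistic codon usage, RNA editing,
sequencing error, annotation noise, IR boundary expansion/contraction —
bounds what passing tests show: they demonstrate correctness of the
measurement machinery on clean annotations, not robustness to dirty
real-world deposits.

## Problem sizes and numerical choices

The oracle comparisons run at desk scale by design: 100 sequences of
10–50 kb for the IR finder (the exhaustive oracle is vectorized to make
this cheap), 21 synthetic genomes at full default size for pipeline
recovery, 200 small trees for parsimony enumeration, 100 intron constructs
for the scanner.  Ties in reference matching break to the longest
reference then lexically smallest id; Spearman uses average ranks;
rounding is half-away-from-zero everywhere a printed-table convention is
reproduced.

## Known limitations

- The IR finder's mismatch-tolerant mode is greedy and does not guarantee
  maximality under its budget; only the exact mode (the default) is
  oracle-verified.
- Gene identity is name-based (with a small synonym table, e.g.
  ycf13 → mat1); deposits with inconsistent naming need a user-supplied
  synonym map.
- Whole-genome (non-coding-inclusive) identity is out of scope; the coding
  identity value depends on the documented scoring and is not claimed to
  match any particular published pipeline.
- Architecture calls trust the annotation for operon membership; a genome
  with an unannotated operon copy will be called by what its feature table
  shows.
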