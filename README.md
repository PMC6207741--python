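# plastocompare

Comparative analysis of euglenid plastid (chloroplast) genomes.

Photosynthetic euglenids (Euglenophyta) carry secondary plastids of green
algal origin whose genomes are remarkably dynamic: the canonical
quadripartite architecture — two identical inverted-repeat (IR) arms
carrying the rRNA operon (16S, trnI, trnA, 23S, 5S), separated by
single-copy regions — has been lost repeatedly; group II self-splicing
introns have proliferated and degenerated into euglenid-specific "group
III" introns of only 73–119 nt; introns nest inside other introns
(twintrons); and intron-encoded maturases (mat1/ycf13, mat2, mat5) appear
and disappear along with the intron load they are thought to sustain.

`plastocompare` is a library for analysing annotated plastomes in this
setting, aimed at researchers in organelle comparative genomics.  It:

- reads/writes GenBank flat files into a normalized 0-based interval model,
  extracting introns from `join()` annotations and classifying them as
  group II (≥120 nt), group III (73–119 nt) or undetermined;
- detects inverted repeats by seed-and-extend over anti-diagonals and calls
  the architecture (quadripartite / single-copy / tandem rRNA operons /
  unresolved) by checking operon content of the arms;
- computes the per-genome characteristics row (size, G+C, PCG counts and
  lengths with intron space, intron load), the maturase inventory, and the
  Spearman rank association between maturase and intron counts (exact
  permutation p-value for small cohorts);
- measures coding-space percent identity between strains via global CDS
  alignments, and decomposes two signed gene orders into maximal collinear
  blocks (direct or inverted);
- screens homologous external introns for nested group III introns using
  IUPAC motif patterns, producing table-style calls `Y[n5,n3]`, `Y*`, `N`,
  `NH`, `—`;
- counts minimum character losses on a rooted species tree under Dollo
  parsimony (single gain at the root, irreversible losses — the natural
  model for IR evolution) and minimum changes under Fitch parsimony, with
  `?` tips unconstrained;
- generates fully annotated synthetic plastomes with ground-truth
  manifests, so every stage is testable without downloads.

## The models in brief

**Dollo loss counting.**  For a binary character with the root fixed to
present, the minimum number of irreversible 1→0 transitions equals the
number of maximal clades whose tips are all absent (or unknown) and contain
at least one observed absence; the loss edges are those clades' stems and
are unique.  Fitch minimum change is computed as a unit-cost Sankoff
dynamic program (handles polytomies and unknown tips uniformly) and always
satisfies `fitch ≤ dollo`.

**Twintron scan.**  Within an external intron homologous to a reference
twintron-bearing intron (global-alignment identity ≥ 60%), `n3` counts 3'
group III motifs strictly internal to the intron (the final 20 nt hold the
external intron's own 3' motif and are excluded) and `n5` counts 5'
insertion-site motifs lying far enough upstream of a counted 3' motif to
accommodate an internal intron of ≥ 73 nt.  `Y` requires `n5 ≥ 1` and
`n3 ≥ 1`; external introns under 88 nt are flagged putative (`Y*`).

## Worked example

```python
from plastocompare import count_losses
from plastocompare.datasets import euglenophyta_tree, ir_character

rep = count_losses(euglenophyta_tree(), ir_character(),
                   model="dollo", root_state="1")
print(rep.min_changes, rep.loss_edges)
```

prints

```
3 ['Euglenaceae', 'Eutreptia_viridis', 'Phacus']
```

— assuming the ancestral plastome was quadripartite, the IR was lost three
times across the Euglenophyta: on the Eutreptia lineage, on the stem of the
Phacus clade, and on the stem of the Euglenaceae.  `examples/` contains one
short script per capability (statistics, IR detection, twintron scanning,
loss mapping, synteny/identity), each printing the numbers it computes and
what they mean.

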