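"""Per-genome feature statistics, maturase inventory, coding identity and
gene-order collinear blocks.

Counting conventions follow the comparative-table style used for euglenid
plastomes: protein-coding genes (PCGs) are counted as distinct gene names
(an IR-duplicated gene counts once), whereas tRNA and rRNA genes are counted
per copy (a quadripartite genome therefore lists 6 rRNAs, a single-IR genome
3).  Average PCG length includes intron space (outermost end - outermost
start).  Ratios are rounded half-away-from-zero to the table's printed
precision: introns/PCG to 2 dp, percentages to 1 dp.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import Seq
from scipy import stats as sstats

from .ir_architecture import classify_architecture, find_inverted_repeats
from .model import (ArchitectureCall, ArchitectureClass, FeatureKind,
                    MaturaseInventory, Plastome, StatsRow)
from .plastome_io import extract_introns, resolve_gene_name

MATURASE_GENES = ("mat1", "mat2", "mat5")


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def derived_ratios(n_introns: int, n_pcg: int,
                   n_pcg_with_introns: int) -> tuple[Optional[float], Optional[float]]:
    """(introns per PCG to 2 dp, % of PCGs with introns to 1 dp).

    Returns (None, None) when there are no PCGs rather than dividing by zero.
    """
    if n_pcg == 0:
        return None, None
    return (round_half_away(n_introns / n_pcg, 2),
            round_half_away(100.0 * n_pcg_with_introns / n_pcg, 1))


def gc_percent(seq: str) -> float:
    """GC as 100*(G+C)/(A+C+G+T), ambiguity codes excluded, 1 dp."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return round_half_away(100.0 * (counts["G"] + counts["C"]) / denom, 1)


def compute_stats_row(p: Plastome, taxon: str | None = None,
                      arch: ArchitectureCall | None = None) -> StatsRow:
    """The physical-characteristics row for one annotated genome.

    When ``arch`` is omitted the IR copy number is derived by running the IR
    finder on the sequence.  Introns are counted once per distinct PCG (so an
    IR-duplicated gene does not double its introns) and per copy for
    tRNA/rRNA hosts, matching the PCG/RNA counting conventions above.
    """
    cds = [f for f in p.features if f.kind is FeatureKind.CDS]
    first_of: dict[str, object] = {}
    for f in cds:
        first_of.setdefault(f.gene, f)
    n_pcg = len(first_of)
    avg_len = (round_half_away(
        sum(f.span_length for f in first_of.values()) / n_pcg, 1)
        if n_pcg else None)

    introns = extract_introns(p)
    seen_cds_genes: set[str] = set()
    n_introns = 0
    genes_with_introns: set[str] = set()
    per_gene_counts: dict[str, int] = {}
    for f in cds:
        if f.gene in seen_cds_genes:
            continue
        seen_cds_genes.add(f.gene)
        k = len([None for (_, e0), (s1, _) in zip(f.intervals, f.intervals[1:])
                 if s1 > e0])
        per_gene_counts[f.gene] = k
        if k:
            genes_with_introns.add(f.gene)
        n_introns += k
    n_introns += sum(1 for r in introns if r.host_kind is not FeatureKind.CDS)

    if arch is None:
        arch = classify_architecture(p, find_inverted_repeats(p.seq))
    n_ir = 2 if arch.klass is ArchitectureClass.QUADRIPARTITE else 1

    ipp, pct = derived_ratios(n_introns, n_pcg, len(genes_with_introns))
    return StatsRow(
        taxon=taxon or p.id, size_bp=len(p.seq),
        size_is_lower_bound=not p.is_complete, n_ir_copies=n_ir,
        gc_percent=gc_percent(p.seq), n_pcg=n_pcg, avg_pcg_len=avg_len,
        n_trna=len(p.features_of_kind(FeatureKind.TRNA)),
        n_rrna=len(p.features_of_kind(FeatureKind.RRNA)),
        n_introns=n_introns, introns_per_pcg=ipp,
        n_pcg_with_introns=len(genes_with_introns), pct_pcg_with_introns=pct)


def stats_table(genomes: Iterable[tuple[str, Plastome]]):
    """Table-style DataFrame of StatsRows, one genome per row."""
    import pandas as pd

    rows = [compute_stats_row(p, taxon) for taxon, p in genomes]
    return pd.DataFrame([vars(r) for r in rows])


def maturase_inventory(p: Plastome, taxon: str | None = None,
                       synonyms: dict[str, str] | None = None) -> MaturaseInventory:
    """Which of mat1/mat2/mat5 the genome encodes.

    Matches resolved gene names of CDS features (free-standing or
    intron-encoded ORFs, which deposits annotate as CDS as well, e.g. ycf13
    inside the ancestral psbC intron) and 'product' qualifier tokens.
    """
    present: set[str] = set()
    for f in p.features:
        if f.kind is not FeatureKind.CDS:
            continue
        name = resolve_gene_name(f.gene, synonyms).lower()
        if name in MATURASE_GENES:
            present.add(name)
        product = f.qualifiers.get("product", "").lower()
        for tok in product.replace(",", " ").split():
            tok = resolve_gene_name(tok, synonyms).lower()
            if tok in MATURASE_GENES:
                present.add(tok)
    return MaturaseInventory(taxon=taxon or p.id, present=frozenset(present))


def maturase_intron_association(
        rows: Sequence[tuple[int, int]]) -> tuple[float, float]:
    """Spearman rank correlation between maturase count and intron count.

    Average ranks handle ties; the two-sided p-value is computed by exact
    permutation when n <= 10 and by the t approximation otherwise.  Raises
    on fewer than 3 rows or when every maturase count is equal (the
    correlation is undefined on a constant margin).
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 rows")
    x = np.asarray([r[0] for r in rows], dtype=float)
    y = np.asarray([r[1] for r in rows], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("maturase counts are all equal; correlation undefined")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    n = len(rows)
    if n <= 10:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
        obs = abs(float(cx @ cy))
        count = total = 0
        batch: list[tuple[int, ...]] = []

        def flush(batch):
            nonlocal count, total
            if not batch:
                return
            perm = np.asarray(batch)
            stat = np.abs(cy[perm] @ cx)
            count += int(np.sum(stat >= obs - 1e-9))
            total += len(batch)

        for perm in itertools.permutations(range(n)):
            batch.append(perm)
            if len(batch) == 200_000:
                flush(batch)
                batch = []
        flush(batch)
        p = count / total
    else:
        p = float(sstats.spearmanr(x, y).pvalue)
    return rho, p


def _spliced_cds(p: Plastome, gene: str) -> str | None:
    for f in p.features:
        if f.kind is FeatureKind.CDS and f.gene == gene:
            s = "".join(p.seq[a:b] for a, b in f.intervals)
            return s if f.strand == 1 else str(Seq(s).reverse_complement())
    return None


def _make_aligner(match: float = 1, mismatch: float = -1,
                  gap_open: float = -5, gap_extend: float = -1) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def alignment_identity(s1: str, s2: str,
                       aligner: Align.PairwiseAligner | None = None
                       ) -> tuple[float, int]:
    """(% identical columns, alignment columns) of one global alignment."""
    al = aligner or _make_aligner()
    aln = al.align(s1, s2)[0]
    c = aln.counts()
    cols = c.gaps + c.identities + c.mismatches
    return 100.0 * c.identities / cols, cols


def coding_identity(a: Plastome, b: Plastome, **scoring) -> float:
    """Length-weighted mean % identity over shared genes' spliced CDSs (1 dp).

    Each shared gene is globally aligned (match +1, mismatch -1, gap open -5,
    extend -1 by default) and identity is identical columns over alignment
    columns, weighted by alignment columns across genes.
    """
    genes_a = {f.gene for f in a.features if f.kind is FeatureKind.CDS}
    genes_b = {f.gene for f in b.features if f.kind is FeatureKind.CDS}
    shared = sorted(genes_a & genes_b)
    if not shared:
        raise ValueError("genomes share no CDS gene names")
    al = _make_aligner(**scoring)
    wsum = w = 0.0
    for g in shared:
        ident, cols = alignment_identity(_spliced_cds(a, g), _spliced_cds(b, g), al)
        wsum += ident * cols
        w += cols
    return round_half_away(wsum / w, 1)


SignedGene = tuple[str, int]  # (name, +1/-1)


@dataclass
class CollinearBlock:
    genes: list[SignedGene]  # in orderA's orientation
    orientation: int  # +1 same in both orders, -1 inverted in B


def collinear_blocks(orderA: Sequence[SignedGene],
                     orderB: Sequence[SignedGene]) -> list[CollinearBlock]:
    """Maximal runs shared by two signed gene orders.

    A block is a maximal run contiguous in both orders that is identical
    either directly (same genes, same signs, same direction) or under
    simultaneous reversal and sign flip (an inversion).  Genes private to one
    order break contiguity; every shared gene lands in exactly one block.
    """
    for order in (orderA, orderB):
        names = [g for g, _ in order]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names in an order")
    posB = {g: i for i, (g, _) in enumerate(orderB)}
    signB = {g: s for g, s in orderB}
    shared = set(posB) & {g for g, _ in orderA}

    blocks: list[CollinearBlock] = []
    i = 0
    while i < len(orderA):
        g, s = orderA[i]
        if g not in shared:
            i += 1
            continue
        # direction in B implied by the sign relation of the anchor gene
        direction = 1 if signB[g] == s else -1
        run = [(g, s)]
        j = i + 1
        while j < len(orderA):
            h, t = orderA[j]
            if h not in shared:
                break
            ok_dir = 1 if signB[h] == t else -1
            if ok_dir != direction or posB[h] != posB[run[-1][0]] + direction:
                break
            run.append((h, t))
            j += 1
        blocks.append(CollinearBlock(genes=run, orientation=direction))
        i = j
    return blocks
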