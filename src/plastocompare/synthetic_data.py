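"""Synthetic annotated plastomes with ground-truth manifests.

The generator emulates the genome properties the rest of the package
analyses: a 5-gene rRNA operon (16S, trnI, trnA, 23S, 5S) present once,
duplicated as an inverted repeat across a short non-coding spacer, or
tandemly repeated on one strand; multi-exon protein-coding genes carrying
group II (200-700 nt) and group III (73-119 nt) introns at a Poisson rate
per gene; optional maturase genes; and planted twintrons — external introns
carrying a 5' insertion-site motif and a 3' group III motif at configured
offsets, with the external intron's own 3' motif seated in the terminal
window the scanner excludes.  Every construct is recorded in a
:class:`TruthManifest` so pipeline outputs can be compared field-for-field.

Defaults mirror a mid-sized euglenid plastome: 60 protein-coding genes, one
intron per gene on average with ~70% group III, GC near 29%, a
quadripartite arrangement with a short gene-free spacer between the arms.

All randomness flows from one integer seed; per-purpose sub-streams are
derived by stable hashing of (genome id, purpose), so regenerating with the
same spec is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .character_evolution import _node_id
from .intron_stats import derived_ratios, round_half_away
from .ir_architecture import revcomp
from .model import (ArchitectureClass, BinaryCharacter, Feature, FeatureKind,
                    IntronRecord, IRPair, MaturaseInventory, MotifPattern,
                    Plastome, ReferenceIntron, StatsRow, TwintronCall,
                    TwintronCode)
from .plastome_io import classify_intron_group
from .twintron import TwintronConfig

BASES = np.array(list("ACGT"))

DEFAULT_GENE_POOL = (
    "psbA psbB psbC psbD psbE psbF psbH psbI psbJ psbK psbL psbN psbT "
    "psaA psaB psaC psaI psaJ psaM atpA atpB atpE atpF atpH atpI "
    "petA petB petD petG rbcL rpoA rpoB rpoC1 rpoC2 "
    "rps2 rps3 rps4 rps7 rps8 rps9 rps11 rps12 rps14 rps18 rps19 "
    "rpl2 rpl5 rpl12 rpl14 rpl16 rpl20 rpl22 rpl23 rpl32 rpl36 "
    "ycf4 ycf12 tufA clpP ccsA cemA chlB chlL chlN roaA"
).split()

_OPERON_PLAN = (  # (gene, kind, length)
    ("rrn16", FeatureKind.RRNA, 1500),
    ("trnI", FeatureKind.TRNA, 75),
    ("trnA", FeatureKind.TRNA, 75),
    ("rrn23", FeatureKind.RRNA, 2900),
    ("rrn5", FeatureKind.RRNA, 120),
)
_OPERON_SPACER = 50


class SynthSpecError(ValueError):
    pass


@dataclass(frozen=True)
class TwintronPlant:
    gene: str
    ordinal: int
    motif5_offset: int
    motif3_offset: int


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    genome_id: str = "synth1"
    n_pcg: int = 60
    gene_name_pool: tuple[str, ...] = tuple(DEFAULT_GENE_POOL)
    intron_rate: float = 1.0
    group3_fraction: float = 0.7
    ir_copies: int = 2
    tandem_copies: int = 1
    spacer_len: int = 200
    twintron_plants: tuple[TwintronPlant, ...] = ()
    maturases: tuple[str, ...] = ("mat1", "mat2")
    gc_target: float = 0.29
    motif5: str = "ATGGCGTT"
    motif3: str = "TTCGACGA"
    min_internal: int = 73
    putative_below: int = 88
    terminal_exclusion: int = 20
    ref_divergence: float = 0.0
    intergenic_len: int = 120
    is_circular: bool = True

    def twintron_config(self) -> TwintronConfig:
        return TwintronConfig(
            motif5=MotifPattern(self.motif5, 0),
            motif3=MotifPattern(self.motif3, 0),
            min_internal=self.min_internal,
            putative_below=self.putative_below,
            terminal_exclusion=self.terminal_exclusion)

    def validate(self) -> None:
        if self.ir_copies not in (1, 2):
            raise SynthSpecError("ir_copies must be 1 or 2")
        if self.tandem_copies < 1:
            raise SynthSpecError("tandem_copies must be >= 1")
        if self.ir_copies == 2 and self.tandem_copies > 1:
            raise SynthSpecError("an IR and tandem operon copies are exclusive")
        if not (0.0 <= self.gc_target <= 1.0):
            raise SynthSpecError("gc_target must be a fraction")
        if self.n_pcg > len(self.gene_name_pool):
            raise SynthSpecError("gene_name_pool smaller than n_pcg")
        if self.twintron_plants and self.intron_rate == 0:
            raise SynthSpecError("twintron plant requested in an intronless genome")
        chosen = set(self.gene_name_pool[:self.n_pcg])
        for pl in self.twintron_plants:
            if pl.gene not in chosen:
                raise SynthSpecError(f"twintron plant in absent gene {pl.gene!r}")
            if pl.ordinal < 1:
                raise SynthSpecError("plant ordinal is 1-based")
            implied = pl.motif3_offset + len(self.motif3) - pl.motif5_offset
            if not (0 <= pl.motif5_offset < pl.motif3_offset):
                raise SynthSpecError("motif5 offset must precede motif3 offset")
            if implied < self.min_internal:
                raise SynthSpecError(
                    f"plant implies internal intron of {implied} nt "
                    f"< min_internal {self.min_internal}")


@dataclass
class TruthManifest:
    genome_id: str
    stats: StatsRow
    architecture: ArchitectureClass
    ir: Optional[IRPair]
    introns: list[IntronRecord]
    twintron_calls: list[TwintronCall]
    maturases: MaturaseInventory
    external_introns: dict[str, str]  # "gene.iN" -> sequence (gene orientation)

    def to_json_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, (ArchitectureClass, FeatureKind, TwintronCode)):
                return obj.value
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return {k: enc(v) for k, v in vars(self).items()}


def _rng(seed: int, *tags: str) -> np.random.Generator:
    h = zlib.crc32("/".join(tags).encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, h])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def _literal_hits(seq: str, motif: str) -> list[int]:
    return [i for i in range(len(seq) - len(motif) + 1)
            if seq[i:i + len(motif)] == motif]


def _scrub(seq: str, motifs: list[str], keep: list[tuple[int, int]],
           rng: np.random.Generator) -> str:
    """Mutate spurious motif occurrences away, leaving planted windows intact."""
    s = list(seq)
    protected = set()
    for a, b in keep:
        protected.update(range(a, b))
    for _ in range(200):
        dirty = False
        for motif in motifs:
            for pos in _literal_hits("".join(s), motif):
                span = range(pos, pos + len(motif))
                if all((pos, pos + len(motif)) != (a, b) for a, b in keep) and \
                        not set(span) <= protected:
                    editable = [i for i in span if i not in protected]
                    i = editable[rng.integers(len(editable))]
                    choices = [b for b in "ACGT" if b != s[i]]
                    s[i] = choices[rng.integers(3)]
                    dirty = True
        if not dirty:
            return "".join(s)
    raise RuntimeError("motif scrubbing did not converge")


def _build_gene(spec: SynthSpec, gene: str, rng: np.random.Generator,
                plants: dict[int, TwintronPlant]
                ) -> tuple[str, list[tuple[int, int]], list[tuple[int, int, int]], dict[int, str]]:
    """One gene in its own 5'->3' orientation.

    Returns (sequence, exon intervals, intron (ordinal, start, end) triples,
    {ordinal: external intron seq} for planted twintrons) — all in gene-local
    coordinates.
    """
    n_introns = int(rng.poisson(spec.intron_rate))
    if plants:
        n_introns = max(n_introns, max(plants))
    exon_lens = [int(rng.integers(150, 601)) for _ in range(n_introns + 1)]
    m5, m3 = spec.motif5, spec.motif3

    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int, int]] = []
    planted_seqs: dict[int, str] = {}
    pos = 0
    for idx, elen in enumerate(exon_lens):
        parts.append(_random_seq(rng, elen, spec.gc_target))
        exons.append((pos, pos + elen))
        pos += elen
        if idx >= n_introns:
            break
        ordinal = idx + 1
        plant = plants.get(ordinal)
        if plant is not None:
            need = plant.motif3_offset + len(m3) + spec.terminal_exclusion + 4
            ilen = max(int(rng.integers(200, 701)), need)
            iseq = list(_random_seq(rng, ilen, spec.gc_target))
            iseq[plant.motif5_offset:plant.motif5_offset + len(m5)] = m5
            iseq[plant.motif3_offset:plant.motif3_offset + len(m3)] = m3
            # the external intron's own 3' motif sits in the excluded window
            own3 = ilen - len(m3) - 3
            iseq[own3:own3 + len(m3)] = m3
            keep = [(plant.motif5_offset, plant.motif5_offset + len(m5)),
                    (plant.motif3_offset, plant.motif3_offset + len(m3)),
                    (own3, own3 + len(m3))]
            cleaned = _scrub("".join(iseq), [m5, m3], keep, rng)
            planted_seqs[ordinal] = cleaned
            parts.append(cleaned)
            introns.append((ordinal, pos, pos + ilen))
            pos += ilen
        else:
            if rng.random() < spec.group3_fraction:
                ilen = int(rng.integers(73, 120))
            else:
                ilen = int(rng.integers(200, 701))
            parts.append(_random_seq(rng, ilen, spec.gc_target))
            introns.append((ordinal, pos, pos + ilen))
            pos += ilen
    return "".join(parts), exons, introns, planted_seqs


def _operon_block(rng: np.random.Generator, gc: float
                  ) -> tuple[str, list[tuple[str, FeatureKind, int, int]]]:
    parts: list[str] = []
    feats: list[tuple[str, FeatureKind, int, int]] = []
    pos = 0
    for i, (gene, kind, length) in enumerate(_OPERON_PLAN):
        if i:
            parts.append(_random_seq(rng, _OPERON_SPACER, gc))
            pos += _OPERON_SPACER
        parts.append(_random_seq(rng, length, gc))
        feats.append((gene, kind, pos, pos + length))
        pos += length
    return "".join(parts), feats


_COMP_CH = {"A": "T", "C": "G", "G": "C", "T": "A"}


def generate_plastome(spec: SynthSpec) -> tuple[Plastome, TruthManifest]:
    """Deterministically build one annotated genome plus its truth manifest."""
    spec.validate()
    gid = spec.genome_id
    chosen = list(spec.gene_name_pool[:spec.n_pcg])
    plants_by_gene: dict[str, dict[int, TwintronPlant]] = {}
    for pl in spec.twintron_plants:
        plants_by_gene.setdefault(pl.gene, {})[pl.ordinal] = pl

    segments: list[str] = []
    features: list[Feature] = []
    truth_introns: list[IntronRecord] = []
    external_introns: dict[str, str] = {}
    pcg_span_sum = 0
    n_introns_total = 0
    genes_with_introns = 0
    cursor = 0

    def emit(seq: str) -> int:
        nonlocal cursor
        segments.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    margin_rng = _rng(spec.seed, gid, "margins")
    emit(_random_seq(margin_rng, 300, spec.gc_target))

    # protein-coding genes (maturases appended as intronless CDSs)
    for gene in chosen + list(spec.maturases):
        grng = _rng(spec.seed, gid, "gene", gene)
        if gene in spec.maturases:
            gseq, exons, introns, planted = _random_seq(grng, 900, spec.gc_target), \
                [(0, 900)], [], {}
        else:
            gseq, exons, introns, planted = _build_gene(
                spec, gene, grng, plants_by_gene.get(gene, {}))
        strand = 1 if grng.random() < 0.5 else -1
        L = len(gseq)
        start = emit(gseq if strand == 1 else revcomp(gseq))
        if strand == 1:
            intervals = [(start + s, start + e) for s, e in exons]
        else:
            intervals = [(start + L - e, start + L - s) for s, e in exons]
        features.append(Feature(kind=FeatureKind.CDS, gene=gene, strand=strand,
                                intervals=intervals))
        pcg_span_sum += L
        n_introns_total += len(introns)
        if introns:
            genes_with_introns += 1
        for ordinal, s, e in introns:
            span = ((start + s, start + e) if strand == 1
                    else (start + L - e, start + L - s))
            truth_introns.append(IntronRecord(
                host_gene=gene, host_kind=FeatureKind.CDS, ordinal=ordinal,
                span=span, group=classify_intron_group(e - s)))
        for ordinal, seq_ in planted.items():
            external_introns[f"{gene}.i{ordinal}"] = seq_
        emit(_random_seq(margin_rng, spec.intergenic_len, spec.gc_target))

    # rRNA operon: single copy, inverted repeat, or tandem repeats
    orng = _rng(spec.seed, gid, "operon")
    op_seq, op_feats = _operon_block(orng, spec.gc_target)
    Lop = len(op_seq)
    ir_truth: Optional[IRPair] = None
    a0 = emit(op_seq)
    for gene, kind, s, e in op_feats:
        features.append(Feature(kind=kind, gene=gene, strand=1,
                                intervals=[(a0 + s, a0 + e)]))
    n_operon_copies = 1
    if spec.ir_copies == 2:
        emit(_random_seq(orng, spec.spacer_len, spec.gc_target))
        b0 = emit(revcomp(op_seq))
        for gene, kind, s, e in op_feats:
            features.append(Feature(kind=kind, gene=gene, strand=-1,
                                    intervals=[(b0 + Lop - e, b0 + Lop - s)]))
        ir_truth = IRPair(armA=(a0, a0 + Lop), armB=(b0, b0 + Lop))
        n_operon_copies = 2
    elif spec.tandem_copies > 1:
        for _ in range(spec.tandem_copies - 1):
            emit(_random_seq(orng, 60, spec.gc_target))
            t0 = emit(op_seq)
            for gene, kind, s, e in op_feats:
                features.append(Feature(kind=kind, gene=gene, strand=1,
                                        intervals=[(t0 + s, t0 + e)]))
        n_operon_copies = spec.tandem_copies

    emit(_random_seq(margin_rng, 300, spec.gc_target))
    seq = list("".join(segments))

    if ir_truth is not None:
        # break chance extensions so the planted arms are the maximal pair
        (ia0, ia1), (ib0, ib1) = ir_truth.armA, ir_truth.armB
        if ia0 >= 1 and ib1 < len(seq) and seq[ia0 - 1] == _COMP_CH[seq[ib1]]:
            seq[ib1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[ib1]]
        if ia1 < ib0 and seq[ia1] == _COMP_CH[seq[ib0 - 1]]:
            seq[ib0 - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[ib0 - 1]]
    genome_seq = "".join(seq)

    if spec.ir_copies == 2:
        arch = ArchitectureClass.QUADRIPARTITE
    elif spec.tandem_copies > 1:
        arch = ArchitectureClass.TANDEM_RRN
    else:
        arch = ArchitectureClass.SINGLE_COPY

    n_pcg = len(chosen) + len(spec.maturases)
    counts = {b: genome_seq.count(b) for b in "ACGT"}
    gc = round_half_away(100.0 * (counts["G"] + counts["C"]) /
                         sum(counts.values()), 1)
    ipp, pct = derived_ratios(n_introns_total, n_pcg, genes_with_introns)
    stats = StatsRow(
        taxon=gid, size_bp=len(genome_seq), size_is_lower_bound=False,
        n_ir_copies=2 if spec.ir_copies == 2 else 1, gc_percent=gc,
        n_pcg=n_pcg,
        avg_pcg_len=round_half_away(pcg_span_sum / n_pcg, 1),
        n_trna=2 * n_operon_copies, n_rrna=3 * n_operon_copies,
        n_introns=n_introns_total, introns_per_pcg=ipp,
        n_pcg_with_introns=genes_with_introns, pct_pcg_with_introns=pct)

    calls = []
    for pl in spec.twintron_plants:
        ext = external_introns[f"{pl.gene}.i{pl.ordinal}"]
        code = (TwintronCode.Y_PUTATIVE if len(ext) < spec.putative_below
                else TwintronCode.Y)
        calls.append(TwintronCall(
            taxon=gid, site=(pl.gene, pl.ordinal), code=code, n5=1, n3=1,
            matched_reference=f"ref.{pl.gene}.i{pl.ordinal}"))

    manifest = TruthManifest(
        genome_id=gid, stats=stats, architecture=arch, ir=ir_truth,
        introns=truth_introns, twintron_calls=calls,
        maturases=MaturaseInventory(taxon=gid,
                                    present=frozenset(spec.maturases)),
        external_introns=external_introns)
    plastome = Plastome(id=gid, seq=genome_seq, is_circular=spec.is_circular,
                        is_complete=True, features=features)
    return plastome, manifest


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    s = list(seq)
    hits = np.flatnonzero(rng.random(len(s)) < rate)
    for i in hits:
        s[i] = [b for b in "ACGT" if b != s[i]][rng.integers(3)]
    return "".join(s)


def generate_reference_set(spec: SynthSpec,
                           manifest: TruthManifest) -> list[ReferenceIntron]:
    """Reference introns for every planted twintron site, at the configured
    substitution divergence (0 => identical to the planted external introns)."""
    rng = _rng(spec.seed, spec.genome_id, "refs")
    refs = []
    for key, seq in sorted(manifest.external_introns.items()):
        gene, ord_tag = key.rsplit(".i", 1)
        refs.append(ReferenceIntron(
            id=f"ref.{gene}.i{ord_tag}", gene=gene, ordinal=int(ord_tag),
            seq=_mutate(seq, spec.ref_divergence, rng)))
    return refs


def random_rooted_tree(n_leaves: int, seed: int,
                       prefix: str = "T") -> dendropy.Tree:
    """Uniform random binary rooted topology with labeled leaves."""
    rng = _rng(seed, "tree", str(n_leaves))
    taxa = dendropy.TaxonNamespace([f"{prefix}{i+1}" for i in range(n_leaves)])
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=t)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def simulate_loss_history(tree: dendropy.Tree, loss_rate: float, seed: int,
                          name: str = "trait"
                          ) -> tuple[BinaryCharacter, int, list[str]]:
    """Irreversible loss process from a present root.

    Each edge below a state-1 parent loses the trait with probability
    loss_rate; descendants of a loss stay 0.  Returns the tip character, the
    number of loss events, and the loss-edge ids (child-node ids).
    """
    if not (0.0 <= loss_rate <= 1.0):
        raise ValueError("loss_rate must be a probability")
    rng = _rng(seed, "loss-history")
    state: dict[int, int] = {id(tree.seed_node): 1}
    losses: list[str] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = state[id(node.parent_node)]
        s = parent
        if parent == 1 and rng.random() < loss_rate:
            s = 0
            losses.append(_node_id(node))
        state[id(node)] = s
    tips = {lf.taxon.label: str(state[id(lf)]) for lf in tree.leaf_node_iter()}
    return BinaryCharacter(name=name, states=tips), len(losses), sorted(losses)


def write_synthetic_cohort(specs: list[SynthSpec], outdir: str | os.PathLike
                           ) -> None:
    """GenBank + reference FASTA + truth JSON per spec, under outdir."""
    from .plastome_io import write_fasta, write_genbank

    os.makedirs(outdir, exist_ok=True)
    for spec in specs:
        p, truth = generate_plastome(spec)
        write_genbank(p, os.path.join(outdir, f"{spec.genome_id}.gb"))
        refs = generate_reference_set(spec, truth)
        if refs:
            write_fasta([(r.id, r.seq) for r in refs],
                        os.path.join(outdir, f"{spec.genome_id}.refs.fasta"))
        with open(os.path.join(outdir, f"{spec.genome_id}.truth.json"), "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1)
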