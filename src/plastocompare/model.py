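"""Core data model for annotated plastid genomes.

Coordinates are 0-based half-open on the forward strand throughout; the
GenBank 1-based inclusive convention is converted at the IO boundary only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class FeatureKind(str, enum.Enum):
    CDS = "CDS"
    TRNA = "tRNA"
    RRNA = "rRNA"
    REPEAT_REGION = "repeat_region"
    OTHER = "other"


class IntronGroup(str, enum.Enum):
    II = "II"
    III = "III"
    UNDETERMINED = "undetermined"


@dataclass
class Feature:
    """One annotated feature, possibly multi-exon.

    ``intervals`` are [start, end) pairs on the forward strand, sorted by
    start; for a minus-strand gene the 5'->3' exon order is the reverse of
    this list.  Gaps between consecutive intervals are the gene's introns.
    """

    kind: FeatureKind
    gene: str
    strand: int  # +1 or -1
    intervals: list[tuple[int, int]]
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("feature needs at least one interval")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValueError(f"bad interval [{s}, {e})")
        self.intervals = sorted(self.intervals)
        for (_, e0), (s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exon intervals in {self.gene!r}")
        if self.kind is FeatureKind.CDS and not self.gene:
            raise ValueError("CDS feature requires a gene name")

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def span_length(self) -> int:
        """Outermost extent, intron space included."""
        return self.end - self.start

    def exon_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class Plastome:
    """One annotated plastid genome."""

    id: str
    seq: str
    is_circular: bool = False
    is_complete: bool = True
    features: list[Feature] = field(default_factory=list)
    rotation_offset: int = 0  # applied to un-wrap origin-spanning features

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("plastome id must be non-empty")
        if not self.seq:
            raise ValueError("plastome sequence must be non-empty")
        n = len(self.seq)
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"feature {f.gene!r} ends at {f.end} beyond sequence length {n}"
                )

    def features_of_kind(self, kind: FeatureKind) -> list[Feature]:
        return [f for f in self.features if f.kind is kind]


@dataclass
class IntronRecord:
    """An intron located inside a host gene, 1-based ordinal counted 5'->3'."""

    host_gene: str
    host_kind: FeatureKind
    ordinal: int
    span: tuple[int, int]
    group: IntronGroup

    def __post_init__(self) -> None:
        s, e = self.span
        if e - s < 1:
            raise ValueError(f"intron span [{s}, {e}) is empty")
        if self.ordinal < 1:
            raise ValueError("intron ordinal is 1-based")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class IRPair:
    """A detected inverted-repeat pair: armA precedes armB on the forward strand."""

    armA: tuple[int, int]
    armB: tuple[int, int]
    mismatches: int = 0
    contained_genes: tuple[tuple[str, ...], tuple[str, ...]] = ((), ())

    def __post_init__(self) -> None:
        if self.armA[1] - self.armA[0] != self.armB[1] - self.armB[0]:
            raise ValueError("IR arms must have equal length")
        if self.armA[1] > self.armB[0]:
            raise ValueError("armA must precede armB without overlap")

    @property
    def arm_length(self) -> int:
        return self.armA[1] - self.armA[0]

    @property
    def spacer(self) -> tuple[int, int]:
        return (self.armA[1], self.armB[0])


class ArchitectureClass(str, enum.Enum):
    QUADRIPARTITE = "quadripartite"
    SINGLE_COPY = "single_copy"
    TANDEM_RRN = "tandem_rrn"
    UNRESOLVED = "unresolved"


@dataclass
class ArchitectureCall:
    klass: ArchitectureClass
    ir: Optional[IRPair] = None
    evidence: str = ""


@dataclass
class StatsRow:
    """Per-genome physical-characteristics row (counts, GC, intron load)."""

    taxon: str
    size_bp: int
    size_is_lower_bound: bool
    n_ir_copies: int
    gc_percent: float
    n_pcg: int
    avg_pcg_len: Optional[float]
    n_trna: int
    n_rrna: int
    n_introns: int
    introns_per_pcg: Optional[float]
    n_pcg_with_introns: int
    pct_pcg_with_introns: Optional[float]


@dataclass
class MaturaseInventory:
    taxon: str
    present: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.present)


@dataclass
class MotifPattern:
    """IUPAC degenerate motif with a mismatch budget."""

    iupac: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        from .twintron import IUPAC_SETS  # local import avoids a cycle

        if not self.iupac:
            raise ValueError("motif must be non-empty")
        bad = set(self.iupac.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC symbols in motif: {sorted(bad)}")
        if not (0 <= self.max_mismatches < len(self.iupac)):
            raise ValueError("max_mismatches must be < motif length")
        self.iupac = self.iupac.upper()


class TwintronCode(str, enum.Enum):
    NO_INTRON = "—"
    N = "N"
    NH = "NH"
    Y = "Y"
    Y_PUTATIVE = "Y*"


@dataclass
class TwintronCall:
    taxon: str
    site: tuple[str, int]  # (gene, intron ordinal)
    code: TwintronCode
    n5: int = 0
    n3: int = 0
    matched_reference: Optional[str] = None
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.code in (TwintronCode.Y, TwintronCode.Y_PUTATIVE):
            if self.n5 < 1 or self.n3 < 1:
                raise ValueError("a positive twintron call requires n5>=1 and n3>=1")
        if self.code in (TwintronCode.NO_INTRON, TwintronCode.NH):
            if self.n5 or self.n3:
                raise ValueError(f"{self.code.value} call must have n5=n3=0")
        if self.code is TwintronCode.NH and self.matched_reference is not None:
            raise ValueError("NH call cannot carry a matched reference")


@dataclass
class ReferenceIntron:
    """A twintron-bearing external intron used as the homology reference."""

    id: str
    gene: str
    ordinal: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 50:
            raise ValueError("reference intron shorter than 50 nt")


@dataclass
class BinaryCharacter:
    """Taxon -> {0, 1, ?} presence/absence states ('?' = unknown)."""

    name: str
    states: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.states.values()} - {"0", "1", "?"}
        if bad:
            raise ValueError(f"states must be '0'/'1'/'?', got {sorted(bad)}")


@dataclass
class LossReport:
    character: str
    model: str  # "dollo" | "fitch"
    min_changes: int
    loss_edges: list[str] = field(default_factory=list)
    gain_edges: list[str] = field(default_factory=list)
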