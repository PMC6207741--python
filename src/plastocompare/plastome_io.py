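"""Read/write GenBank, FASTA and TSV, and normalize annotations.

GenBank flat files use 1-based inclusive coordinates, ``join()`` compound
locations and ``complement()`` strands; everything is converted here to the
internal 0-based half-open forward-strand model.  Features that span the
origin of a circular record are un-wrapped by rotating the sequence (the
rotation offset is recorded on the :class:`~plastocompare.model.Plastome`).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import Feature, FeatureKind, IntronRecord, IntronGroup, Plastome

# Intron-class length bounds (nt).  Group III introns are degenerate group II
# derivatives reduced to 73-119 nt in euglenid plastids; anything at or above
# GROUP2_MIN is called group II, shorter than GROUP3_MIN is left undetermined.
GROUP3_MIN = 73
GROUP3_MAX = 119

#: deposit-dialect gene-name synonyms, applied case-insensitively
DEFAULT_SYNONYMS = {"ycf13": "mat1", "matk": "matK"}

_KIND_BY_GB = {
    "CDS": FeatureKind.CDS,
    "tRNA": FeatureKind.TRNA,
    "rRNA": FeatureKind.RRNA,
    "repeat_region": FeatureKind.REPEAT_REGION,
}
_GB_BY_KIND = {v: k for k, v in _KIND_BY_GB.items()}


def resolve_gene_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Map a deposit gene name onto its canonical form, case-insensitively."""
    table = DEFAULT_SYNONYMS if synonyms is None else synonyms
    return table.get(name.lower(), name)


class GenBankParseError(ValueError):
    pass


def _gene_name(f: SeqFeature) -> str:
    for key in ("gene", "product", "label", "note"):
        if key in f.qualifiers:
            return str(f.qualifiers[key][0])
    return ""


def _feature_from_seqfeature(f: SeqFeature) -> Feature:
    kind = _KIND_BY_GB.get(f.type, FeatureKind.OTHER)
    strand = -1 if f.location.strand == -1 else 1
    intervals = [(int(p.start), int(p.end)) for p in f.location.parts]
    quals = {k: str(v[0]) for k, v in f.qualifiers.items()}
    return Feature(kind=kind, gene=_gene_name(f), strand=strand,
                   intervals=intervals, qualifiers=quals)


def _wrap_offset(record: SeqRecord) -> int:
    """Rotation offset that un-wraps the first origin-spanning feature, or 0.

    A feature wraps the origin when, in the join() order as written (Biopython
    reverses part order for minus-strand features), a later part restarts at
    the sequence start after an earlier part ran to the sequence end.
    """
    n = len(record.seq)
    for f in record.features:
        parts = list(f.location.parts)
        if f.location.strand == -1:
            parts = parts[::-1]
        starts = [int(p.start) for p in parts]
        if (len(parts) > 1
                and any(b < a for a, b in zip(starts, starts[1:]))
                and min(int(p.start) for p in parts) == 0
                and max(int(p.end) for p in parts) == n):
            return starts[0]
    return 0


def read_genbank(path: str | os.PathLike) -> Plastome:
    """Parse one annotated GenBank flat file into a :class:`Plastome`."""
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise GenBankParseError(f"{path}: {exc}") from exc
    n = len(record.seq)
    if n == 0:
        raise GenBankParseError(f"{path}: record has no sequence")
    is_circular = record.annotations.get("topology", "linear") == "circular"
    keywords = [k.lower() for k in record.annotations.get("keywords", [])]
    is_complete = not any("partial" in k for k in keywords)

    offset = _wrap_offset(record) if is_circular else 0
    seq = str(record.seq).upper()
    if offset:
        seq = seq[offset:] + seq[:offset]

    features = []
    for f in record.features:
        if f.type in ("source", "gene"):
            continue
        feat = _feature_from_seqfeature(f)
        if offset:
            feat.intervals = sorted(((s - offset) % n, ((e - 1 - offset) % n) + 1)
                                    for s, e in feat.intervals)
        if feat.end > n:
            raise GenBankParseError(
                f"{path}: feature {feat.gene!r} exceeds sequence length {n}")
        features.append(feat)
    return Plastome(id=record.id or record.name, seq=seq,
                    is_circular=is_circular, is_complete=is_complete,
                    features=features, rotation_offset=offset)


def write_genbank(p: Plastome, path: str | os.PathLike) -> None:
    """Serialize a :class:`Plastome` back to a GenBank flat file."""
    record = SeqRecord(Seq(p.seq), id=p.id, name=p.id.split(".")[0][:16],
                       description="plastid genome")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if p.is_circular else "linear"
    record.annotations["date"] = "01-JAN-1980"  # fixed: byte-stable output
    if not p.is_complete:
        record.annotations["keywords"] = ["partial sequence"]
    for f in p.features:
        parts = [FeatureLocation(s, e, strand=f.strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals = {k: [v] for k, v in f.qualifiers.items()}
        if f.gene and "gene" not in quals:
            quals["gene"] = [f.gene]
        record.features.append(SeqFeature(loc, type=_GB_BY_KIND.get(f.kind, "misc_feature"),
                                          qualifiers=quals))
    SeqIO.write(record, path, "genbank")


def classify_intron_group(length: int, g3_min: int = GROUP3_MIN,
                          g3_max: int = GROUP3_MAX) -> IntronGroup:
    """Call the intron class from its length alone.

    Group III iff g3_min <= length <= g3_max (defaults 73/119, inclusive);
    group II iff longer; anything shorter is ``undetermined`` rather than an
    error, since the length rule is a range observed in euglenids, not a
    classifier with guarantees.
    """
    if length < 1:
        raise ValueError(f"intron length must be positive, got {length}")
    if length >= g3_max + 1:
        return IntronGroup.II
    if length >= g3_min:
        return IntronGroup.III
    return IntronGroup.UNDETERMINED


def extract_introns(p: Plastome, g3_min: int = GROUP3_MIN,
                    g3_max: int = GROUP3_MAX) -> list[IntronRecord]:
    """One IntronRecord per gap between consecutive exons of every feature.

    Ordinals count 5'->3' in the gene's own orientation, so for a minus-strand
    gene intron 1 is the gap with the highest forward-strand coordinate.
    """
    records: list[IntronRecord] = []
    for f in p.features:
        if len(f.intervals) < 2:
            continue
        # abutting exons (zero gap) carry no intron; overlap is rejected by Feature
        gaps = [(e0, s1) for (_, e0), (s1, _) in zip(f.intervals, f.intervals[1:])
                if s1 > e0]
        if not gaps:
            continue
        if f.strand == -1:
            gaps = gaps[::-1]
        for ordinal, (s, e) in enumerate(gaps, start=1):
            records.append(IntronRecord(
                host_gene=f.gene, host_kind=f.kind, ordinal=ordinal,
                span=(s, e), group=classify_intron_group(e - s, g3_min, g3_max)))
    return records


def intron_seq(p: Plastome, rec: IntronRecord) -> str:
    """Intron sequence in gene orientation (5'->3')."""
    s, e = rec.span
    seg = p.seq[s:e]
    host = next(f for f in p.features
                if f.gene == rec.host_gene and f.intervals[0][0] <= s < f.intervals[-1][1])
    return seg if host.strand == 1 else str(Seq(seg).reverse_complement())


def introns_to_tsv(records: Iterable[IntronRecord], path: str | os.PathLike) -> None:
    rows = [{"host_gene": r.host_gene, "host_kind": r.host_kind.value,
             "ordinal": r.ordinal, "start": r.span[0], "end": r.span[1],
             "length": r.length, "group": r.group.value} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str] | Sequence[tuple[str, str]],
                path: str | os.PathLike) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, path, "fasta")
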