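"""Twintron scanning: motif matching inside homologous external introns.

A twintron is an intron nested inside another ("external") intron and
excised sequentially.  The scan mirrors the screening logic used for
euglenid plastomes: an external intron is first matched against a reference
set of known twintron-bearing introns (non-homologous introns are reported
NH and not scanned); within homologous introns, candidate internal group III
introns are evidenced by a conserved 3' motif strictly internal to the
external intron (the final ``terminal_exclusion`` nt are excluded so the
external intron's own 3' motif is never counted) and by 5' insertion-site
motifs far enough upstream of a counted 3' motif to fit a minimal group III
intron.  Calls use the table glyphs: ``—`` no intron at the site, ``N`` no
twintron, ``NH`` non-homologous, ``Y[n5,n3]`` potential twintron, ``Y*``
putative (external intron shorter than the putative threshold).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd
import yaml

from .intron_stats import _make_aligner, alignment_identity
from .model import (MotifPattern, Plastome, ReferenceIntron,
                    TwintronCall, TwintronCode)
from .plastome_io import extract_introns, intron_seq, read_fasta

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def iupac_match(base: str, code: str) -> bool:
    """True iff the base sets of the two IUPAC symbols intersect."""
    try:
        return bool(IUPAC_SETS[base.upper()] & IUPAC_SETS[code.upper()])
    except KeyError as exc:
        raise ValueError(f"non-IUPAC symbol {exc.args[0]!r}") from None


def scan_motif(seq: str, m: MotifPattern) -> list[int]:
    """All 0-based start positions matching the pattern, forward strand only.

    A window matches when at most ``m.max_mismatches`` positions fail the
    IUPAC set-intersection test.  Patterns longer than the sequence match
    nowhere.
    """
    seq = seq.upper()
    L = len(m.iupac)
    if L > len(seq):
        return []
    sets = [IUPAC_SETS[c] for c in m.iupac]
    for ch in set(seq):
        if ch not in IUPAC_SETS:
            raise ValueError(f"non-IUPAC symbol {ch!r} in sequence")
    hits = []
    for i in range(len(seq) - L + 1):
        mism = 0
        for j, allowed in enumerate(sets):
            if not (IUPAC_SETS[seq[i + j]] & allowed):
                mism += 1
                if mism > m.max_mismatches:
                    break
        else:
            hits.append(i)
    return hits


NH = "NH"  # sentinel returned when no reference is homologous


def match_reference_intron(query: str, refs: list[ReferenceIntron],
                           min_identity: float = 60.0):
    """Best-matching homologous reference intron, or the NH marker.

    Each reference is globally aligned to the query; the highest-identity
    reference wins if its identity reaches ``min_identity`` percent
    (default 60, safely above the ~40% identity floor that global alignment
    of unrelated sequences produces under the default scoring).  Ties
    break to the longest reference, then lexically smallest id.
    """
    if not refs:
        return NH
    al = _make_aligner()
    scored = [(alignment_identity(query, r.seq, al)[0], r) for r in refs]
    scored.sort(key=lambda t: (-t[0], -len(t[1].seq), t[1].id))
    ident, best = scored[0]
    return best if ident >= min_identity else NH


@dataclass
class TwintronConfig:
    """Motifs and thresholds driving the scan.

    min_internal: smallest internal group III intron (nt) a 5'/3' motif pair
    may imply; putative_below: external introns shorter than this are flagged
    putative (``Y*``); terminal_exclusion: 3'-terminal window excluded from
    internal 3'-motif counting.
    """

    motif5: MotifPattern
    motif3: MotifPattern
    min_internal: int = 73
    putative_below: int = 88
    terminal_exclusion: int = 20

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "TwintronConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            m5 = MotifPattern(d["motif5"]["iupac"],
                              int(d["motif5"].get("max_mismatches", 0)))
            m3 = MotifPattern(d["motif3"]["iupac"],
                              int(d["motif3"].get("max_mismatches", 0)))
        except KeyError as exc:
            raise ValueError(f"motif config missing key: {exc}") from None
        return cls(motif5=m5, motif3=m3,
                   min_internal=int(d.get("min_internal", 73)),
                   putative_below=int(d.get("putative_below", 88)),
                   terminal_exclusion=int(d.get("terminal_exclusion", 20)))


def default_config() -> TwintronConfig:
    """Config shipped with the package (data/motifs.yaml)."""
    from importlib.resources import files

    with (files("plastocompare") / "data" / "motifs.yaml").open() as fh:
        d = yaml.safe_load(fh)
    m5 = MotifPattern(d["motif5"]["iupac"], int(d["motif5"].get("max_mismatches", 0)))
    m3 = MotifPattern(d["motif3"]["iupac"], int(d["motif3"].get("max_mismatches", 0)))
    return TwintronConfig(m5, m3, int(d.get("min_internal", 73)),
                          int(d.get("putative_below", 88)),
                          int(d.get("terminal_exclusion", 20)))


def count_motifs(external_seq: str, cfg: TwintronConfig) -> tuple[int, int]:
    """(n5, n3) motif counts inside one homologous external intron.

    n3 counts 3'-motif matches whose window lies strictly before the final
    ``terminal_exclusion`` nt.  n5 counts 5'-motif matches lying upstream of
    at least one counted 3' motif with an implied internal intron length
    (5' match start to 3' motif end) of at least ``min_internal`` nt.
    """
    if cfg.motif5 is None or cfg.motif3 is None:
        raise ValueError("both motif5 and motif3 must be configured")
    L3 = len(cfg.motif3.iupac)
    limit = len(external_seq) - cfg.terminal_exclusion
    hits3 = [p for p in scan_motif(external_seq, cfg.motif3) if p + L3 <= limit]
    hits5 = [p for p in scan_motif(external_seq, cfg.motif5)
             if any(p3 + L3 - p >= cfg.min_internal for p3 in hits3 if p3 > p)]
    return len(hits5), len(hits3)


def call_twintron(taxon: str, site: tuple[str, int],
                  external_seq: str | None,
                  refs: list[ReferenceIntron], cfg: TwintronConfig,
                  min_identity: float = 60.0) -> TwintronCall:
    """One table cell: the twintron call for (taxon, gene, intron ordinal)."""
    if external_seq is None:
        return TwintronCall(taxon, site, TwintronCode.NO_INTRON,
                            evidence="no intron at site")
    ref = match_reference_intron(external_seq, refs, min_identity)
    if ref is NH:
        return TwintronCall(taxon, site, TwintronCode.NH,
                            evidence="no homologous reference intron")
    n5, n3 = count_motifs(external_seq, cfg)
    if n5 >= 1 and n3 >= 1:
        code = (TwintronCode.Y_PUTATIVE
                if len(external_seq) < cfg.putative_below else TwintronCode.Y)
        return TwintronCall(taxon, site, code, n5=n5, n3=n3,
                            matched_reference=ref.id)
    return TwintronCall(taxon, site, TwintronCode.N, matched_reference=ref.id)


def serialize_call(call: TwintronCall) -> str:
    """Table glyph: '—', 'N', 'NH', 'Y[n5,n3]' or 'Y*[n5,n3]'."""
    if call.code in (TwintronCode.Y, TwintronCode.Y_PUTATIVE):
        return f"{call.code.value}[{call.n5},{call.n3}]"
    return call.code.value


def build_twintron_table(genomes: list[tuple[str, Plastome]],
                         sites: list[tuple[str, int]],
                         refs: list[ReferenceIntron], cfg: TwintronConfig,
                         min_identity: float = 60.0) -> pd.DataFrame:
    """Calls for every (taxon, site), as a taxa x sites DataFrame of
    TwintronCall; use :func:`table_to_glyphs` for the printable form.

    References are filtered to the queried (gene, ordinal is ignored —
    deposits number introns differently per taxon, so homology is decided
    against every reference for the gene).
    """
    matrix: dict[str, dict[str, TwintronCall]] = {}
    for taxon, p in genomes:
        introns = {(r.host_gene, r.ordinal): r for r in extract_introns(p)}
        gene_names = {f.gene for f in p.features}
        row: dict[str, TwintronCall] = {}
        for gene, ordinal in sites:
            key = f"{gene}.i{ordinal}"
            rec = introns.get((gene, ordinal))
            if rec is None:
                note = ("gene absent from genome" if gene not in gene_names
                        else "no intron at site")
                row[key] = TwintronCall(taxon, (gene, ordinal),
                                        TwintronCode.NO_INTRON, evidence=note)
                continue
            seq = intron_seq(p, rec)
            site_refs = [r for r in refs if r.gene == gene]
            row[key] = call_twintron(taxon, (gene, ordinal), seq, site_refs,
                                     cfg, min_identity)
        matrix[taxon] = row
    return pd.DataFrame.from_dict(matrix, orient="index")


def table_to_glyphs(table: pd.DataFrame) -> pd.DataFrame:
    return table.map(serialize_call)


def read_reference_fasta(path: str | os.PathLike) -> list[ReferenceIntron]:
    """References from FASTA with ids '<taxon>.<gene>.i<ordinal>'."""
    refs = []
    for rid, seq in read_fasta(path).items():
        parts = rid.split(".")
        if len(parts) < 3 or not parts[-1].startswith("i"):
            raise ValueError(f"reference id {rid!r} not of form taxon.gene.iN")
        refs.append(ReferenceIntron(id=rid, gene=parts[-2],
                                    ordinal=int(parts[-1][1:]), seq=seq))
    return refs
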