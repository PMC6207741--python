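"""Inverted-repeat detection and plastome architecture classification.

An inverted repeat (IR) pair is two equal-length arms on the forward strand,
armA before armB, with revcomp(armA) ~= armB.  In coordinate terms a perfect
pair satisfies seq[i] == complement(seq[c - i]) for every armA position i,
where c = armA.start + armB.end - 1 is the pair's anti-diagonal; maximal
pairs are non-extendable runs along such anti-diagonals.

Detection is seed-and-extend: exact k-mer matches between the sequence and
its reverse complement seed candidate anti-diagonals, which are then extended
to maximal runs.  With the default mismatch tolerance of 0 this is exact for
arms longer than the seed k-mer.
"""

from __future__ import annotations

from collections import defaultdict

from .model import (ArchitectureCall, ArchitectureClass, Feature, FeatureKind,
                    IRPair, Plastome)

#: rRNA-operon members used to validate IR/tandem architecture calls
OPERON_GENES = ("rrn5", "rrn16", "rrn23", "trnI", "trnA")

_COMP = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def find_inverted_repeats(seq: str, min_arm: int = 1000,
                          max_mismatch_frac: float = 0.0,
                          k: int = 21) -> list[IRPair]:
    """All maximal inverted-repeat pairs with arms >= min_arm.

    Returns pairs sorted by arm length descending (ties by armA start).
    A sequence shorter than 2*min_arm yields an empty list.  With
    max_mismatch_frac > 0 (capped below 0.05) arms are extended greedily
    past isolated mismatches while the overall mismatch fraction stays
    within budget; the default 0 reports perfect repeats only.
    """
    if not (0.0 <= max_mismatch_frac < 0.05):
        raise ValueError("max_mismatch_frac must be in [0, 0.05)")
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_arm:
        return []
    k = min(k, min_arm)
    comp = seq.translate(_COMP)  # comp[j] pairs with seq positions on anti-diagonals

    # seed: k-mer of seq matching revcomp k-mer => seq[a:a+k] == revcomp(seq[b:b+k])
    # <=> seq[a+t] == complement(seq[b+k-1-t]) for all t  => anti-diagonal
    # c = a + b + k - 1 is constant.
    index: dict[str, list[int]] = defaultdict(list)
    for a in range(n - k + 1):
        index[seq[a:a + k]].append(a)
    rc = revcomp(seq)
    diagonals: set[int] = set()
    for p in range(n - k + 1):
        kmer = rc[p:p + k]
        if kmer in index:
            b = n - k - p  # start of the matching window on the forward strand
            for a in index[kmer]:
                c = a + b + k - 1
                if min_arm <= c <= 2 * n - 1 - min_arm:
                    diagonals.add(c)

    pairs: list[IRPair] = []
    seen: set[tuple[int, int, int]] = set()
    for c in sorted(diagonals):
        lo = max(0, c - n + 1)
        hi = (c - 1) // 2
        if hi - lo + 1 < min_arm:
            continue
        i = lo
        while i <= hi:
            if seq[i] != comp[c - i]:
                i += 1
                continue
            j = i
            mism = 0
            best_end = i
            budget = int(max_mismatch_frac * (hi - lo + 1))
            while j <= hi:
                if seq[j] == comp[c - j]:
                    best_end = j
                elif mism + 1 > budget:
                    break
                else:
                    mism += 1
                j += 1
            run_len = best_end - i + 1
            if run_len >= min_arm:
                key = (c, i, best_end)
                if key not in seen:
                    seen.add(key)
                    armA = (i, best_end + 1)
                    armB = (c - best_end, c - i + 1)
                    nm = sum(seq[t] != comp[c - t] for t in range(i, best_end + 1))
                    pairs.append(IRPair(armA=armA, armB=armB, mismatches=nm))
            i = best_end + 1 if best_end >= i else i + 1
    pairs.sort(key=lambda p: (-p.arm_length, p.armA[0]))
    return pairs


def _operon_copies(p: Plastome, max_gap: int = 5000) -> list[tuple[int, int, int, list[str]]]:
    """Cluster annotated rRNA-operon members into operon copies.

    Returns (start, end, strand, genes) per copy: consecutive operon-member
    features on the same strand within max_gap of each other.
    """
    members = [f for f in p.features
               if f.kind in (FeatureKind.RRNA, FeatureKind.TRNA)
               and f.gene in OPERON_GENES]
    members.sort(key=lambda f: f.start)
    copies: list[tuple[int, int, int, list[str]]] = []
    for f in members:
        if (copies and f.strand == copies[-1][2]
                and f.start - copies[-1][1] <= max_gap
                and f.gene not in copies[-1][3]):  # repeated gene: new copy
            s, e, st, genes = copies[-1]
            copies[-1] = (s, max(e, f.end), st, genes + [f.gene])
        else:
            copies.append((f.start, f.end, f.strand, [f.gene]))
    return copies


def _genes_in(p: Plastome, span: tuple[int, int]) -> tuple[str, ...]:
    s, e = span
    return tuple(f.gene for f in p.features if f.start >= s and f.end <= e and f.gene)


def classify_architecture(p: Plastome, pairs: list[IRPair],
                          min_operon_genes: int = 2) -> ArchitectureCall:
    """Call the plastome architecture from detected IR pairs and annotation.

    quadripartite: an IR pair whose both arms hold >= min_operon_genes operon
    members (the threshold of 2 tolerates deposits missing the short 5S);
    tandem_rrn: >= 2 same-strand operon copies and no qualifying IR;
    single_copy: exactly one operon copy; unresolved otherwise.
    """
    rrna = [f for f in p.features if f.kind is FeatureKind.RRNA]
    if not rrna:
        return ArchitectureCall(ArchitectureClass.UNRESOLVED, None,
                                "no rRNA genes annotated")
    for pair in pairs:
        genes_a = _genes_in(p, pair.armA)
        genes_b = _genes_in(p, pair.armB)
        na = len(set(genes_a) & set(OPERON_GENES))
        nb = len(set(genes_b) & set(OPERON_GENES))
        if na >= min_operon_genes and nb >= min_operon_genes:
            ir = IRPair(pair.armA, pair.armB, pair.mismatches, (genes_a, genes_b))
            return ArchitectureCall(
                ArchitectureClass.QUADRIPARTITE, ir,
                f"IR arms {pair.armA}/{pair.armB} carry {na}/{nb} operon genes")
    copies = _operon_copies(p)
    if len(copies) >= 2 and len({st for _, _, st, _ in copies}) == 1:
        return ArchitectureCall(ArchitectureClass.TANDEM_RRN, None,
                                f"{len(copies)} same-strand operon copies, no IR")
    if len(copies) == 1:
        return ArchitectureCall(ArchitectureClass.SINGLE_COPY, None,
                                "single rRNA operon copy")
    return ArchitectureCall(ArchitectureClass.UNRESOLVED, None,
                            f"{len(copies)} operon copies of mixed orientation")
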