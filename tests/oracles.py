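"""Independent brute-force oracles used to cross-check the package.

Each oracle re-derives the quantity from first principles with a different
algorithm (exhaustive scans, exhaustive enumeration) and shares no code with
the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

_ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_force_motif_scan(seq: str, pattern: str, max_mismatches: int) -> list[int]:
    """Sliding-window IUPAC scan checking every window position explicitly."""
    seq, pattern = seq.upper(), pattern.upper()
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        mism = sum(
            1 for a, b in zip(seq[i:i + len(pattern)], pattern)
            if not (set(_ORACLE_IUPAC[a]) & set(_ORACLE_IUPAC[b])))
        if mism <= max_mismatches:
            hits.append(i)
    return hits


def brute_force_inverted_repeats(seq: str, min_arm: int) -> set[tuple]:
    """Exhaustive anti-diagonal scan for maximal perfect inverted repeats.

    Position i pairs with position j = c - i on anti-diagonal c when
    seq[i] == complement(seq[j]); a maximal run of pairings with
    i < j and length >= min_arm is one maximal IR pair.  O(n^2) over all
    anti-diagonals; a blockwise all-True prefilter (exact: any run of
    length >= 2*(min_arm//2) must contain one fully-True aligned block)
    keeps the run extraction to candidate diagonals only.
    """
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    comp = np.zeros(256, np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    carr_rev = comp[arr][::-1].copy()
    n = len(arr)
    B = max(1, min_arm // 2)
    found: set[tuple] = set()
    for c in range(2 * n - 2):
        lo = max(0, c - n + 1)
        hi = (c - 1) // 2
        width = hi - lo + 1
        if width < min_arm:
            continue
        # arr[i] vs comp(arr[c-i]) for i in [lo, hi]
        m = arr[lo:hi + 1] == carr_rev[n - 1 - c + lo: n - c + hi]
        pad = (-len(m)) % B
        blocks = np.concatenate([m, np.zeros(pad, bool)]).reshape(-1, B)
        if not blocks.all(axis=1).any():
            continue
        padded = np.concatenate(([False], m, [False])).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_arm:
                i0, i1 = lo + int(s), lo + int(e)
                found.add(((i0, i1), (c - i1 + 1, c - i0 + 1)))
    return found


def enumerate_min_changes(tree, states: dict[str, str], model: str,
                          root_state: str = "1") -> int:
    """Minimum changes by exhaustive enumeration over all node labelings.

    dollo: root forced to root_state, 0->1 transitions forbidden, count 1->0
    edges.  fitch: any labeling (root constrained unless 'free'), count all
    state-changing edges.  Leaves scored '?' range over both states.
    """
    nodes = list(tree.preorder_node_iter())
    leaves = [nd for nd in nodes if nd.is_leaf()]
    internals = [nd for nd in nodes if not nd.is_leaf()]
    free_leaves = [nd for nd in leaves if states[nd.taxon.label] == "?"]
    best = None
    for internal_assign in itertools.product((0, 1), repeat=len(internals)):
        lab = {id(nd): s for nd, s in zip(internals, internal_assign)}
        root = lab[id(tree.seed_node)]
        if root_state in ("0", "1") and root != int(root_state):
            continue
        for leaf_assign in itertools.product((0, 1), repeat=len(free_leaves)):
            for nd in leaves:
                s = states[nd.taxon.label]
                lab[id(nd)] = (leaf_assign[free_leaves.index(nd)]
                               if s == "?" else int(s))
            changes = gains = 0
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                ps, cs = lab[id(nd.parent_node)], lab[id(nd)]
                if ps != cs:
                    changes += 1
                    if cs == 1:
                        gains += 1
            if model == "dollo" and gains:
                continue
            if best is None or changes < best:
                best = changes
    assert best is not None, "no feasible labeling"
    return best


def brute_force_collinear_blocks(orderA, orderB) -> list[tuple]:
    """All maximal common signed substrings of two signed gene orders.

    Enumerates every contiguous window of orderA, tests whether it occurs in
    orderB either directly or reversed-with-flipped-signs as a contiguous
    window, and keeps the windows not contained in a longer match.  Returned
    as (genes tuple in A orientation, orientation) sorted by A position.
    """
    def windows(order):
        for i in range(len(order)):
            for j in range(i + 1, len(order) + 1):
                yield i, j, tuple(order[i:j])

    b_windows = set()
    for _, _, w in windows(orderB):
        b_windows.add(w)
    matches = []
    for i, j, w in windows(orderA):
        rev = tuple((g, -s) for g, s in reversed(w))
        if w in b_windows:
            matches.append((i, j, w, 1))
        elif rev in b_windows:
            matches.append((i, j, w, -1))
    maximal = [m for m in matches
               if not any(o[0] <= m[0] and m[1] <= o[1] and o is not m
                          and (o[1] - o[0]) > (m[1] - m[0]) for o in matches)]
    # keep left-to-right disjoint cover (maximal runs never overlap for
    # unique gene names)
    maximal.sort(key=lambda m: m[0])
    return [(m[2], m[3]) for m in maximal]
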