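"""Dollo and Fitch parsimony for binary presence/absence characters on a
rooted species tree.

The headline model for inverted-repeat evolution is Dollo parsimony with the
root fixed to "present": the character can be gained once (at or above the
root) and only lost thereafter, reflecting that re-creating an IR de novo in
an IR-less plastome is far less likely than repeated loss.  Under that model
the minimum-loss reconstruction is unique: losses sit on the stem edges of
the maximal clades whose leaves are all absent (or unknown) and that contain
at least one observed absence.  Fitch parsimony (unordered minimum change,
computed as a unit-cost Sankoff DP so polytomies and '?' leaves are handled
uniformly) is provided as a sensitivity check; its change count can never
exceed Dollo's.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

from .model import (ArchitectureCall, ArchitectureClass, BinaryCharacter,
                    LossReport, MaturaseInventory)

INF = float("inf")


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted newick string; polytomies are preserved.

    Raises on duplicate leaf labels or malformed newick.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"newick parse failed: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dups}")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _node_id(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon:
        return node.taxon.label
    if node.label:
        return node.label
    # stable synthetic id: sorted leaf labels under the node
    return "(" + ",".join(sorted(lf.taxon.label for lf in node.leaf_iter())) + ")"


def _check_states(tree: dendropy.Tree, ch: BinaryCharacter) -> None:
    missing = [l for l in leaf_labels(tree) if l not in ch.states]
    if missing:
        raise ValueError(f"character {ch.name!r} lacks states for: {missing}")


def _dollo(tree: dendropy.Tree, ch: BinaryCharacter) -> LossReport:
    # can_zero[node]: every leaf below is '0' or '?'; has_zero: some leaf is '0'
    can_zero: dict[int, bool] = {}
    has_zero: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = ch.states[node.taxon.label]
            can_zero[id(node)] = s in ("0", "?")
            has_zero[id(node)] = s == "0"
        else:
            kids = node.child_nodes()
            can_zero[id(node)] = all(can_zero[id(c)] for c in kids)
            has_zero[id(node)] = any(has_zero[id(c)] for c in kids)

    loss_edges: list[str] = []

    def walk(node: dendropy.Node) -> None:
        for c in node.child_nodes():
            if can_zero[id(c)] and has_zero[id(c)]:
                loss_edges.append(_node_id(c))  # maximal all-absent clade stem
            elif can_zero[id(c)] and not has_zero[id(c)]:
                pass  # only '?' below: stays present at no cost
            else:
                walk(c)

    walk(tree.seed_node)
    return LossReport(character=ch.name, model="dollo",
                      min_changes=len(loss_edges), loss_edges=sorted(loss_edges))


def _sankoff_fitch(tree: dendropy.Tree, ch: BinaryCharacter,
                   root_state: str) -> LossReport:
    cost: dict[int, list[float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = ch.states[node.taxon.label]
            cost[id(node)] = ([0.0, 0.0] if s == "?" else
                              [0.0, INF] if s == "0" else [INF, 0.0])
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = cost[id(child)]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            cost[id(node)] = [c0, c1]

    r0, r1 = cost[id(tree.seed_node)]
    if root_state == "0":
        total, root_assign = r0, 0
    elif root_state == "1":
        total, root_assign = r1, 1
    else:
        total, root_assign = (r0, 0) if r0 <= r1 else (r1, 1)
    if total == INF:
        raise ValueError(f"character {ch.name!r}: no labeling consistent "
                         f"with root state {root_state}")

    gain_edges: list[str] = []
    loss_edges: list[str] = []

    def assign(node: dendropy.Node, state: int) -> None:
        for child in node.child_nodes():
            k0, k1 = cost[id(child)]
            keep = (k0 if state == 0 else k1)
            switch = (k1 if state == 0 else k0) + 1
            child_state = state if keep <= switch else 1 - state  # ties keep parent
            if child_state != state:
                (gain_edges if child_state == 1 else loss_edges).append(_node_id(child))
            if not child.is_leaf():
                assign(child, child_state)

    assign(tree.seed_node, root_assign)
    return LossReport(character=ch.name, model="fitch", min_changes=int(total),
                      loss_edges=sorted(loss_edges), gain_edges=sorted(gain_edges))


def count_losses(tree: dendropy.Tree, ch: BinaryCharacter,
                 model: str = "dollo", root_state: str = "1") -> LossReport:
    """Minimum-change reconstruction of a binary character on a rooted tree.

    model="dollo": gains forbidden below the root; root_state must be "1"
    (a root of "0" with gains forbidden is only feasible for all-absent data
    and is rejected for clarity).  Leaves scored '?' are unconstrained.
    model="fitch": standard minimum unordered change; root_state may be
    "0", "1" or "free".  For Fitch the reported gain/loss edges are one
    optimal labeling (ties resolved toward the parent state); the count is
    the invariant quantity.
    """
    _check_states(tree, ch)
    if model == "dollo":
        if root_state != "1":
            raise ValueError("dollo model requires root_state='1'")
        return _dollo(tree, ch)
    if model == "fitch":
        if root_state not in ("0", "1", "free"):
            raise ValueError("root_state must be '0', '1' or 'free'")
        return _sankoff_fitch(tree, ch, root_state)
    raise ValueError(f"unknown model {model!r}")


def character_from_calls(arch: dict[str, ArchitectureCall],
                         mats: dict[str, MaturaseInventory],
                         maturase_genes: Iterable[str] = ("mat1", "mat2", "mat5"),
                         ) -> list[BinaryCharacter]:
    """Binary characters from architecture calls and maturase inventories.

    The IR character is 1 for quadripartite genomes, '?' for unresolved ones
    (incomplete deposits) and 0 otherwise; one character per maturase gene
    records its presence.  Taxon sets of the two inputs must agree.
    """
    if mats and arch and set(arch) != set(mats):
        off = sorted(set(arch) ^ set(mats))
        raise ValueError(f"taxon sets differ between inputs: {off}")
    chars = []
    if arch:
        ir_states = {}
        for taxon, call in arch.items():
            if call.klass is ArchitectureClass.QUADRIPARTITE:
                ir_states[taxon] = "1"
            elif call.klass is ArchitectureClass.UNRESOLVED:
                ir_states[taxon] = "?"
            else:
                ir_states[taxon] = "0"
        chars.append(BinaryCharacter(name="IR", states=ir_states))
    if mats:
        for gene in maturase_genes:
            chars.append(BinaryCharacter(
                name=gene,
                states={t: "1" if gene in inv.present else "0"
                        for t, inv in mats.items()}))
    return chars
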