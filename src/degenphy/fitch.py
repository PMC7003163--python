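"""Fitch parsimony state-switch counting on rooted binary trees.

The post-order pass assigns each internal node the intersection of its
two children's state sets when that intersection is nonempty, else
their union. The number of union events equals the minimum number of
discrete state changes the tree requires (the Fitch parsimony length) —
for example, the minimum number of aquatic/terrestrial habitat switches
along a phylogeny with tips scored W (water) or L (land).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy


class MultifurcationError(ValueError):
    """An internal node with a child count other than two."""


@dataclass
class _Node:
    label: str | None
    children: list["_Node"] = field(default_factory=list)
    state_set: frozenset[str] | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class StateTree:
    """A rooted binary tree with discrete states at the tips.

    Tips without an entry in ``tip_states`` (or mapped to '?') are
    treated as unknown and receive the full state alphabet during
    reconstruction.
    """

    root: _Node
    tip_states: dict[str, str]

    @property
    def tip_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: _Node) -> None:
            if node.is_leaf:
                out.append(node.label)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(s for s in self.tip_states.values() if s != "?")

    def to_newick(self, with_states: bool = False) -> str:
        """Newick string; ``with_states`` appends node state sets as
        comments (after reconstruction)."""

        def fmt(node: _Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                s = "(" + ",".join(fmt(ch) for ch in node.children) + ")"
            if with_states and node.state_set is not None:
                s += "[&states={" + "".join(sorted(node.state_set)) + "}]"
            return s

        return fmt(self.root) + ";"


def _convert(dnode: dendropy.Node) -> _Node:
    children = dnode.child_nodes()
    if children and len(children) != 2:
        label = dnode.taxon.label if dnode.taxon else (dnode.label or "<unnamed>")
        raise MultifurcationError(
            f"internal node {label!r} has {len(children)} children; "
            "only rooted binary trees are supported"
        )
    label = dnode.taxon.label if dnode.taxon else dnode.label
    return _Node(label=label, children=[_convert(ch) for ch in children])


def parse_newick(text: str, tip_states: dict[str, str] | None = None) -> StateTree:
    """Parse a newick string into a :class:`StateTree`.

    States come either from ``tip_states`` (identifier -> state) or
    from tip-label suffixes of the form ``id=STATE``. Multifurcating
    internal nodes are rejected rather than silently resolved, since
    resolution changes switch counts. A state-table entry without a
    matching tip is an error.
    """
    # quote bare id=STATE tip labels so the newick tokenizer accepts them
    text = re.sub(r"(?<!['\w])([^,():;'\"\s]+=[^,():;'\"\s]+)", r"'\1'", text)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    root = _convert(dtree.seed_node)
    if root.is_leaf:
        raise ValueError("tree has a single node")

    states: dict[str, str] = {}
    labels = []

    def strip_suffix(node: _Node) -> None:
        if node.is_leaf and node.label and "=" in node.label:
            name, _, st = node.label.partition("=")
            node.label = name.strip()
            states[node.label] = st.strip()
        for ch in node.children:
            strip_suffix(ch)

    strip_suffix(root)
    tree = StateTree(root=root, tip_states=states)
    labels = tree.tip_labels
    if any(lbl is None for lbl in labels):
        raise ValueError("every tip must be labeled")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    if tip_states:
        unmatched = set(tip_states) - set(labels)
        if unmatched:
            raise ValueError(f"state-table entries without matching tips: {sorted(unmatched)}")
        tree.tip_states.update(tip_states)
    return tree


def fitch_count(tree: StateTree) -> tuple[int, dict[str, frozenset[str]]]:
    """Fitch post-order reconstruction; returns the union count (the
    minimum number of state switches) and every node's state set.

    Internal nodes are keyed ``node<k>`` in post-order; tips by label.
    Tips with unknown state get the full alphabet.
    """
    alphabet = tree.alphabet
    if not alphabet:
        raise ValueError("no tip states supplied")
    unions = 0
    node_sets: dict[str, frozenset[str]] = {}
    counter = [0]

    def post(node: _Node) -> frozenset[str]:
        nonlocal unions
        if node.is_leaf:
            state = tree.tip_states.get(node.label, "?")
            node.state_set = alphabet if state == "?" else frozenset({state})
            node_sets[node.label] = node.state_set
            return node.state_set
        left, right = (post(ch) for ch in node.children)
        inter = left & right
        if inter:
            node.state_set = inter
        else:
            node.state_set = left | right
            unions += 1
        counter[0] += 1
        node_sets[f"node{counter[0]}"] = node.state_set
        return node.state_set

    post(tree.root)
    return unions, node_sets
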