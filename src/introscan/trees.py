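"""Rooted trees: a light node structure, Newick round-trip, canonical forms.

Every downstream stage (the coalescent simulator, topology weighting, the
quartet-concordance scorer) works on :class:`Node`, a minimal rooted tree.
Newick parsing is delegated to dendropy; serialisation is plain recursion.

Canonical forms are the backbone of topology matching: a rooted binary
leaf-labelled topology is encoded as a nested-parenthesis string in which the
two children of every internal node are sorted lexicographically.  Two trees
have the same canonical form iff they are the same rooted topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "parse_newick",
    "read_newick",
    "write_newick",
    "canonical_form",
    "count_rooted_topologies",
    "enumerate_rooted_topologies",
    "TopologyCatalog",
    "resolve_polytomies",
    "reroot_on_tip",
]


@dataclass
class Node:
    """One node of a rooted tree.

    ``length`` is the length of the edge above the node (``None`` when the
    source had no branch lengths); ``time`` is an optional node age used by
    the coalescent simulator (0 at the tips, increasing toward the root).
    """

    label: str | None = None
    length: float | None = None
    time: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.postorder())

    def copy(self) -> "Node":
        return Node(
            label=self.label,
            length=self.length,
            time=self.time,
            children=[c.copy() for c in self.children],
        )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.children.append(_from_dendropy(child))
    return node


def parse_newick(newick: str) -> Node:
    """Parse a single Newick string into a rooted :class:`Node` tree."""
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    root = _from_dendropy(tree.seed_node)
    labels = root.leaf_labels()
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    return root


def read_newick(path) -> list[Node]:
    """Read one tree per line; blank lines are skipped.

    Unparseable lines (e.g. unbalanced parentheses) raise ``ValueError``
    naming the offending line number.
    """
    trees = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.count("(") != line.count(")"):
                raise ValueError(f"line {lineno}: unbalanced parentheses")
            try:
                trees.append(parse_newick(line))
            except Exception as exc:  # dendropy raises several types
                raise ValueError(f"line {lineno}: cannot parse Newick ({exc})") from exc
    return trees


def write_newick(node: Node, lengths: bool = True) -> str:
    def render(n: Node) -> str:
        if n.is_leaf:
            body = n.label or ""
        else:
            body = "(" + ",".join(render(c) for c in n.children) + ")"
            if n.label:
                body += n.label
        if lengths and n.length is not None:
            body += f":{n.length:g}"
        return body

    return render(node) + ";"


# ---------------------------------------------------------------------------
# Canonical forms and topology enumeration
# ---------------------------------------------------------------------------

NestedTopology = str | tuple  # leaf label, or a pair of NestedTopology


def canonical_nested(topology: NestedTopology) -> str:
    if isinstance(topology, str):
        return topology
    parts = sorted(canonical_nested(child) for child in topology)
    return "(" + ",".join(parts) + ")"


def canonical_form(node: Node, rename=None) -> str:
    """Canonical string of the rooted topology of ``node``.

    ``rename`` optionally maps tip labels (e.g. sample ids to group names)
    before encoding.
    """
    if node.is_leaf:
        label = node.label
        return rename(label) if rename else label
    parts = sorted(canonical_form(c, rename) for c in node.children)
    return "(" + ",".join(parts) + ")"


def nested_clades(topology: NestedTopology) -> set[frozenset[str]]:
    """All clades (tip-label sets of internal nodes, including the root)."""
    clades: set[frozenset[str]] = set()

    def collect(t: NestedTopology) -> frozenset[str]:
        if isinstance(t, str):
            return frozenset([t])
        tips = frozenset().union(*(collect(c) for c in t))
        clades.add(tips)
        return tips

    collect(topology)
    return clades


def count_rooted_topologies(n: int) -> int:
    """Number of rooted binary leaf-labelled topologies: (2n-3)!!."""
    if n < 2:
        raise ValueError("need at least 2 taxa")
    result = 1
    for k in range(3, 2 * n - 2, 2):
        result *= k
    return result


def _insert_leaf(topology: NestedTopology, leaf: str) -> Iterator[NestedTopology]:
    # Attach above the root ...
    yield (topology, leaf)
    # ... or recursively inside either subtree.
    if isinstance(topology, tuple):
        left, right = topology
        for new_left in _insert_leaf(left, leaf):
            yield (new_left, right)
        for new_right in _insert_leaf(right, leaf):
            yield (left, new_right)


@dataclass
class TopologyCatalog:
    """The canonical, deterministically ordered set of rooted topologies."""

    taxa: tuple[str, ...]
    topologies: tuple[NestedTopology, ...]
    forms: tuple[str, ...]

    def __post_init__(self):
        self._index = {form: i for i, form in enumerate(self.forms)}

    def __len__(self) -> int:
        return len(self.topologies)

    def index_of(self, form: str) -> int:
        return self._index[form]

    def clade_mask(self, clade: Sequence[str]):
        """Boolean list: does each topology contain ``clade`` as monophyletic?"""
        clade_set = frozenset(clade)
        if not clade_set <= set(self.taxa):
            raise ValueError("clade contains labels outside the catalog taxa")
        if len(clade_set) < 2 or len(clade_set) >= len(self.taxa):
            raise ValueError("clade must be a nontrivial subset of the taxa")
        return [clade_set in nested_clades(t) for t in self.topologies]


def enumerate_rooted_topologies(taxa: Sequence[str], allow_large: bool = False) -> TopologyCatalog:
    """All rooted binary topologies over ``taxa``, canonically ordered.

    Trees are grown by inserting each successive taxon on every edge
    (including above the root) of every tree over the previous taxa, which
    yields each topology exactly once.  Guarded at 8 taxa (10395 topologies
    at 7 already; the double factorial explodes beyond that) unless
    ``allow_large`` is set.
    """
    labels = list(taxa)
    if len(set(labels)) != len(labels):
        raise ValueError("taxon labels must be unique")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n > 8 and not allow_large:
        raise ValueError(
            f"{n} taxa give {count_rooted_topologies(n)} topologies; "
            "pass allow_large=True to override"
        )
    ordered = sorted(labels)
    trees: list[NestedTopology] = [(ordered[0], ordered[1])]
    for leaf in ordered[2:]:
        trees = [t for base in trees for t in _insert_leaf(base, leaf)]
    paired = sorted((canonical_nested(t), t) for t in trees)
    forms = tuple(form for form, _ in paired)
    assert len(set(forms)) == len(forms) == count_rooted_topologies(n)
    return TopologyCatalog(taxa=tuple(ordered), topologies=tuple(t for _, t in paired), forms=forms)


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------

def resolve_polytomies(node: Node, rng) -> Node:
    """Return a copy with every polytomy resolved uniformly at random."""
    out = node.copy()
    for n in out.postorder():
        while len(n.children) > 2:
            i, j = sorted(rng.sample(range(len(n.children)), 2))
            b = n.children.pop(j)
            a = n.children.pop(i)
            n.children.append(Node(length=0.0, children=[a, b]))
    return out


def reroot_on_tip(node: Node, tip_label: str) -> Node:
    """Re-root on the edge above ``tip_label`` (tip becomes one root child)."""
    labels = node.leaf_labels()
    if tip_label not in labels:
        raise ValueError(f"tip {tip_label!r} not in tree")
    tree = dendropy.Tree.get(
        data=write_newick(node),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tip = next(l for l in tree.leaf_node_iter() if l.taxon.label == tip_label)
    tree.reroot_at_edge(tip.edge, update_bipartitions=False)
    tree.suppress_unifurcations()
    return _from_dendropy(tree.seed_node)
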