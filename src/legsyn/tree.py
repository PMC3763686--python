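"""Minimal unrooted phylogenetic tree container used by the gene-family module.

The tree is stored rooted at an arbitrary internal node (degree 3 for an
unrooted binary topology); bipartition helpers treat it as unrooted.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Clade:
    """One node: a leaf (name set, no children) or an internal node."""

    name: str | None = None
    length: float | None = None  # branch length to parent
    support: float | None = None  # bootstrap percentage in [0, 100]
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    root: Clade

    @property
    def leaves(self) -> list[Clade]:
        return [n for n in self.root.walk() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    def to_newick(self) -> str:
        return _newick(self.root) + ";"

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the frozenset of leaf names on the side
        not containing the reference leaf (the lexicographically first name)."""
        names = sorted(self.leaf_names)
        ref = names[0]
        all_names = frozenset(names)
        splits = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(n.name for n in node.walk() if n.is_leaf)
            if ref in side:
                side = all_names - side
            if 2 <= len(side) <= len(names) - 2:
                splits.add(side)
        return splits

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.root.walk() if n is not self.root)


def _fmt_num(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return repr(round(float(x), 10))


def _newick(node: Clade) -> str:
    if node.is_leaf:
        core = node.name or ""
    else:
        inner = ",".join(_newick(c) for c in node.children)
        label = ""
        if node.support is not None:
            label = str(int(round(node.support)))
        core = f"({inner}){label}"
    if node.length is not None:
        core += f":{_fmt_num(node.length)}"
    return core


def from_dendropy(dtree) -> PhyloTree:
    """Convert a dendropy Tree to a PhyloTree (used by the Newick reader)."""

    def conv(dnode):
        node = Clade(
            name=dnode.taxon.label if dnode.taxon else None,
            length=dnode.edge.length,
        )
        if dnode.label is not None and not dnode.is_leaf():
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.name = dnode.label
        node.children = [conv(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(root=conv(dtree.seed_node))
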