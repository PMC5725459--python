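"""Rooted species trees.

The interaction-evolution analysis runs on a small rooted species tree
(by default ``((dog,cat),(horse,(pig,cow)))`` with the mouse state used
as an outgroup to resolve the root).  Parsing and serialization go
through dendropy; internally we keep a minimal node structure that the
Fitch pass iterates over.

Unnamed internal nodes are auto-named ``A1, A2, ...`` in preorder so
branch reports are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy


@dataclass
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """A rooted tree with uniquely labelled tips.

    Branches are identified by the name of the child node they lead
    into, e.g. the terminal branch into ``dog`` is branch ``"dog"``.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._name_internal_nodes()
        names = [n.name for n in self.preorder()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate node labels in tree: {sorted(dupes)}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        _check_parentheses(newick)
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=False
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"newick parse error: {exc}") from exc
        tips = [lf.taxon.label for lf in dtree.leaf_node_iter() if lf.taxon]
        dupes = {t for t in tips if tips.count(t) > 1}
        if dupes:
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")

        def convert(dnode) -> TreeNode:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = TreeNode(name=label or "")
            for child in dnode.child_nodes():
                cn = convert(child)
                cn.parent = node
                node.children.append(cn)
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def read(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    def _name_internal_nodes(self) -> None:
        counter = 0
        for node in self.preorder():
            if not node.is_leaf and not node.name:
                counter += 1
                node.name = f"A{counter}"

    # -- traversal ----------------------------------------------------

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[TreeNode]:
        return list(reversed([n for n in self._preorder_rl()]))

    def _preorder_rl(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def branches(self) -> list[str]:
        """Branch ids (child-node names) for every non-root node, preorder."""
        return [n.name for n in self.preorder() if n.parent is not None]

    def node(self, name: str) -> TreeNode:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.name}"

        return render(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- comparison ---------------------------------------------------

    def clades(self) -> set[frozenset[str]]:
        """Tip-label sets of every node; two rooted trees are topologically
        identical iff these sets coincide."""
        result: set[frozenset[str]] = set()

        def collect(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(collect(c) for c in node.children))
            result.add(s)
            return s

        collect(self.root)
        return result

    def same_topology(self, other: "SpeciesTree") -> bool:
        return self.clades() == other.clades()

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({self.to_newick()!r})"


def _check_parentheses(newick: str) -> None:
    depth = 0
    for i, ch in enumerate(newick):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {i}")
    if depth != 0:
        raise ValueError("unbalanced '(' in newick string")


#: Default analysis tree: the four comparison species plus dog.  The
#: mouse outgroup is not a tip here; its interaction state resolves the
#: root during parsimony reconstruction.
DEFAULT_NEWICK = "((dog,cat),(horse,(pig,cow)));"


def default_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_NEWICK)
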