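"""Tree data model and Newick/NHX input-output.

Two tree flavours share one node structure:

* a *species tree* — rooted, binary, ultrametric, with node ages rescaled so
  the root sits at age 1 and tips at age 0, and a letter label on every
  non-root branch;
* a *gene tree* — rooted, branch lengths in substitutions/site, each tip
  carrying the species it was sampled from (encoded in the tip name as
  ``species<sep>gene``), and per-node event annotations filled in by the
  reconciliation step.

Newick parsing is delegated to :mod:`dendropy`; NHX-style hot comments
(``[&&NHX:Ev=S:Snode=3:NULLED=1]``) are decoded from the raw comment strings
dendropy preserves, since dendropy has no native NHX support.
"""

from __future__ import annotations

import math
import string
from typing import Callable, Iterator, Optional

import dendropy

#: Branch length upstream tree builders emit in place of zero.
DEFAULT_BRANCH_LENGTH = 1e-6

#: Relative tolerance (fraction of root age) for the ultrametricity check.
ULTRAMETRIC_RTOL = 1e-8

#: Recognised node event states.
EVENTS = ("speciation", "duplication", "null", "unassigned")


class TreeError(ValueError):
    """Malformed or inconsistent tree input."""


class Node:
    """A node in a rooted tree.

    Attributes
    ----------
    name : str or None
        Tip label, or an optional internal-node label.
    length : float or None
        Length of the branch above this node (None on the root).
    event : str
        One of :data:`EVENTS`; meaningful on gene trees only.
    species_node : Node or None
        For speciation nodes (and tips), the corresponding species-tree node.
    age : float or None
        Node age in species-tree time units; set by calibration, and by
        construction on species trees.
    branch_label : str or None
        Species-tree branch identifier (letter) of the branch above this node.
    """

    __slots__ = (
        "name", "length", "children", "parent", "event", "species_node",
        "age", "branch_label", "id", "extra",
    )

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.event: str = "unassigned"
        self.species_node: Optional[Node] = None
        self.age: Optional[float] = None
        self.branch_label: Optional[str] = None
        self.id: Optional[int] = None
        self.extra: dict = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def ancestors(self) -> Iterator["Node"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def depth(self) -> float:
        """Path length (branch-length sum) from the root to this node."""
        d = 0.0
        node = self
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        return d

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)}-child"
        return f"<Node {self.name or self.id} ({kind}, event={self.event})>"


class Tree:
    """A rooted tree with utility traversals shared by both tree flavours."""

    def __init__(self, root: Node):
        self.root = root
        self.assign_ids()

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def assign_ids(self) -> None:
        """Number nodes 0, 1, ... in preorder (stable identities)."""
        for i, node in enumerate(self.preorder()):
            node.id = i

    def node_by_id(self, node_id: int) -> Node:
        for node in self.preorder():
            if node.id == node_id:
                return node
        raise KeyError(node_id)

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    def mrca(self, nodes: list[Node]) -> Node:
        """Most recent common ancestor of a non-empty set of nodes."""
        if not nodes:
            raise ValueError("mrca of an empty node set")
        paths = []
        for node in nodes:
            path = [node] + list(node.ancestors())
            paths.append(list(reversed(path)))
        mrca = paths[0][0]
        for level in range(min(len(p) for p in paths)):
            candidate = paths[0][level]
            if all(p[level] is candidate for p in paths):
                mrca = candidate
            else:
                break
        return mrca

    def copy(self) -> "Tree":
        new_root = _copy_subtree(self.root)
        tree = object.__new__(type(self))
        Tree.__init__(tree, new_root)
        # preserve original ids rather than renumbering
        for old, new in zip(self.preorder(), tree.preorder()):
            new.id = old.id
        return tree

    def canonicalize(self) -> "Tree":
        """Sort children by smallest descendant leaf name, in place."""

        def key(node: Node) -> str:
            return min(leaf.name or "" for leaf in node.leaves())

        for node in self.preorder():
            node.children.sort(key=key)
        return self


def _copy_subtree(node: Node) -> Node:
    new = Node(node.name, node.length)
    new.event = node.event
    new.species_node = node.species_node
    new.age = node.age
    new.branch_label = node.branch_label
    new.id = node.id
    new.extra = dict(node.extra)
    for child in node.children:
        new.add_child(_copy_subtree(child))
    return new


class SpeciesTree(Tree):
    """Rooted binary ultrametric species tree, root age rescaled to 1."""

    def __init__(self, root: Node):
        super().__init__(root)
        self._validate_binary()
        self._set_ages()
        self._species_index = {leaf.name: leaf for leaf in self.leaves()}

    def _validate_binary(self) -> None:
        for node in self.internal_nodes():
            if len(node.children) != 2:
                raise TreeError(
                    f"species tree must be binary; node {node.name or node.id} "
                    f"has {len(node.children)} children"
                )
        names = [leaf.name for leaf in self.leaves()]
        if any(not n for n in names):
            raise TreeError("species tree has unlabeled tips")
        if len(set(names)) != len(names):
            raise TreeError("duplicate species tip names")

    def _set_ages(self) -> None:
        depths = {leaf: leaf.depth() for leaf in self.leaves()}
        root_age = max(depths.values())
        if root_age <= 0:
            raise TreeError("species tree has zero height")
        spread = max(depths.values()) - min(depths.values())
        if spread > ULTRAMETRIC_RTOL * root_age:
            raise TreeError(
                f"species tree is not ultrametric: tip depth spread {spread:g} "
                f"exceeds tolerance ({ULTRAMETRIC_RTOL:g} x root age)"
            )
        # rescale so the root sits at age 1, tips at exactly 0
        for node in self.preorder():
            if node.is_leaf:
                node.age = 0.0
            else:
                node.age = (root_age - node.depth()) / root_age
        self.root.age = 1.0
        for node in self.preorder():
            if not node.is_root:
                node.length = node.parent.age - node.age

    def copy(self) -> "SpeciesTree":
        tree = super().copy()
        tree._species_index = {leaf.name: leaf for leaf in tree.leaves()}
        return tree

    def species(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def leaf_for_species(self, species: str) -> Node:
        try:
            return self._species_index[species]
        except KeyError:
            raise TreeError(f"species {species!r} not in species tree") from None

    def mrca_of_species(self, species: set[str] | list[str]) -> Node:
        leaves = [self.leaf_for_species(s) for s in species]
        return self.mrca(leaves)


def species_from_tip(tip_name: str, separator: str = "@") -> str:
    """Extract the species identifier from a ``species<sep>gene`` tip name."""
    return tip_name.split(separator)[0]


class GeneTree(Tree):
    """Rooted gene tree; tips carry species identity in their names."""

    def __init__(self, root: Node, separator: str = "@", tree_id: str = ""):
        super().__init__(root)
        self.separator = separator
        self.tree_id = tree_id
        for leaf in self.leaves():
            if not leaf.name:
                raise TreeError("gene tree has unlabeled tips")
            leaf.extra.setdefault("species", species_from_tip(leaf.name, separator))
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length on node {node.name or node.id}")

    def tip_species(self, leaf: Node) -> str:
        return leaf.extra["species"]

    def species_set(self) -> set[str]:
        return {self.tip_species(leaf) for leaf in self.leaves()}

    def copy(self) -> "GeneTree":
        tree = super().copy()
        tree.separator = self.separator
        tree.tree_id = self.tree_id
        return tree


# ----------------------------------------------------------------------------
# Newick / NHX I/O
# ----------------------------------------------------------------------------

_NHX_EVENT_CODES = {"S": "speciation", "D": "duplication", "N": "null"}
_NHX_EVENT_CODES_REV = {"speciation": "S", "duplication": "D", "null": "N"}


def _parse_nhx_comment(comment: str) -> dict:
    """Decode ``&&NHX:key=value:...`` into a dict; non-NHX comments ignored."""
    comment = comment.strip("[]")
    if not comment.startswith("&&NHX"):
        return {}
    fields = {}
    for part in comment.split(":")[1:]:
        if "=" in part:
            key, _, value = part.partition("=")
            fields[key] = value
    return fields


def read_newick(source: str, kind: str = "gene", separator: str = "@",
                tree_id: str = "", is_path: Optional[bool] = None):
    """Parse a Newick string or file into a :class:`SpeciesTree` or :class:`GeneTree`.

    NHX hot comments are honoured on gene trees: ``Ev`` (S/D/N) presets the
    node event, ``Snode`` records a species-node id to resolve after mapping,
    ``NULLED=1`` marks a null node.
    """
    if kind not in ("species", "gene"):
        raise ValueError(f"kind must be 'species' or 'gene', got {kind!r}")
    if is_path is None:
        is_path = "(" not in source
    get_kwargs = dict(
        schema="newick",
        extract_comment_metadata=False,
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    try:
        if is_path:
            dtree = dendropy.Tree.get(path=source, **get_kwargs)
        else:
            dtree = dendropy.Tree.get(data=source, **get_kwargs)
    except Exception as exc:  # dendropy raises several error types with position info
        raise TreeError(f"newick parse error: {exc}") from exc

    root = _from_dendropy(dtree.seed_node)
    if kind == "species":
        return SpeciesTree(root)
    return GeneTree(root, separator=separator, tree_id=tree_id)


def _from_dendropy(dnode) -> Node:
    name = dnode.taxon.label if dnode.taxon is not None else (dnode.label or None)
    node = Node(name=name, length=dnode.edge.length)
    for comment in dnode.comments:
        fields = _parse_nhx_comment(comment)
        if "Ev" in fields:
            node.event = _NHX_EVENT_CODES.get(fields["Ev"], "unassigned")
        if fields.get("NULLED") == "1":
            node.event = "null"
        if "Snode" in fields:
            node.extra["nhx_snode"] = fields["Snode"]
        if "Age" in fields:
            node.age = float(fields["Age"])
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def write_newick(tree: Tree, path: Optional[str] = None, nhx: bool = False,
                 precision: int = 12) -> str:
    """Serialise a tree to Newick, optionally with NHX event annotations.

    Written by hand because dendropy cannot emit NHX hot comments; the output
    round-trips through :func:`read_newick`.
    """

    def fmt_length(length: Optional[float]) -> str:
        if length is None:
            return ""
        return f":{length:.{precision}g}"

    def fmt_nhx(node: Node) -> str:
        if not nhx:
            return ""
        fields = []
        if node.event in _NHX_EVENT_CODES_REV:
            fields.append(f"Ev={_NHX_EVENT_CODES_REV[node.event]}")
        if node.species_node is not None:
            fields.append(f"Snode={node.species_node.id}")
        if node.event == "null":
            fields.append("NULLED=1")
        if node.age is not None:
            fields.append(f"Age={node.age:.{precision}g}")
        if not fields:
            return ""
        return "[&&NHX:" + ":".join(fields) + "]"

    def rec(node: Node) -> str:
        if node.is_leaf:
            return f"{node.name}{fmt_length(node.length)}{fmt_nhx(node)}"
        inner = ",".join(rec(c) for c in node.children)
        label = node.name or ""
        return f"({inner}){label}{fmt_length(node.length)}{fmt_nhx(node)}"

    text = rec(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ----------------------------------------------------------------------------
# Species-branch labels
# ----------------------------------------------------------------------------

def _letter_label(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet-style)."""
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = letters[rem] + out
    return out


def label_species_branches(tree: SpeciesTree) -> SpeciesTree:
    """Assign deterministic preorder letter labels to every non-root branch.

    The branch above each non-root node gets the next letter (A, B, C, ...)
    in preorder; relabelling is idempotent.
    """
    i = 0
    for node in tree.preorder():
        if node.is_root:
            node.branch_label = None
            continue
        node.branch_label = _letter_label(i)
        i += 1
    return tree


def branch_labels(tree: SpeciesTree) -> dict[str, Node]:
    return {n.branch_label: n for n in tree.preorder() if n.branch_label}
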