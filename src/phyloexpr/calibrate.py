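"""Time calibration of gene trees against a species tree.

Every non-null speciation node is pinned to the age of its species-tree node
(species-tree root = 1, tips = 0); gene-tree tips are pinned to age 0.
Unconstrained nodes (duplications and null nodes) receive ages by
deterministic interpolation: a node's age lies between its nearest
constrained ancestor and its oldest constrained descendant, positioned
proportionally to the original substitutions/site branch lengths along that
path.  If every length on the path is at or below the upstream default
(1e-6, the zero placeholder), ages are spread evenly instead, which avoids
zero-length calibrated branches.

Processed top-down, this sequential interpolation reproduces the global
proportional placement along unconstrained chains while guaranteeing strict
parent-over-child age ordering.  An unconstrained region containing the root
(e.g. duplications above all speciation constraints) is aged bottom-up: each
node sits above its oldest child by the child's branch length converted to
time at the child subtree's local substitution rate.

Calibration fails — returning :class:`CalibrationFailure` naming the node
pair — when the constraints themselves violate ancestor-over-descendant
ordering (a deeper node pinned to an equal or older age), which is exactly
the situation null-marking exists to prevent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .trees import DEFAULT_BRANCH_LENGTH, GeneTree, Node, SpeciesTree

#: Minimum age gap enforced between parent and child (strict ordering).
MIN_AGE_GAP = 1e-12


@dataclass
class CalibrationFailure:
    tree_id: str
    reason: str
    node_a: str
    node_b: str


def _is_constrained(node: Node) -> bool:
    if node.is_leaf:
        return True
    return node.event == "speciation" and node.species_node is not None


def _constraint_age(node: Node) -> float:
    if node.is_leaf:
        return 0.0
    return node.species_node.age


def _label(node: Node) -> str:
    return node.name or f"node{node.id}"


def _oldest_constrained_descendant(node: Node, cache: dict) -> tuple[Node, float]:
    """(descendant, substitution path length) of the max-age constrained
    descendant below ``node``; tips count as constrained at age 0 so one
    always exists."""
    if node in cache:
        return cache[node]
    best: Optional[tuple[Node, float]] = None
    best_age = -1.0
    for child in node.children:
        edge = max(child.length or 0.0, DEFAULT_BRANCH_LENGTH)
        if _is_constrained(child):
            cand, dist, age = child, edge, _constraint_age(child)
        else:
            sub, subdist = _oldest_constrained_descendant(child, cache)
            cand, dist, age = sub, edge + subdist, _constraint_age(sub)
        if age > best_age:
            best, best_age = (cand, dist), age
    cache[node] = best
    return best


def _path_all_default(top: Node, bottom: Node) -> bool:
    """True if every edge on the path top->bottom is at/below the default."""
    node = bottom
    while node is not top:
        if (node.length or 0.0) > DEFAULT_BRANCH_LENGTH:
            return False
        node = node.parent
        if node is None:
            raise ValueError("bottom is not a descendant of top")
    return True


def _count_edges(top: Node, bottom: Node) -> int:
    n, node = 0, bottom
    while node is not top:
        n += 1
        node = node.parent
    return n


def _mean_tip_distance(node: Node) -> float:
    leaves = node.leaves()
    total = 0.0
    for leaf in leaves:
        d, cur = 0.0, leaf
        while cur is not node:
            d += max(cur.length or 0.0, DEFAULT_BRANCH_LENGTH)
            cur = cur.parent
        total += d
    return total / len(leaves)


def calibrate_gene_tree(
    gt: GeneTree, st: SpeciesTree
) -> Union[GeneTree, CalibrationFailure]:
    """Return a calibrated copy (ages set, branch lengths in time) or a failure.

    Requires events, species-node mappings and null marks to be present
    (see :mod:`phyloexpr.reconcile`).
    """
    ct = gt.copy()
    desc_cache: dict = {}

    # Feasibility: every constrained node must be strictly younger than its
    # nearest constrained ancestor.
    anc_stack: list[tuple[Node, Optional[Node]]] = [(ct.root, None)]
    while anc_stack:
        node, anc = anc_stack.pop()
        nearest = anc
        if _is_constrained(node):
            if anc is not None and _constraint_age(node) >= _constraint_age(anc) - MIN_AGE_GAP:
                return CalibrationFailure(
                    tree_id=ct.tree_id,
                    reason=(
                        f"constrained node {_label(node)} (age "
                        f"{_constraint_age(node):g}) not younger than ancestor "
                        f"{_label(anc)} (age {_constraint_age(anc):g})"
                    ),
                    node_a=_label(anc),
                    node_b=_label(node),
                )
            nearest = node
        for child in node.children:
            anc_stack.append((child, nearest))

    # Top-down age assignment for nodes with an aged parent chain.
    # Nodes in the unconstrained crown region (no constrained ancestor,
    # including an unconstrained root) are deferred and aged bottom-up after.
    deferred: list[Node] = []
    order = list(ct.preorder())
    for node in order:
        if _is_constrained(node):
            node.age = _constraint_age(node)
            continue
        if node.parent is None or node.parent.age is None:
            deferred.append(node)
            continue
        parent_age = node.parent.age
        desc, below = _oldest_constrained_descendant(node, desc_cache)
        desc_age = _constraint_age(desc)
        if parent_age <= desc_age + MIN_AGE_GAP:
            return CalibrationFailure(
                tree_id=ct.tree_id,
                reason=(
                    f"no age room for unconstrained node {_label(node)} between "
                    f"ancestor at {parent_age:g} and descendant {_label(desc)} "
                    f"at {desc_age:g}"
                ),
                node_a=_label(node.parent),
                node_b=_label(desc),
            )
        if _path_all_default(node.parent, desc):
            # even spreading by edge count
            n_below = _count_edges(node, desc)
            n_total = _count_edges(node.parent, desc)
            frac = n_below / n_total
        else:
            above = max(node.length or 0.0, DEFAULT_BRANCH_LENGTH)
            frac = below / (above + below)
        node.age = desc_age + frac * (parent_age - desc_age)

    # Bottom-up pass for the unconstrained crown region (root side).
    for node in reversed(order):
        if node.age is not None or node not in deferred:
            continue
        child = max(node.children, key=lambda c: c.age)
        edge = max(child.length or 0.0, DEFAULT_BRANCH_LENGTH)
        if child.age > 0:
            rate = _mean_tip_distance(child) / child.age  # substitutions per time
            dt = edge / rate if rate > 0 else edge
        else:
            dt = edge
        node.age = child.age + max(dt, MIN_AGE_GAP)

    # Branch lengths become time spans.
    for node in ct.preorder():
        if not node.is_root:
            node.length = node.parent.age - node.age
    ct.root.length = None
    return ct


def root_depth(ct: GeneTree) -> float:
    """Maximum node age of a calibrated gene tree (root age)."""
    if ct.root.age is None:
        raise ValueError("tree is not calibrated")
    return ct.root.age


def time_length(node: Node) -> float:
    """Calibrated time span of the branch above ``node``."""
    return node.parent.age - node.age
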