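"""Maximum-likelihood ancestral state reconstruction under Brownian motion.

For a continuous trait x observed at the tips of a tree with branch lengths
t, the joint ML ancestral states minimize

    sum over branches of (x_child - x_parent)^2 / t

which is a weighted least-squares problem solved exactly in linear time by
two passes over the tree (Felsenstein-style pruning):

* upward — each internal node accumulates from its children a conditional
  value v (precision-weighted mean) and an effective extra branch length
  lambda = 1 / sum(1/l_i);
* downward — each internal node's final value combines its conditional value
  with its parent's final value, weighted by 1/lambda and 1/t.

Trees are first pruned to the tips that carry observations; suppressed
degree-2 nodes have their incident time lengths summed so pairwise tip
distances are conserved, and surviving nodes keep their original identities
so reconstructed values can be mapped back onto the unpruned tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .trees import GeneTree, Node

#: Floor applied to zero-length branches so precisions stay finite.
LENGTH_FLOOR = 1e-9


@dataclass
class TraitMap:
    """Per-node trait values with provenance (observed at tips,
    reconstructed at surviving internal nodes, absent elsewhere)."""

    values: dict[int, float] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def set(self, node_id: int, value: float, prov: str) -> None:
        self.values[node_id] = value
        self.provenance[node_id] = prov

    def get(self, node_id: int) -> Optional[float]:
        return self.values.get(node_id)

    def __len__(self) -> int:
        return len(self.values)


def prune_to_observed(ct: GeneTree, tip_values: Mapping[str, float]) -> Optional[GeneTree]:
    """Restrict a calibrated tree to tips with (finite) observed values.

    Unvalued tips are removed; resulting degree-2 nodes are suppressed with
    their incident branch lengths summed.  Surviving nodes retain their
    original node ids.  Returns None when fewer than one valued tip remains.
    """
    valued = {
        name for name, v in tip_values.items() if v is not None and np.isfinite(v)
    }
    pruned = ct.copy()
    keep_tips = [leaf for leaf in pruned.leaves() if leaf.name in valued]
    if not keep_tips:
        return None

    keep: set[Node] = set(keep_tips)
    for leaf in keep_tips:
        keep.update(leaf.ancestors())

    def rebuild(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if node in keep else None
        new_children = [c for c in (rebuild(child) for child in node.children) if c]
        if not new_children:
            return None
        if len(new_children) == 1:
            # suppress this degree-2 node; extend the surviving child's branch
            child = new_children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            child.parent = node.parent
            return child
        node.children = new_children
        for c in new_children:
            c.parent = node
        return node

    new_root = rebuild(pruned.root)
    if new_root is None:
        return None
    new_root.parent = None
    out = object.__new__(GeneTree)
    out.root = new_root
    out.separator = ct.separator
    out.tree_id = ct.tree_id
    return out


def reconstruct_ancestral_bm(
    ct: GeneTree, tip_values: Mapping[str, float]
) -> TraitMap:
    """Joint ML ancestral values for one trait on a (pruned) calibrated tree.

    ``tip_values`` maps tip names to observations; every tip of ``ct`` must
    be valued.  Returns a :class:`TraitMap` over the tree's node ids with
    tips marked ``observed`` and internal nodes ``reconstructed``.
    """
    for leaf in ct.leaves():
        if leaf.name not in tip_values:
            raise ValueError(f"tip {leaf.name!r} has no observed value; prune first")

    cond_value: dict[Node, float] = {}
    cond_extra: dict[Node, float] = {}  # lambda: effective extra length above v

    # upward pass
    for node in ct.postorder():
        if node.is_leaf:
            cond_value[node] = float(tip_values[node.name])
            cond_extra[node] = 0.0
        else:
            precisions, values = [], []
            for child in node.children:
                eff_len = max(child.length or 0.0, LENGTH_FLOOR) + cond_extra[child]
                precisions.append(1.0 / eff_len)
                values.append(cond_value[child])
            total_prec = sum(precisions)
            cond_value[node] = sum(p * v for p, v in zip(precisions, values)) / total_prec
            cond_extra[node] = 1.0 / total_prec

    # downward pass
    traits = TraitMap()
    final: dict[Node, float] = {}
    for node in ct.preorder():
        if node.is_leaf:
            final[node] = float(tip_values[node.name])
            traits.set(node.id, final[node], "observed")
            continue
        if node.is_root:
            final[node] = cond_value[node]
        else:
            t = max(node.length or 0.0, LENGTH_FLOOR)
            w_below = 1.0 / cond_extra[node] if cond_extra[node] > 0 else None
            if w_below is None:
                final[node] = cond_value[node]
            else:
                w_above = 1.0 / t
                final[node] = (
                    w_below * cond_value[node] + w_above * final[node.parent]
                ) / (w_below + w_above)
        traits.set(node.id, final[node], "reconstructed")
    return traits


def map_back(traits: TraitMap, unpruned: GeneTree) -> TraitMap:
    """Carry reconstructed values back onto the unpruned tree by node id.

    Nodes suppressed during pruning have no value (provenance ``absent``);
    no interpolation is attempted for them.
    """
    out = TraitMap()
    for node in unpruned.preorder():
        if node.id in traits.values:
            out.set(node.id, traits.values[node.id], traits.provenance[node.id])
        else:
            out.provenance[node.id] = "absent"
    return out


def reconstruct_tissue(
    ct: GeneTree, tip_values: Mapping[str, float], min_tips: int = 1
) -> Optional[TraitMap]:
    """Prune to observed tips, reconstruct, and map back onto ``ct``.

    Returns None when fewer than ``min_tips`` tips carry values.  Separate
    tissues are reconstructed by independent calls (one trait per run).
    """
    pruned = prune_to_observed(ct, tip_values)
    if pruned is None or len(pruned.leaves()) < max(min_tips, 1):
        return None
    traits = reconstruct_ancestral_bm(pruned, tip_values)
    return map_back(traits, ct)
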