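"""Gene-tree/species-tree reconciliation by species overlap.

Three steps, run in order on a rooted gene tree:

1. :func:`label_events_species_overlap` — an internal node is a *duplication*
   if the species sets of its child subtrees intersect, otherwise a
   *speciation* (the species-overlap rule).  Pre-existing NHX event labels
   are honoured and left untouched.
2. :func:`map_speciation_nodes` — each speciation node is mapped to the MRCA
   in the species tree of its descendant species set.
3. :func:`mark_null_nodes` — a speciation node that has a non-null speciation
   ancestor mapped to the *same* species-tree node is demoted to *null*
   (its mapping is kept for diagnostics).  Without this, nested nodes would
   receive equal-age calibration constraints.  Intervening duplication nodes
   do not reset the scan.
"""

from __future__ import annotations

from .trees import GeneTree, Node, SpeciesTree, TreeError


def subtree_species_sets(gt: GeneTree) -> dict[Node, frozenset]:
    """Species set of every node's subtree (postorder, linear time)."""
    sets: dict[Node, frozenset] = {}
    for node in gt.postorder():
        if node.is_leaf:
            sets[node] = frozenset([gt.tip_species(node)])
        else:
            acc = frozenset()
            for child in node.children:
                acc |= sets[child]
            sets[node] = acc
    return sets


def label_events_species_overlap(gt: GeneTree) -> GeneTree:
    """Assign speciation/duplication to internal nodes lacking an event label.

    Nonbinary nodes are treated as a single event over all children (pairwise
    overlap of any two child subtrees makes it a duplication).
    """
    sets = subtree_species_sets(gt)
    for node in gt.internal_nodes():
        if node.event != "unassigned":
            continue  # honour precomputed reconciliation (NHX Ev tags)
        seen: set = set()
        dup = False
        for child in node.children:
            if seen & sets[child]:
                dup = True
                break
            seen |= sets[child]
        node.event = "duplication" if dup else "speciation"
    return gt


def map_speciation_nodes(gt: GeneTree, st: SpeciesTree) -> GeneTree:
    """Attach to each speciation node the species-tree MRCA of its species set.

    Tips are mapped to their species' leaf; duplication nodes carry no
    mapping.  A tip species absent from the species tree is an error.
    """
    sets = subtree_species_sets(gt)
    for species in sets[gt.root]:
        st.leaf_for_species(species)  # raises TreeError naming the species
    for node in gt.preorder():
        if node.is_leaf:
            node.species_node = st.leaf_for_species(gt.tip_species(node))
        elif node.event in ("speciation", "null"):
            node.species_node = st.mrca_of_species(sets[node])
        else:
            node.species_node = None
    return gt


def mark_null_nodes(gt: GeneTree) -> int:
    """Demote repeated same-mapping speciation nodes to null; return the count.

    Root-to-tip traversal carrying the set of species-node ids of non-null
    speciation ancestors; a speciation node whose mapping is already in that
    set becomes null.  In a chain of three same-mapping speciation nodes the
    two deeper ones are nulled.
    """
    n_null = 0
    stack: list[tuple[Node, frozenset]] = [(gt.root, frozenset())]
    while stack:
        node, ancestor_ids = stack.pop()
        ids = ancestor_ids
        if node.event == "speciation" and node.species_node is not None:
            sid = node.species_node.id
            if sid in ancestor_ids:
                node.event = "null"
                n_null += 1
            else:
                ids = ancestor_ids | {sid}
        for child in node.children:
            stack.append((child, ids))
    return n_null


def annotate(gt: GeneTree, st: SpeciesTree) -> tuple[GeneTree, int]:
    """Run the full annotation: events, species-node mapping, null marking."""
    label_events_species_overlap(gt)
    map_speciation_nodes(gt, st)
    n_null = mark_null_nodes(gt)
    return gt, n_null


def node_table(gt: GeneTree) -> list[dict]:
    """Long-format per-node summary (node_id, event, species_node, nulled)."""
    rows = []
    for node in gt.preorder():
        rows.append(
            {
                "tree_id": gt.tree_id,
                "node_id": node.id,
                "name": node.name or "",
                "event": node.event if not node.is_leaf else "tip",
                "species_node": node.species_node.id if node.species_node else "",
                "nulled": int(node.event == "null"),
            }
        )
    return rows
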