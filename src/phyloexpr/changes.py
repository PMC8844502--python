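"""Species branch filtering core: scaled per-branch expression changes,
species-equivalent branch identification, classification, and tallies.

For each gene-tree branch whose endpoints both carry trait values, the
scaled change is

    (child value - parent value) / calibrated time length

classified against a symmetric neutral band: negative below -2, positive
above +2, neutral on the closed interval in between (band edges inclusive).

A branch u -> v is *species-equivalent* to species-tree branch B when u is a
non-null speciation node and either v is a non-null speciation node whose
species node is the child of u's in the species tree, or v is a tip of
species S whose species-tree leaf is the child of u's mapping.  B is the
label of the species-tree branch above v's mapping.  Multiple gene-tree
branches may share one species-tree branch (deep duplications copy them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .asr import TraitMap
from .trees import GeneTree, Node, SpeciesTree

#: Floor for calibrated time lengths used as scaled-change denominators.
TIME_FLOOR = 1e-9


@dataclass
class ChangeThresholds:
    """Neutral band and the large-change cutoff (absolute scaled change)."""

    neutral_lo: float = -2.0
    neutral_hi: float = 2.0
    large: float = 5.0

    def __post_init__(self):
        if not (self.neutral_lo < 0 < self.neutral_hi < self.large):
            raise ValueError("thresholds must satisfy lo < 0 < hi < large")


@dataclass
class BranchChangeRecord:
    tree_id: str
    parent_node: int
    child_node: int
    tissue: str
    parent_value: float
    child_value: float
    time_length: float
    scaled_change: float
    change_class: str
    species_branch: Optional[str] = None
    floored: bool = False


def classify_change(delta: float, thresholds: Optional[ChangeThresholds] = None) -> str:
    """negative | neutral | positive; band edges classify as neutral."""
    th = thresholds or ChangeThresholds()
    if math.isnan(delta):
        raise ValueError("scaled change is NaN")
    if delta < th.neutral_lo:
        return "negative"
    if delta > th.neutral_hi:
        return "positive"
    return "neutral"


def ratio_trait(numerator: TraitMap, denominator: TraitMap) -> TraitMap:
    """Log-ratio trait: value difference at nodes valued for both tissues."""
    out = TraitMap()
    for node_id, value in numerator.values.items():
        if node_id in denominator.values:
            out.set(
                node_id,
                value - denominator.values[node_id],
                "ratio",
            )
    return out


def scaled_branch_changes(
    ct: GeneTree,
    traits: TraitMap,
    tissue: str,
    thresholds: Optional[ChangeThresholds] = None,
    species_branches: Optional[dict[int, str]] = None,
) -> list[BranchChangeRecord]:
    """One record per branch with both endpoints valued, for one trait.

    ``species_branches`` (child node id -> species branch label) attaches
    species-equivalent labels; branches whose calibrated length fell below
    the 1e-9 floor are flagged.
    """
    records = []
    for node in ct.preorder():
        if node.is_root:
            continue
        pv = traits.get(node.parent.id)
        cv = traits.get(node.id)
        if pv is None or cv is None:
            continue
        t_raw = node.parent.age - node.age
        floored = t_raw < TIME_FLOOR
        t = max(t_raw, TIME_FLOOR)
        delta = (cv - pv) / t
        records.append(
            BranchChangeRecord(
                tree_id=ct.tree_id,
                parent_node=node.parent.id,
                child_node=node.id,
                tissue=tissue,
                parent_value=pv,
                child_value=cv,
                time_length=t,
                scaled_change=delta,
                change_class=classify_change(delta, thresholds),
                species_branch=(species_branches or {}).get(node.id),
                floored=floored,
            )
        )
    return records


def find_species_equivalent_branches(
    gt: GeneTree, st: SpeciesTree
) -> dict[int, str]:
    """Map child-node ids of species-equivalent gene-tree branches to the
    letter label of the corresponding species-tree branch.

    Requires events, species-node mappings, null marks on the gene tree and
    branch labels on the species tree.  Tip branches are eligible (species
    leaves carry branch labels too).
    """
    mapping: dict[int, str] = {}
    for node in gt.preorder():
        if node.is_root:
            continue
        parent = node.parent
        if parent.event != "speciation" or parent.species_node is None:
            continue
        if node.is_leaf:
            child_snode = node.species_node  # the species leaf
        elif node.event == "speciation" and node.species_node is not None:
            child_snode = node.species_node
        else:
            continue
        if child_snode.parent is parent.species_node and child_snode.branch_label:
            mapping[node.id] = child_snode.branch_label
    return mapping


def tally_changes(records: Iterable[BranchChangeRecord]) -> pd.DataFrame:
    """Contingency counts per (species_branch, tissue, class).

    Only records with a species-equivalent label are tallied; classes with
    zero counts appear as zeros, and species branches absent under a given
    trait set simply have no rows (e.g. ratio traits on species lacking the
    denominator tissue).
    """
    rows = [
        {
            "species_branch": r.species_branch,
            "tissue": r.tissue,
            "change_class": r.change_class,
        }
        for r in records
        if r.species_branch is not None
    ]
    if not rows:
        return pd.DataFrame(
            columns=["species_branch", "tissue", "negative", "neutral", "positive", "total"]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["species_branch", "tissue", "change_class"])
        .size()
        .unstack("change_class", fill_value=0)
    )
    for cls in ("negative", "neutral", "positive"):
        if cls not in counts.columns:
            counts[cls] = 0
    counts = counts[["negative", "neutral", "positive"]]
    counts["total"] = counts.sum(axis=1)
    return counts.reset_index()


def mean_branch_counts(tally: pd.DataFrame) -> pd.Series:
    """Mean (over tissues) number of species-equivalent branches per
    species branch — the Table-1-style summary."""
    if tally.empty:
        return pd.Series(dtype=float, name="mean_branches")
    out = tally.groupby("species_branch")["total"].mean()
    out.name = "mean_branches"
    return out


def records_frame(records: Iterable[BranchChangeRecord]) -> pd.DataFrame:
    """Long-format records table (the supplementary-style export)."""
    return pd.DataFrame(
        [
            {
                "tree_id": r.tree_id,
                "parent_node": r.parent_node,
                "child_node": r.child_node,
                "tissue": r.tissue,
                "parent_value": r.parent_value,
                "child_value": r.child_value,
                "time_length": r.time_length,
                "scaled_change": r.scaled_change,
                "change_class": r.change_class,
                "species_branch": r.species_branch or "",
                "floored": int(r.floored),
            }
            for r in records
        ]
    )
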