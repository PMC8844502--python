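"""Species tree filtering: strict-ortholog extraction and two-factor
variance partitioning into species-variable (SVG) and tissue-variable (TVG)
genes.

A *strict ortholog* group has exactly one gene per listed species and a
connecting gene-tree subtree containing only (non-null) speciation events.
For each group, expression values on a species x tissue grid are decomposed
with an additive two-factor linear model; each factor's share is its sum of
squares adjusted for the other factor (type-II, order-invariant) divided by
the total sum of squares.  A gene is an SVG when species + tissue together
explain more than 75% of the variance and the species share is more than
twice the tissue share; a TVG is the mirror image; everything else is
"other".

Model fitting is delegated to statsmodels (OLS + type-II ANOVA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .trees import GeneTree, Node

logger = logging.getLogger(__name__)


@dataclass
class SvgTvgThresholds:
    min_combined: float = 0.75
    dominance: float = 2.0


@dataclass
class VariancePartitionRecord:
    ortholog_id: str
    species_prop: float
    tissue_prop: float
    residual_prop: float
    label: str = ""


# ---------------------------------------------------------------------------
# strict orthologs
# ---------------------------------------------------------------------------

def extract_strict_orthologs(
    gene_trees: Iterable[GeneTree], species_list: Sequence[str]
) -> list[dict[str, str]]:
    """Strict-ortholog groups from annotated gene trees.

    A tree yields a group iff each species in ``species_list`` is
    represented by exactly one tip (single-copy in every listed species)
    and every internal node on the subtree connecting those tips is a
    plain speciation node (no duplication, no null).  A family duplicated
    ancestrally — even into two species-complete copies — is excluded:
    its lineages are not related only by speciation.
    """
    wanted = set(species_list)
    groups = []
    for gt in gene_trees:
        tips = [t for t in gt.leaves() if gt.tip_species(t) in wanted]
        species = [gt.tip_species(t) for t in tips]
        if len(tips) != len(wanted) or set(species) != wanted:
            continue
        # connecting (Steiner) subtree: union of tip-to-MRCA paths
        mrca = gt.mrca(tips)
        path_nodes: set[Node] = {mrca}
        for tip in tips:
            node = tip
            while node is not mrca:
                path_nodes.add(node)
                node = node.parent
        clean = all(
            n.is_leaf or n.event == "speciation" for n in path_nodes
        )
        if clean:
            groups.append({gt.tip_species(t): t.name for t in tips})
    return groups


def validate_ortholog_table(
    table: pd.DataFrame, species_list: Sequence[str]
) -> list[dict[str, str]]:
    """Validate an external single-copy table (columns = species, one gene
    per cell); rows with missing or duplicated species entries are rejected
    and logged."""
    groups = []
    missing_cols = [s for s in species_list if s not in table.columns]
    if missing_cols:
        raise ValueError(f"ortholog table missing species column(s): {missing_cols}")
    for idx, row in table.iterrows():
        genes = [row[s] for s in species_list]
        if any(pd.isna(g) or g == "" for g in genes):
            logger.warning("ortholog row %s rejected: missing gene", idx)
            continue
        if len(set(genes)) != len(genes):
            logger.warning("ortholog row %s rejected: duplicated gene id", idx)
            continue
        groups.append({s: row[s] for s in species_list})
    return groups


# ---------------------------------------------------------------------------
# variance partition
# ---------------------------------------------------------------------------

def variance_partition(
    values: pd.DataFrame, ortholog_id: str = ""
) -> VariancePartitionRecord:
    """Partition variance of one ortholog's species x tissue expression grid.

    ``values`` is a long DataFrame with columns ``species``, ``tissue``,
    ``value`` (one value per cell, already averaged over replicates), or a
    wide species-by-tissue frame.  Requires at least 2 species and 2
    tissues; incomplete grids should be dropped by the caller (complete-case
    analysis).  Constant values yield all-zero proportions.
    """
    df = _as_long(values)
    if df["species"].nunique() < 2 or df["tissue"].nunique() < 2:
        raise ValueError("need >=2 species and >=2 tissues")
    y = df["value"].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 0 or not np.isfinite(ss_total):
        return VariancePartitionRecord(ortholog_id, 0.0, 0.0, 0.0, "other")
    model = smf.ols("value ~ C(species) + C(tissue)", data=df).fit()
    table = anova_lm(model, typ=2)
    ss_species = float(table.loc["C(species)", "sum_sq"])
    ss_tissue = float(table.loc["C(tissue)", "sum_sq"])
    species_prop = ss_species / ss_total
    tissue_prop = ss_tissue / ss_total
    residual_prop = max(1.0 - species_prop - tissue_prop, 0.0)
    return VariancePartitionRecord(
        ortholog_id, species_prop, tissue_prop, residual_prop
    )


def _as_long(values: pd.DataFrame) -> pd.DataFrame:
    if {"species", "tissue", "value"}.issubset(values.columns):
        return values[["species", "tissue", "value"]].copy()
    long = values.stack().reset_index()
    long.columns = ["species", "tissue", "value"]
    return long


def classify_svg_tvg(
    record: VariancePartitionRecord,
    thresholds: Optional[SvgTvgThresholds] = None,
) -> VariancePartitionRecord:
    """SVG / TVG / other, per the combined-variance and dominance rules."""
    th = thresholds or SvgTvgThresholds()
    combined = record.species_prop + record.tissue_prop
    if combined > th.min_combined and record.species_prop > th.dominance * record.tissue_prop:
        record.label = "SVG"
    elif combined > th.min_combined and record.tissue_prop > th.dominance * record.species_prop:
        record.label = "TVG"
    else:
        record.label = "other"
    return record


def partition_all(
    expression: pd.DataFrame,
    groups: Sequence[dict[str, str]],
    thresholds: Optional[SvgTvgThresholds] = None,
) -> pd.DataFrame:
    """Variance-partition every strict-ortholog group with complete data.

    ``expression`` has genes as rows and a (species, tissue) MultiIndex of
    columns (e.g. summarized TPM10K); each group's grid stacks the per-
    species gene rows.  Groups with any missing cell are dropped (complete-
    case), mirroring a complete-grid requirement.
    """
    tissues = sorted(expression.columns.get_level_values("tissue").unique())
    rows = []
    for i, group in enumerate(groups):
        recs = []
        complete = True
        for species, gene in group.items():
            if gene not in expression.index or species not in expression.columns.get_level_values("species"):
                complete = False
                break
            sub = expression.loc[gene, species]
            for tissue in tissues:
                if tissue not in sub.index or pd.isna(sub[tissue]):
                    complete = False
                    break
                recs.append({"species": species, "tissue": tissue, "value": sub[tissue]})
            if not complete:
                break
        if not complete:
            continue
        rec = variance_partition(pd.DataFrame(recs), ortholog_id=f"og{i}")
        rec = classify_svg_tvg(rec, thresholds)
        rows.append(
            {
                "ortholog_id": rec.ortholog_id,
                "species_prop": rec.species_prop,
                "tissue_prop": rec.tissue_prop,
                "residual_prop": rec.residual_prop,
                "label": rec.label,
            }
        )
    return pd.DataFrame(rows)
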