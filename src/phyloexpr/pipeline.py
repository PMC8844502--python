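"""End-to-end orchestration of the branch-filtering analysis.

Chains the module stages on in-memory objects: annotate gene trees
(events, species-node mapping, null marks), screen them with the
pre-calibration filters, time-calibrate against the species tree, screen
again (root depth), reconstruct ancestral log-expression per tissue,
derive ratio traits against a denominator tissue, and emit classified
scaled-change records restricted to species-equivalent branches.

The CLI and the test surface both drive this module; it never mutates its
inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import asr, calibrate, changes, filters, reconcile
from .changes import BranchChangeRecord, ChangeThresholds
from .filters import FilterThresholds, TreeFilterReport
from .norm import ExpressionMatrix
from .trees import GeneTree, SpeciesTree, label_species_branches

logger = logging.getLogger(__name__)


@dataclass
class SbfResult:
    """Outcome of a branch-filtering run over a forest."""

    records: list = field(default_factory=list)
    reports: list = field(default_factory=list)           # TreeFilterReport per tree
    calibrated: dict = field(default_factory=dict)        # tree_id -> calibrated tree
    traits: dict = field(default_factory=dict)            # (tree_id, trait) -> TraitMap
    failures: list = field(default_factory=list)          # CalibrationFailure

    def records_frame(self) -> pd.DataFrame:
        return changes.records_frame(self.records)

    def tally(self) -> pd.DataFrame:
        return changes.tally_changes(self.records)

    def mean_branch_counts(self) -> pd.Series:
        return changes.mean_branch_counts(self.tally())


def tip_values_for(
    expr: ExpressionMatrix, gt: GeneTree, tissue_col: str
) -> dict[str, float]:
    """Observed values for a gene tree's tips from a summarized expression
    matrix with (species, tissue) columns: a tip named ``sp@gene`` reads the
    (sp, tissue) column at row ``sp@gene``."""
    values = {}
    table = expr.values
    for leaf in gt.leaves():
        sp = gt.tip_species(leaf)
        key = (sp, tissue_col)
        if key not in table.columns:
            continue
        if leaf.name in table.index:
            v = table.loc[leaf.name, key]
            if pd.notna(v):
                values[leaf.name] = float(v)
    return values


def run_sbf(
    gene_trees: Sequence[GeneTree],
    species_tree: SpeciesTree,
    logexpr: ExpressionMatrix,
    tissues: Optional[Sequence[str]] = None,
    ratio_denominator: Optional[str] = None,
    filter_thresholds: Optional[FilterThresholds] = None,
    change_thresholds: Optional[ChangeThresholds] = None,
    use_ratios: bool = True,
    use_raw: bool = True,
) -> SbfResult:
    """Run the full branch-level analysis over a forest.

    ``logexpr`` is the summarized log matrix (unit logTPM10K) whose row
    index matches gene-tree tip names and whose columns are
    (species, tissue).  Raw per-tissue traits and/or tissue-over-denominator
    ratio traits are analysed; ratio traits use only nodes valued for both
    tissues.
    """
    st = species_tree
    if not any(n.branch_label for n in st.preorder()):
        label_species_branches(st)
    if tissues is None:
        tissues = sorted(logexpr.values.columns.get_level_values("tissue").unique())
    fth = filter_thresholds or FilterThresholds()
    result = SbfResult()

    for gt in gene_trees:
        annotated = gt.copy()
        reconcile.annotate(annotated, st)

        report = filters.branch_length_summary(annotated)
        filters.annotation_summary(annotated, report)
        if report.max_len is None or len(annotated.leaves()) < 2:
            report.discard("degenerate_tree")
            result.reports.append(report)
            continue
        filters.apply_tree_filters(report, "pre-calibration", fth)
        if report.verdict == "discard":
            result.reports.append(report)
            continue

        ct = calibrate.calibrate_gene_tree(annotated, st)
        if isinstance(ct, calibrate.CalibrationFailure):
            result.failures.append(ct)
            report.discard("calibration_failure")
            result.reports.append(report)
            continue
        report.root_depth = calibrate.root_depth(ct)
        filters.apply_tree_filters(report, "post-calibration", fth)
        if report.verdict == "discard":
            result.reports.append(report)
            continue

        tissue_traits = {}
        for tissue in tissues:
            tips = tip_values_for(logexpr, ct, tissue)
            if len(tips) < fth.min_expression_tips:
                continue
            traits = asr.reconstruct_tissue(ct, tips, min_tips=fth.min_expression_tips)
            if traits is not None:
                tissue_traits[tissue] = traits
        report.n_expression_tips = max(
            (len([p for p in t.provenance.values() if p == "observed"])
             for t in tissue_traits.values()),
            default=0,
        )
        filters.apply_tree_filters(report, "post-pruning", fth)
        result.reports.append(report)
        if report.verdict == "discard":
            continue

        result.calibrated[ct.tree_id] = ct
        sp_branches = changes.find_species_equivalent_branches(ct, st)

        if use_raw:
            for tissue, traits in tissue_traits.items():
                result.traits[(ct.tree_id, tissue)] = traits
                result.records.extend(
                    changes.scaled_branch_changes(
                        ct, traits, tissue, change_thresholds, sp_branches
                    )
                )
        if use_ratios and ratio_denominator and ratio_denominator in tissue_traits:
            denom = tissue_traits[ratio_denominator]
            for tissue, traits in tissue_traits.items():
                if tissue == ratio_denominator:
                    continue
                rt = changes.ratio_trait(traits, denom)
                label = f"{tissue}/{ratio_denominator}"
                result.traits[(ct.tree_id, label)] = rt
                result.records.extend(
                    changes.scaled_branch_changes(
                        ct, rt, label, change_thresholds, sp_branches
                    )
                )
    return result
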