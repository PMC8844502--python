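"""Gene-tree exclusion rules with per-tree reasons.

Trees are screened at three stages with the following defaults:

* pre-calibration — discard if the maximum branch length exceeds 2 or more
  than 25% of branches sit at the default length 1e-6 (either condition
  suffices; the pair is configurable to a conjunction), if null nodes exceed
  0.3 per internal node, or if the tree has no speciation event at all;
* post-calibration — discard if the root age exceeds 5 (species-tree root
  is 1), indicative of calibration problems;
* post-pruning — discard if fewer than 3 tips carry expression values.

All statistics exclude the root edge, whose length is not meaningful on a
rooted Newick tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .trees import DEFAULT_BRANCH_LENGTH, GeneTree

STAGES = ("pre-calibration", "post-calibration", "post-pruning")


@dataclass
class FilterThresholds:
    max_branch_length: float = 2.0
    max_default_fraction: float = 0.25
    length_rule_mode: str = "or"  # "or": either violation discards; "and": both
    max_null_per_internal: float = 0.3
    min_speciation_nodes: int = 1
    max_root_depth: float = 5.0
    min_expression_tips: int = 3


@dataclass
class TreeFilterReport:
    tree_id: str = ""
    max_len: Optional[float] = None
    min_len: Optional[float] = None
    sd_len: Optional[float] = None
    default_fraction: Optional[float] = None
    null_per_internal: Optional[float] = None
    n_speciation: Optional[int] = None
    root_depth: Optional[float] = None
    n_expression_tips: Optional[int] = None
    verdict: str = "keep"
    reasons: list = field(default_factory=list)

    def discard(self, reason: str) -> None:
        self.verdict = "discard"
        if reason not in self.reasons:
            self.reasons.append(reason)


def branch_length_summary(gt: GeneTree, report: Optional[TreeFilterReport] = None
                          ) -> TreeFilterReport:
    """Branch-length statistics over all non-root branches.

    ``default_fraction`` counts branches whose length equals the upstream
    default 1e-6 exactly (the placeholder for zero-length branches).
    """
    if report is None:
        report = TreeFilterReport(tree_id=gt.tree_id)
    lengths = np.array(
        [n.length for n in gt.preorder() if not n.is_root and n.length is not None]
    )
    if lengths.size:
        report.max_len = float(lengths.max())
        report.min_len = float(lengths.min())
        report.sd_len = float(lengths.std())
        report.default_fraction = float((lengths == DEFAULT_BRANCH_LENGTH).mean())
    return report


def annotation_summary(gt: GeneTree, report: Optional[TreeFilterReport] = None
                       ) -> TreeFilterReport:
    """Speciation counts and null-per-internal-node ratio (after annotation)."""
    if report is None:
        report = TreeFilterReport(tree_id=gt.tree_id)
    internal = gt.internal_nodes()
    n_null = sum(1 for n in internal if n.event == "null")
    report.n_speciation = sum(1 for n in internal if n.event == "speciation")
    report.null_per_internal = n_null / len(internal) if internal else 0.0
    return report


def apply_tree_filters(
    report: TreeFilterReport,
    stage: str,
    thresholds: Optional[FilterThresholds] = None,
) -> TreeFilterReport:
    """Apply the stage's discard rules to a (partially filled) report.

    Thresholds are strict inequalities throughout: e.g. a default fraction of
    exactly 0.25 is kept.  A field required by the stage but absent from the
    report is an error.
    """
    th = thresholds or FilterThresholds()
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")

    def need(attr: str):
        value = getattr(report, attr)
        if value is None:
            raise ValueError(f"stage {stage!r} requires report field {attr!r}")
        return value

    if stage == "pre-calibration":
        long_branch = need("max_len") > th.max_branch_length
        many_defaults = need("default_fraction") > th.max_default_fraction
        if th.length_rule_mode == "or":
            if long_branch:
                report.discard("long_branch")
            if many_defaults:
                report.discard("default_fraction")
        else:
            if long_branch and many_defaults:
                report.discard("long_branch+default_fraction")
        if need("null_per_internal") > th.max_null_per_internal:
            report.discard("null_fraction")
        if need("n_speciation") < th.min_speciation_nodes:
            report.discard("no_speciation")
    elif stage == "post-calibration":
        if need("root_depth") > th.max_root_depth:
            report.discard("deep_root")
    else:  # post-pruning
        if need("n_expression_tips") < th.min_expression_tips:
            report.discard("few_expression_tips")
    return report


def report_row(report: TreeFilterReport) -> dict:
    return {
        "tree_id": report.tree_id,
        "max_len": report.max_len,
        "min_len": report.min_len,
        "sd_len": report.sd_len,
        "default_fraction": report.default_fraction,
        "null_per_internal": report.null_per_internal,
        "n_speciation": report.n_speciation,
        "root_depth": report.root_depth,
        "n_expression_tips": report.n_expression_tips,
        "verdict": report.verdict,
        "reasons": ";".join(report.reasons),
    }
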