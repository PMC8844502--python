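"""Flat-file formats: TSV tables and Newick forests.

Conventions:

* counts / lengths — TSV, rows = genes (first column ``gene``), columns =
  libraries;
* metadata — TSV with columns ``library, species, tissue, stage, replicate``
  (``run``/``lane`` optional);
* flags — TSV with columns ``gene, is_rRNA, is_protein_coding``;
* expression — TSV whose first line is a ``#`` comment recording the unit
  (and pseudocount/log base where applicable); summarized matrices use
  ``species|tissue`` column headers;
* forest — TSV with columns ``tree_id, newick`` (NHX annotations allowed).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .norm import CountMatrix, ExpressionMatrix, SampleMetadata
from .trees import GeneTree, read_newick, write_newick

COLSEP = "|"


def read_counts(counts_path, lengths_path, flags_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)
    if lengths.shape[1] == 1:
        lengths = lengths.iloc[:, 0]
    flags = None
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0)
        for col in ("is_rRNA", "is_protein_coding"):
            flags[col] = flags[col].astype(bool)
    return CountMatrix(counts=counts, effective_length=lengths, gene_flags=flags)


def read_metadata(path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", index_col="library")
    return SampleMetadata(table)


def write_expression(expr: ExpressionMatrix, path) -> None:
    header = f"# unit={expr.unit}"
    if expr.pseudocount is not None:
        header += f" pseudocount={expr.pseudocount:g}"
    if expr.log_base is not None:
        base = "e" if math.isclose(expr.log_base, math.e) else f"{expr.log_base:g}"
        header += f" log_base={base}"
    values = expr.values.copy()
    if isinstance(values.columns, pd.MultiIndex):
        values.columns = [COLSEP.join(map(str, c)) for c in values.columns]
    with open(path, "w") as fh:
        fh.write(header + "\n")
        values.to_csv(fh, sep="\t", index_label="gene")


def read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        values = pd.read_csv(fh, sep="\t", index_col=0)
    fields = dict(
        part.split("=", 1) for part in header.lstrip("# ").split() if "=" in part
    )
    unit = fields.get("unit", "TPM10K")
    pseudocount = float(fields["pseudocount"]) if "pseudocount" in fields else None
    log_base = None
    if "log_base" in fields:
        log_base = math.e if fields["log_base"] == "e" else float(fields["log_base"])
    if any(COLSEP in c for c in values.columns):
        values.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split(COLSEP, 1)) for c in values.columns],
            names=["species", "tissue"],
        )
    return ExpressionMatrix(
        values=values, unit=unit, pseudocount=pseudocount, log_base=log_base
    )


def read_forest(path, separator: str = "@") -> list[GeneTree]:
    """Forest TSV (tree_id, newick) -> list of gene trees."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    forest = []
    for _, row in table.iterrows():
        forest.append(
            read_newick(
                row["newick"], kind="gene", separator=separator,
                tree_id=row["tree_id"], is_path=False,
            )
        )
    return forest


def write_forest(forest, path, nhx: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write("tree_id\tnewick\n")
        for gt in forest:
            fh.write(f"{gt.tree_id}\t{write_newick(gt, nhx=nhx)}\n")
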