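"""Expression normalization: gene filtering, TPM, TPM10K, replicate
summarization, and denominator-tissue expression ratios.

TPM makes libraries comparable within one species but its mean depends on the
reference gene count *n*, so raw TPM is not comparable across species whose
references differ in completeness.  TPM10K rescales:

    TPM10K_i = TPM_i * n / 1e4

so that the per-library mean is 100 regardless of *n* (the sum becomes
100 * n).  Within-species tissue ratios then cancel any unknown per-(gene,
species) counting-efficiency factor, because that factor multiplies every
library of the species equally and ratios are taken within species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TPM_SUM = 1e6
TPM10K_MEAN = 100.0
TPM10K_DIVISOR = 1e4


class NormalizationError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Raw expected counts and effective lengths, genes x libraries.

    ``effective_length`` may be a per-gene Series (shared across libraries) or
    a DataFrame aligned with ``counts``; ``gene_flags`` carries the boolean
    columns ``is_rRNA`` and ``is_protein_coding`` indexed by gene.
    """

    counts: pd.DataFrame
    effective_length: Union[pd.DataFrame, pd.Series]
    gene_flags: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if not self.counts.index.is_unique:
            raise NormalizationError("gene identifiers must be unique")
        vals = self.counts.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise NormalizationError("counts must be finite and non-negative")
        lengths = self.lengths_frame().to_numpy(dtype=float)
        if ((vals > 0) & ~(lengths > 0)).any():
            raise NormalizationError(
                "effective lengths must be positive wherever counts are positive"
            )

    def lengths_frame(self) -> pd.DataFrame:
        if isinstance(self.effective_length, pd.Series):
            return pd.DataFrame(
                np.tile(
                    self.effective_length.reindex(self.counts.index).to_numpy()[:, None],
                    (1, self.counts.shape[1]),
                ),
                index=self.counts.index,
                columns=self.counts.columns,
            )
        return self.effective_length.reindex(
            index=self.counts.index, columns=self.counts.columns
        )

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns


@dataclass
class ExpressionMatrix:
    """Expression values per (gene, sample) in a declared unit."""

    values: pd.DataFrame
    unit: str  # TPM | TPM10K | logTPM10K | logRatio
    n_reference_genes: Optional[Mapping[str, int]] = None
    pseudocount: Optional[float] = None
    log_base: Optional[float] = None


@dataclass
class SampleMetadata:
    """Maps each library to species/tissue/stage/replicate descriptors."""

    table: pd.DataFrame  # indexed by library

    REQUIRED = ("species", "tissue")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise NormalizationError(f"metadata missing required column {col!r}")
        if not self.table.index.is_unique:
            raise NormalizationError("each library must have exactly one metadata row")

    def validate_against(self, libraries) -> None:
        missing = [lib for lib in libraries if lib not in self.table.index]
        if missing:
            raise NormalizationError(f"libraries without metadata: {missing}")

    def species_of(self, library: str) -> str:
        return self.table.loc[library, "species"]

    def tissue_of(self, library: str) -> str:
        return self.table.loc[library, "tissue"]


def filter_genes(cm: CountMatrix) -> CountMatrix:
    """Drop rRNA and non-protein-coding genes and genes expressed in <2 libraries.

    A gene is retained iff it is flagged protein-coding, not rRNA, and has a
    count greater than zero in at least two libraries.  Gene order is
    preserved.
    """
    if cm.gene_flags is None:
        raise NormalizationError("gene_flags required for filtering")
    flags = cm.gene_flags
    missing = cm.genes.difference(flags.index)
    if len(missing):
        raise NormalizationError(
            f"gene flags missing for gene(s): {', '.join(map(str, missing[:5]))}"
        )
    flags = flags.reindex(cm.genes)
    expressed = (cm.counts > 0).sum(axis=1) >= 2
    keep = (~flags["is_rRNA"].astype(bool)) & flags["is_protein_coding"].astype(bool) & expressed
    lengths = cm.effective_length
    if isinstance(lengths, pd.Series):
        lengths = lengths.loc[keep[keep].index]
    else:
        lengths = lengths.loc[keep[keep].index]
    return CountMatrix(
        counts=cm.counts.loc[keep],
        effective_length=lengths,
        gene_flags=flags.loc[keep],
    )


def compute_tpm(cm: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million: 1e6 * (count/length) / sum(count/length) per library."""
    counts = cm.counts.to_numpy(dtype=float)
    lengths = cm.lengths_frame().to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(counts > 0, counts / lengths, 0.0)
    colsum = rate.sum(axis=0)
    zero = colsum <= 0
    if zero.any():
        bad = cm.libraries[zero].tolist()
        raise NormalizationError(f"library with all-zero counts: {bad}")
    tpm = TPM_SUM * rate / colsum
    return ExpressionMatrix(
        values=pd.DataFrame(tpm, index=cm.genes, columns=cm.libraries),
        unit="TPM",
    )


def compute_tpm10k(
    tpm: ExpressionMatrix,
    n_reference: Union[int, Mapping[str, int]],
    meta: Optional[SampleMetadata] = None,
) -> ExpressionMatrix:
    """Rescale TPM by n/1e4 where n is the species' reference gene count.

    ``n_reference`` is either a single integer (one species) or a mapping
    species -> n, in which case ``meta`` resolves each library's species.
    The reference count is the full (pre-filtering) size of the reference,
    supplied explicitly rather than inferred from the matrix.
    """
    if tpm.unit != "TPM":
        raise NormalizationError(f"expected unit TPM, got {tpm.unit}")
    if isinstance(n_reference, Mapping):
        if meta is None:
            raise NormalizationError("per-species n_reference requires sample metadata")
        meta.validate_against(tpm.values.columns)
        n_per_lib = np.array(
            [float(n_reference[meta.species_of(lib)]) for lib in tpm.values.columns]
        )
        n_map = dict(n_reference)
    else:
        n_per_lib = np.full(tpm.values.shape[1], float(n_reference))
        n_map = {"*": int(n_reference)}
    if (n_per_lib <= 0).any():
        raise NormalizationError("reference gene count n must be positive")
    values = tpm.values * (n_per_lib / TPM10K_DIVISOR)
    return ExpressionMatrix(values=values, unit="TPM10K", n_reference_genes=n_map)


def summarize_and_log(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    pseudocount: float = 1.0,
    log_base: float = math.e,
) -> ExpressionMatrix:
    """Mean TPM10K across replicates of each (species, tissue), then log.

    Output columns are a (species, tissue) MultiIndex.  With pseudocount 0,
    zero means produce -inf which is replaced by NaN (dropped downstream)
    with a warning.
    """
    if expr.unit != "TPM10K":
        raise NormalizationError(f"expected unit TPM10K, got {expr.unit}")
    meta.validate_against(expr.values.columns)
    groups: dict[tuple, list[str]] = {}
    for lib in expr.values.columns:
        key = (meta.species_of(lib), meta.tissue_of(lib))
        groups.setdefault(key, []).append(lib)
    cols = {}
    for key in sorted(groups):
        mean = expr.values[groups[key]].mean(axis=1)
        with np.errstate(divide="ignore"):
            logged = np.log(mean + pseudocount) / np.log(log_base)
        if pseudocount == 0:
            n_zero = int(np.isneginf(logged).sum())
            if n_zero:
                logger.warning(
                    "%d zero mean(s) in %s dropped under pseudocount 0", n_zero, key
                )
            logged = logged.replace(-np.inf, np.nan)
        cols[key] = logged
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["species", "tissue"])
    return ExpressionMatrix(
        values=values, unit="logTPM10K", pseudocount=pseudocount, log_base=log_base
    )


def summarize_mean(expr: ExpressionMatrix, meta: SampleMetadata) -> ExpressionMatrix:
    """Mean TPM10K across replicates per (species, tissue), no log.

    The linear-scale companion of :func:`summarize_and_log`, used by the
    variance-partition analysis which works on TPM10K values directly.
    """
    if expr.unit != "TPM10K":
        raise NormalizationError(f"expected unit TPM10K, got {expr.unit}")
    meta.validate_against(expr.values.columns)
    groups: dict[tuple, list[str]] = {}
    for lib in expr.values.columns:
        key = (meta.species_of(lib), meta.tissue_of(lib))
        groups.setdefault(key, []).append(lib)
    cols = {key: expr.values[libs].mean(axis=1) for key, libs in sorted(groups.items())}
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns, names=["species", "tissue"])
    return ExpressionMatrix(values=values, unit="TPM10K",
                            n_reference_genes=expr.n_reference_genes)


def expression_ratio(
    expr: ExpressionMatrix, denominator_tissue: str
) -> ExpressionMatrix:
    """Within-species log-ratios against a denominator tissue.

    For each species that sampled the denominator tissue, every other tissue
    column becomes ``log(tissue) - log(denominator)``; species lacking the
    denominator contribute no ratio columns.  Because an unknown per-(gene,
    species) counting-efficiency factor shifts all of a species' log columns
    equally, it cancels exactly in these differences.
    """
    if expr.unit != "logTPM10K":
        raise NormalizationError(f"expected unit logTPM10K, got {expr.unit}")
    if denominator_tissue not in expr.values.columns.get_level_values("tissue"):
        raise NormalizationError(
            f"denominator tissue {denominator_tissue!r} absent from every species"
        )
    cols = {}
    for species in expr.values.columns.get_level_values("species").unique():
        sub = expr.values[species]
        if denominator_tissue not in sub.columns:
            logger.warning(
                "species %s lacks denominator tissue %s; no ratios",
                species, denominator_tissue,
            )
            continue
        denom = sub[denominator_tissue]
        for tissue in sub.columns:
            if tissue == denominator_tissue:
                continue
            cols[(species, f"{tissue}/{denominator_tissue}")] = sub[tissue] - denom
    values = pd.DataFrame(cols)
    if cols:
        values.columns = pd.MultiIndex.from_tuples(
            values.columns, names=["species", "tissue"]
        )
    return ExpressionMatrix(values=values, unit="logRatio", log_base=expr.log_base)
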