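"""Normalization: gene filters, TPM/TPM10K identities, replicate
summarization, and efficiency-cancelling ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from phyloexpr import (
    CountMatrix,
    SampleMetadata,
    compute_tpm,
    compute_tpm10k,
    expression_ratio,
    filter_genes,
    summarize_and_log,
)
from phyloexpr.norm import NormalizationError, summarize_mean

from conftest import make_metadata


def cm_from_arrays(counts, lengths=None, flags=None, genes=None, libs=None):
    counts = np.asarray(counts, dtype=float)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    libs = libs or [f"lib{j}" for j in range(counts.shape[1])]
    counts_df = pd.DataFrame(counts, index=genes, columns=libs)
    if lengths is None:
        lengths = np.ones_like(counts)
    lengths_df = pd.DataFrame(np.asarray(lengths, dtype=float), index=genes, columns=libs)
    flags_df = None
    if flags is not None:
        flags_df = pd.DataFrame(flags, index=genes)
    else:
        flags_df = pd.DataFrame(
            {"is_rRNA": False, "is_protein_coding": True}, index=genes
        )
    return CountMatrix(counts=counts_df, effective_length=lengths_df, gene_flags=flags_df)


class TestFilterGenes:
    def test_planted_violations_enumerated_by_hand(self):
        # 10 genes; g0 is rRNA, g1 not protein coding, g2 expressed in 1
        # library only -> 7 survivors, order preserved
        counts = np.ones((10, 3))
        counts[2] = [5, 0, 0]
        flags = pd.DataFrame(
            {"is_rRNA": [True] + [False] * 9,
             "is_protein_coding": [True, False] + [True] * 8},
            index=[f"g{i}" for i in range(10)],
        )
        cm = cm_from_arrays(counts, flags=flags)
        kept = filter_genes(cm)
        assert list(kept.genes) == [f"g{i}" for i in (3, 4, 5, 6, 7, 8, 9)]

    def test_expression_threshold_is_at_least_two_libraries(self):
        cm = cm_from_arrays([[5, 0, 0], [1, 1, 0]], genes=["solo", "pair"])
        kept = filter_genes(cm)
        assert list(kept.genes) == ["pair"]

    def test_missing_flags_error_names_gene(self):
        cm = cm_from_arrays([[1, 1], [2, 2]], genes=["known", "mystery"])
        cm.gene_flags = cm.gene_flags.drop("mystery")
        with pytest.raises(NormalizationError, match="mystery"):
            filter_genes(cm)

    def test_no_flags_configuration_error(self):
        cm = cm_from_arrays([[1, 1]])
        cm.gene_flags = None
        with pytest.raises(NormalizationError):
            filter_genes(cm)


class TestTpm:
    def test_equal_counts_equal_lengths_split_evenly(self):
        tpm = compute_tpm(cm_from_arrays([[10], [10]]))
        assert np.allclose(tpm.values.to_numpy().ravel(), [5e5, 5e5])

    def test_length_normalization_equalizes_rates(self):
        tpm = compute_tpm(cm_from_arrays([[10], [20]], lengths=[[1], [2]]))
        assert np.allclose(tpm.values.to_numpy().ravel(), [5e5, 5e5])

    def test_column_sums_are_one_million_on_random_libraries(self):
        rng = np.random.default_rng(42)
        counts = rng.poisson(20.0, size=(50, 1000)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1  # guard empty rows only
        lengths = rng.uniform(200, 5000, size=(50, 1000))
        tpm = compute_tpm(cm_from_arrays(counts, lengths=lengths))
        sums = tpm.values.sum(axis=0).to_numpy()
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_all_zero_library_error_names_library(self):
        cm = cm_from_arrays([[1, 0], [1, 0]], libs=["ok", "empty"])
        with pytest.raises(NormalizationError, match="empty"):
            compute_tpm(cm)


class TestTpm10k:
    def test_uniform_library_gives_mean_100(self):
        tpm = compute_tpm(cm_from_arrays([[1], [1], [1], [1]]))
        t10k = compute_tpm10k(tpm, 4)
        assert np.allclose(t10k.values.to_numpy().ravel(), [100, 100, 100, 100])

    def test_two_gene_arithmetic(self):
        tpm = compute_tpm(cm_from_arrays([[1], [0.0]]))
        # counts (1, 0) -> TPM (1e6, 0); n=2 -> (200, 0)
        t10k = compute_tpm10k(tpm, 2)
        assert np.allclose(t10k.values.to_numpy().ravel(), [200.0, 0.0])

    def test_column_means_100_within_1e9_relative(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(30.0, size=(80, 200)).astype(float) + 1
        lengths = rng.uniform(200, 5000, size=(80, 200))
        tpm = compute_tpm(cm_from_arrays(counts, lengths=lengths))
        t10k = compute_tpm10k(tpm, 80)
        means = t10k.values.mean(axis=0).to_numpy()
        assert np.allclose(means, 100.0, rtol=1e-9)

    def test_nonpositive_n_rejected(self):
        tpm = compute_tpm(cm_from_arrays([[1], [1]]))
        with pytest.raises(NormalizationError):
            compute_tpm10k(tpm, 0)


def small_tpm10k():
    meta = make_metadata(["spX"], ["t1", "t2", "t3"], 2)
    libs = list(meta.table.index)
    values = pd.DataFrame(
        [[10.0, 30.0, 1.0, 3.0, 99.0, 101.0]],
        index=["g0"], columns=libs,
    )
    from phyloexpr import ExpressionMatrix

    return ExpressionMatrix(values=values, unit="TPM10K"), meta


class TestSummarizeAndLog:
    def test_mean_then_log_with_pseudocount(self):
        expr, meta = small_tpm10k()
        out = summarize_and_log(expr, meta, pseudocount=1.0)
        assert out.unit == "logTPM10K"
        # replicates (10, 30) -> log(21); (1, 3) -> log(3); (99, 101) -> log(101)
        expected = [math.log(21), math.log(3), math.log(101)]
        assert np.allclose(out.values.loc["g0"].to_numpy(), expected)

    def test_single_replicate(self):
        meta = make_metadata(["spX"], ["t1"], 1)
        from phyloexpr import ExpressionMatrix

        expr = ExpressionMatrix(
            values=pd.DataFrame([[7.0]], index=["g0"], columns=meta.table.index),
            unit="TPM10K",
        )
        out = summarize_and_log(expr, meta)
        assert np.isclose(out.values.iloc[0, 0], math.log(8))

    def test_replicate_order_invariance(self):
        expr, meta = small_tpm10k()
        shuffled = expr.values[list(expr.values.columns[::-1])]
        from phyloexpr import ExpressionMatrix

        out1 = summarize_and_log(expr, meta)
        out2 = summarize_and_log(ExpressionMatrix(values=shuffled, unit="TPM10K"), meta)
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_log_base_configurable(self):
        expr, meta = small_tpm10k()
        out = summarize_and_log(expr, meta, pseudocount=1.0, log_base=2)
        assert np.isclose(out.values.loc["g0"].iloc[0], math.log2(21))

    def test_summarize_mean_keeps_linear_scale(self):
        expr, meta = small_tpm10k()
        out = summarize_mean(expr, meta)
        assert out.unit == "TPM10K"
        assert np.allclose(out.values.loc["g0"].to_numpy(), [20.0, 2.0, 100.0])


class TestExpressionRatio:
    def logexpr(self, values, species, tissues, genes=None):
        from phyloexpr import ExpressionMatrix

        cols = pd.MultiIndex.from_product([species, tissues],
                                          names=["species", "tissue"])
        genes = genes or [f"g{i}" for i in range(np.asarray(values).shape[0])]
        return ExpressionMatrix(
            values=pd.DataFrame(values, index=genes, columns=cols),
            unit="logTPM10K",
        )

    def test_equal_values_give_zero_ratio(self):
        expr = self.logexpr([[2.0, 2.0]], ["spX"], ["palpon", "gastrozooid"])
        out = expression_ratio(expr, "gastrozooid")
        assert out.values.iloc[0, 0] == 0.0

    def test_log_ratio_is_difference(self):
        expr = self.logexpr([[5.0, 3.0]], ["spX"], ["palpon", "gastrozooid"])
        out = expression_ratio(expr, "gastrozooid")
        assert out.values.iloc[0, 0] == 2.0

    def test_counting_efficiency_cancels_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(3, 1, size=(5, 6))
        expr = self.logexpr(base, ["s1", "s2"], ["a", "b", "gastrozooid"])
        shifted = expr.values.copy()
        # multiply gene g2's TPM10K by e in every tissue of s1: +1 in log
        for tissue in ("a", "b", "gastrozooid"):
            shifted.loc["g2", ("s1", tissue)] += 1.0
        from phyloexpr import ExpressionMatrix

        out1 = expression_ratio(expr, "gastrozooid")
        out2 = expression_ratio(
            ExpressionMatrix(values=shifted, unit="logTPM10K"), "gastrozooid"
        )
        # algebraically exact; floating point leaves ~1 ulp from the shift
        assert np.allclose(out1.values, out2.values, atol=1e-12, rtol=0)

    def test_species_without_denominator_has_no_columns(self):
        from phyloexpr import ExpressionMatrix

        cols = pd.MultiIndex.from_tuples(
            [("s1", "a"), ("s1", "gastrozooid"), ("s2", "a"), ("s2", "b")],
            names=["species", "tissue"],
        )
        expr = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g0"], columns=cols),
            unit="logTPM10K",
        )
        out = expression_ratio(expr, "gastrozooid")
        assert list(out.values.columns.get_level_values("species")) == ["s1"]

    def test_denominator_absent_everywhere_is_error(self):
        expr = self.logexpr([[1.0, 2.0]], ["s1"], ["a", "b"])
        with pytest.raises(NormalizationError):
            expression_ratio(expr, "gastrozooid")
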