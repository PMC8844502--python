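"""Simulators: BM moments, duplication-loss forests, counting efficiencies,
multinomial libraries, and determinism."""

import numpy as np
import pandas as pd
import pytest

from phyloexpr import (
    CountMatrix,
    Scenario,
    balanced_species_tree,
    compute_tpm,
    compute_tpm10k,
    empirical_bm_params,
    generate_scenario,
    read_newick,
    simulate_bm,
    simulate_counts,
    simulate_efficiencies,
    simulate_gene_trees,
)
from phyloexpr.simulate import simulate_gene_tree

from conftest import make_metadata


class TestBm:
    def test_zero_variance_is_constant(self, congruent_gt):
        values = simulate_bm(congruent_gt, 3.0, 0.0, seed=0)
        assert set(values.values()) == {3.0}

    def test_tip_variance_matches_sigma2_t(self):
        gt = read_newick("(A@1:0.5,B@1:2.0);", kind="gene", is_path=False)
        tip = gt.find_leaf("B@1")
        rng = np.random.default_rng(1)
        draws = [simulate_bm(gt, 0.0, 1.5, seed=rng)[tip.id] for _ in range(10000)]
        assert abs(np.var(draws) / (1.5 * 2.0) - 1) < 0.05

    def test_tip_covariance_matches_shared_path(self):
        gt = read_newick("((A@1:0.5,B@1:0.5):0.75,C@1:1.25);", kind="gene",
                         is_path=False)
        a, b = gt.find_leaf("A@1"), gt.find_leaf("B@1")
        rng = np.random.default_rng(2)
        draws = np.array(
            [
                [simvals[a.id], simvals[b.id]]
                for simvals in (
                    simulate_bm(gt, 0.0, 2.0, seed=rng) for _ in range(10000)
                )
            ]
        )
        cov = np.cov(draws.T)[0, 1]
        assert abs(cov / (2.0 * 0.75) - 1) < 0.05

    def test_negative_sigma2_rejected(self, congruent_gt):
        with pytest.raises(ValueError):
            simulate_bm(congruent_gt, 0.0, -1.0, seed=0)

    def test_seed_reproducibility(self, congruent_gt):
        v1 = simulate_bm(congruent_gt, 0.0, 1.0, seed=99)
        v2 = simulate_bm(congruent_gt, 0.0, 1.0, seed=99)
        assert v1 == v2


class TestEmpiricalParams:
    def test_constant_tips_zero_sigma(self, congruent_gt):
        values = {t.name: 4.0 for t in congruent_gt.leaves()}
        root, sigma2 = empirical_bm_params(congruent_gt, values)
        assert root == 4.0 and sigma2 == 0.0

    def test_two_tip_arithmetic(self):
        gt = read_newick("(A@1:1.0,B@1:1.0);", kind="gene", is_path=False)
        root, sigma2 = empirical_bm_params(gt, {"A@1": 0.0, "B@1": 2.0})
        assert root == 1.0
        assert sigma2 == 2.0  # sample variance (n-1) over mean depth 1

    def test_recovery_within_30_percent(self):
        # 50-tip star-ish tree via a large simulated family
        st = balanced_species_tree(7)
        gt = None
        for seed in range(40):
            cand = simulate_gene_tree(st, 2.5, 0.0, seed=seed,
                                      subst_gamma_shape=None)
            if cand is not None and len(cand.leaves()) >= 50:
                gt = cand
                break
        assert gt is not None
        true_sigma2 = 1.0
        rng = np.random.default_rng(3)
        estimates = []
        for _ in range(200):
            values = simulate_bm(gt, 0.0, true_sigma2, seed=rng)
            tipmap = {t.name: values[t.id] for t in gt.leaves()}
            estimates.append(empirical_bm_params(gt, tipmap)[1])
        assert abs(np.mean(estimates) / true_sigma2 - 1) < 0.3


class TestGeneTreeSimulator:
    def test_zero_rates_give_congruent_speciation_only_trees(self, st7):
        forest = simulate_gene_trees(st7, 0.0, 0.0, 10, seed=5)
        assert len(forest) == 10
        for gt in forest:
            assert len(gt.leaves()) == 7
            assert all(
                n.extra["true_event"] == "speciation" for n in gt.internal_nodes()
            )
            species = sorted(gt.tip_species(t) for t in gt.leaves())
            assert species == sorted(st7.species())

    def test_no_loss_keeps_at_least_one_tip_per_species(self, st7):
        forest = simulate_gene_trees(st7, 0.5, 0.0, 20, seed=6)
        for gt in forest:
            assert len(gt.leaves()) >= 7

    def test_mean_tip_count_grows_with_duplication_rate(self):
        st = balanced_species_tree(4)
        means = []
        for rate in (0.0, 0.5, 1.0):
            forest = simulate_gene_trees(st, rate, 0.0, 200, seed=7)
            means.append(np.mean([len(gt.leaves()) for gt in forest]))
        assert means[0] < means[1] < means[2]

    def test_determinism_under_seed(self, st7):
        from phyloexpr import write_newick

        f1 = simulate_gene_trees(st7, 0.4, 0.2, 10, seed=8)
        f2 = simulate_gene_trees(st7, 0.4, 0.2, 10, seed=8)
        assert [write_newick(t) for t in f1] == [write_newick(t) for t in f2]


class TestCounts:
    def setup_exact(self, efficiencies=None):
        genes = [f"spX@g{i}" for i in range(5)]
        meta = make_metadata(["spX"], ["t1", "t2"], 1)
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(
            rng.uniform(1, 100, size=(5, 2)),
            index=genes, columns=meta.table.index,
        )
        if efficiencies is None:
            efficiencies = pd.DataFrame(1.0, index=genes, columns=["spX"])
        return expr, efficiencies, meta

    def test_unit_efficiency_recovers_true_tpm(self):
        expr, eff, meta = self.setup_exact()
        cm = simulate_counts(expr, eff, meta, effective_length=500.0,
                             library_size=10**6, seed=0, exact=True)
        tpm = compute_tpm(cm)
        for lib in expr.columns:
            ratio = tpm.values[lib] / expr[lib]
            assert np.allclose(ratio, ratio.iloc[0])

    def test_efficiency_cancels_in_expected_ratios(self):
        # doubling one gene's efficiency perturbs the TPM normalizing sums,
        # which shifts every gene's log-ratio by the same library-pair
        # constant; gene-relative log-ratios are exactly invariant
        expr, eff, meta = self.setup_exact()
        eff2 = eff.copy()
        eff2.iloc[0, 0] = 2.0
        kwargs = dict(meta=meta, effective_length=500.0, library_size=10**6,
                      seed=0, exact=True)
        t1 = compute_tpm(simulate_counts(expr, eff, **kwargs)).values
        t2 = compute_tpm(simulate_counts(expr, eff2, **kwargs)).values
        r1 = np.log(t1[expr.columns[0]]) - np.log(t1[expr.columns[1]])
        r2 = np.log(t2[expr.columns[0]]) - np.log(t2[expr.columns[1]])
        assert np.allclose(r1 - r1.mean(), r2 - r2.mean(), atol=1e-9)

    def test_efficiency_exactly_invariant_under_shared_composition(self):
        # with multiplicative tissue effects (x_gt = a_g * b_t) the
        # normalizing sums scale identically in both tissues, so log-ratios
        # are exactly invariant to arbitrary per-(gene, species) efficiencies
        genes = [f"spX@g{i}" for i in range(6)]
        meta = make_metadata(["spX"], ["t1", "t2"], 1)
        rng = np.random.default_rng(13)
        a = rng.uniform(1, 50, size=6)
        b = {"t1": 1.0, "t2": 3.5}
        expr = pd.DataFrame(
            {lib: a * b[meta.tissue_of(lib)] for lib in meta.table.index},
            index=genes,
        )
        eff1 = pd.DataFrame(1.0, index=genes, columns=["spX"])
        eff2 = pd.DataFrame(
            np.exp(rng.normal(0, 1, size=(6, 1))), index=genes, columns=["spX"]
        )
        kwargs = dict(meta=meta, effective_length=500.0, library_size=10**6,
                      seed=0, exact=True)
        t1 = compute_tpm(simulate_counts(expr, eff1, **kwargs)).values
        t2 = compute_tpm(simulate_counts(expr, eff2, **kwargs)).values
        libs = list(meta.table.index)
        r1 = np.log(t1[libs[0]]) - np.log(t1[libs[1]])
        r2 = np.log(t2[libs[0]]) - np.log(t2[libs[1]])
        assert np.allclose(r1, r2, atol=1e-12)

    def test_library_size_conserved_exactly(self):
        expr, eff, meta = self.setup_exact()
        cm = simulate_counts(expr, eff, meta, library_size=12345, seed=1)
        assert (cm.counts.sum(axis=0) == 12345).all()

    def test_correlation_with_truth_improves_with_depth(self):
        expr, eff, meta = self.setup_exact()
        cors = []
        for size in (10**3, 10**6):
            cm = simulate_counts(expr, eff, meta, effective_length=500.0,
                                 library_size=size, seed=2)
            tpm = compute_tpm(cm)
            lib = expr.columns[0]
            cors.append(np.corrcoef(tpm.values[lib], expr[lib])[0, 1])
        assert cors[1] > cors[0]
        assert cors[1] > 0.999

    def test_zero_expectation_rejected(self):
        expr, eff, meta = self.setup_exact()
        expr.iloc[:, 0] = 0.0
        with pytest.raises(ValueError, match=str(expr.columns[0])):
            simulate_counts(expr, eff, meta, seed=0)


class TestScenario:
    def test_scenario_is_reproducible_and_complete(self):
        sc = Scenario(n_trees=5, seed=42)
        d1 = generate_scenario(sc)
        d2 = generate_scenario(sc)
        sp = d1.species_tree.species()
        assert set(d1.counts) <= set(sp)
        for s in d1.counts:
            pd.testing.assert_frame_equal(d1.counts[s].counts, d2.counts[s].counts)
        assert d1.n_reference == {
            s: sum(
                1 for gt in d1.gene_trees for t in gt.leaves()
                if gt.tip_species(t) == s
            )
            for s in sp
        }
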