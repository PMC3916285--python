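"""Cohort differential expression, permutation correction, classifiers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfica.association import IcaModule, modules_from_loadings
from tfica.cohort import (collapse_probes, combined_classifier, differential_t,
                          module_de_test, permutation_bias_correction,
                          cohort_projection_test)
from tfica.synthetic import generate_dataset

from conftest import null_config, planted_config


def _cohort(rng, n_genes=200, n_case=30, n_control=30, shift_genes=(), shift=0.0):
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_control)]
    x = rng.normal(size=(n_genes, n_case + n_control))
    expr = pd.DataFrame(x, index=genes, columns=cols)
    labels = pd.Series(["case"] * n_case + ["control"] * n_control, index=cols)
    if shift_genes:
        expr.loc[list(shift_genes), labels == "case"] += shift
    return expr, labels


class TestCollapseProbes:
    def test_one_probe_per_gene_identity(self):
        rng = np.random.default_rng(0)
        probes = pd.DataFrame(rng.normal(size=(3, 4)),
                              index=["p1", "p2", "p3"],
                              columns=list("abcd"))
        out = collapse_probes(probes, {"p1": "g1", "p2": "g2", "p3": "g3"})
        np.testing.assert_allclose(out.loc[["g1", "g2", "g3"]].to_numpy(),
                                   probes.to_numpy())

    def test_median_of_three(self):
        probes = pd.DataFrame({"s": [1.0, 2.0, 9.0]}, index=["p1", "p2", "p3"])
        out = collapse_probes(probes, {p: "g" for p in probes.index})
        assert out.loc["g", "s"] == 2.0

    def test_matches_sort_median_oracle(self):
        rng = np.random.default_rng(1)
        probes = pd.DataFrame(rng.normal(size=(30, 5)),
                              index=[f"p{i}" for i in range(30)],
                              columns=list("abcde"))
        pmap = {f"p{i}": f"g{i % 10}" for i in range(30)}
        out = collapse_probes(probes, pmap)
        for g in out.index:
            rows = [p for p, gg in pmap.items() if gg == g]
            for c in probes.columns:
                vals = sorted(probes.loc[rows, c])
                assert out.loc[g, c] == pytest.approx(vals[len(vals) // 2])

    def test_unmapped_probe_dropped(self):
        probes = pd.DataFrame({"s": [1.0, 2.0]}, index=["p1", "px"])
        out = collapse_probes(probes, {"p1": "g1"})
        assert list(out.index) == ["g1"]


class TestDifferentialT:
    def test_equal_means_small_t(self):
        rng = np.random.default_rng(2)
        expr, labels = _cohort(rng, n_genes=500, n_case=200, n_control=200)
        de = differential_t(expr, labels)
        assert de["t"].abs().mean() < 1.5
        assert de["t"].abs().median() < 1.0

    def test_planted_shift_large_t(self):
        rng = np.random.default_rng(3)
        shift_genes = [f"g{i}" for i in range(30)]
        expr, labels = _cohort(rng, n_case=50, n_control=50,
                               shift_genes=shift_genes, shift=2.0)
        de = differential_t(expr, labels)
        assert de.loc[shift_genes, "t"].abs().median() > 5

    def test_matches_pooled_formula(self):
        """Closed-form pooled-variance t on 20 random genes."""
        rng = np.random.default_rng(4)
        expr, labels = _cohort(rng, n_genes=20)
        de = differential_t(expr, labels)
        case = (labels == "case").to_numpy()
        for g in expr.index:
            x = expr.loc[g].to_numpy()[case]
            y = expr.loc[g].to_numpy()[~case]
            n1, n2 = len(x), len(y)
            sp2 = (((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                   / (n1 + n2 - 2))
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert de.loc[g, "t"] == pytest.approx(t, rel=1e-10)

    def test_zero_variance_flagged(self):
        rng = np.random.default_rng(5)
        expr, labels = _cohort(rng, n_genes=5)
        expr.iloc[0] = 3.0
        de = differential_t(expr, labels)
        assert bool(de["degenerate"].iloc[0])
        assert not de["degenerate"].iloc[1:].any()


class TestModuleDeTest:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(500):
            expr, labels = _cohort(rng, n_genes=120, n_case=10, n_control=10)
            de = differential_t(expr, labels)
            ps.append(module_de_test(de, [f"g{i}" for i in range(15)]).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_module_significant(self):
        rng = np.random.default_rng(7)
        members = [f"g{i}" for i in range(30)]
        expr, labels = _cohort(rng, n_genes=500, n_case=40, n_control=40,
                               shift_genes=members, shift=1.5)
        de = differential_t(expr, labels)
        assert module_de_test(de, members).p < 0.01

    def test_module_covering_all_genes_errors(self):
        rng = np.random.default_rng(8)
        expr, labels = _cohort(rng, n_genes=20)
        de = differential_t(expr, labels)
        with pytest.raises(ValueError):
            module_de_test(de, list(expr.index))

    def test_too_few_members_errors(self):
        rng = np.random.default_rng(9)
        expr, labels = _cohort(rng, n_genes=20)
        de = differential_t(expr, labels)
        with pytest.raises(ValueError):
            module_de_test(de, ["g0", "g1"])


class TestPermutationCorrection:
    def _de(self, rng, n_genes=200):
        expr, labels = _cohort(rng, n_genes=n_genes, n_case=15, n_control=15)
        return differential_t(expr, labels)

    def test_observed_below_all_null_gives_p_one(self):
        rng = np.random.default_rng(10)
        de = self._de(rng)
        # members deliberately the least-DE genes
        members = list(de["t"].abs().nsmallest(10).index)
        universe = list(de.index)
        p = permutation_bias_correction(de, members, universe, n_perm=200, seed=0)
        assert p > 0.9

    def test_observed_above_all_null_gives_add_one_bound(self):
        rng = np.random.default_rng(11)
        de = self._de(rng)
        members = list(de["t"].abs().nlargest(10).index)
        universe = list(de.index)
        p = permutation_bias_correction(de, members, universe, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_bias_removed_vs_naive(self):
        """All module genes mildly shifted: naive set test rejects, the
        permutation p against the module-gene universe does not."""
        rng = np.random.default_rng(12)
        module_universe = [f"g{i}" for i in range(100)]  # all module genes
        members = module_universe[:30]
        expr, labels = _cohort(rng, n_genes=400, n_case=40, n_control=40,
                               shift_genes=module_universe, shift=0.8)
        de = differential_t(expr, labels)
        naive_p = module_de_test(de, members).p
        perm_p = permutation_bias_correction(de, members, module_universe,
                                             n_perm=500, seed=0)
        assert perm_p > naive_p

    def test_universe_smaller_than_module_errors(self):
        rng = np.random.default_rng(13)
        de = self._de(rng, n_genes=30)
        with pytest.raises(ValueError):
            permutation_bias_correction(de, list(de.index[:20]),
                                        list(de.index[:10]), n_perm=100)

    def test_valid_under_null(self):
        """Rejection rate at alpha = 0.05 within binomial noise (500 reps)."""
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 500
        for rep in range(n_rep):
            expr, labels = _cohort(rng, n_genes=150, n_case=8, n_control=8)
            de = differential_t(expr, labels)
            members = [f"g{i}" for i in range(12)]
            universe = [f"g{i}" for i in range(60)]
            p = permutation_bias_correction(de, members, universe,
                                            n_perm=199, seed=rep)
            rejections += p <= 0.05
        rate = rejections / n_rep
        sd = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 2 * sd


class TestProjectionTest:
    def test_planted_shift_significant(self):
        cfg = planted_config(seed=51, cohort_effect_size=1.0)
        ds = generate_dataset(cfg)
        mods = modules_from_loadings(ds.loadings)
        mod = next(iter(sorted(ds.truth.true_de_modules)))
        _, p = cohort_projection_test(ds.cohort, ds.cohort_labels, mods[mod])
        assert p < 0.01

    def test_null_p_uniform(self):
        rng = np.random.default_rng(15)
        ps = []
        members = [f"g{i}" for i in range(10)]
        mod = IcaModule("m", {g: 1.0 for g in members})
        for _ in range(300):
            expr, labels = _cohort(rng, n_genes=30, n_case=12, n_control=12)
            _, p = cohort_projection_test(expr, labels, mod,
                                          alternative="two-sided")
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_gene_module_is_scaled_row(self):
        rng = np.random.default_rng(16)
        expr, labels = _cohort(rng, n_genes=5)
        mod = IcaModule("m", {"g2": 1.7})
        proj, _ = cohort_projection_test(expr, labels, mod)
        np.testing.assert_allclose(proj.to_numpy(),
                                   1.7 * expr.loc["g2"].to_numpy())


class TestCombinedClassifier:
    def test_label_like_projection_gives_high_auroc(self):
        rng = np.random.default_rng(17)
        expr, labels = _cohort(rng, n_genes=10)
        y = (labels == "case").astype(float).to_numpy()
        expr.loc["g0"] = y + rng.normal(scale=0.01, size=len(y))
        mod = IcaModule("m", {"g0": 1.0})
        out = combined_classifier(expr, labels, "g1", mod)
        res = {r.metric: r for r in out["results"]}
        assert res["module_projection"].auroc > 0.99

    @pytest.mark.parametrize("seed", range(20))
    def test_complementary_features_combined_wins(self, seed):
        rng = np.random.default_rng(100 + seed)
        expr, labels = _cohort(rng, n_genes=30, n_case=40, n_control=40)
        y = (labels == "case").astype(float).to_numpy()
        expr.loc["g0"] = y + rng.normal(scale=1.0, size=len(y))  # TF gene
        members = [f"g{i}" for i in range(1, 11)]
        expr.loc[members, labels == "case"] += 0.5
        mod = IcaModule("m", {g: 1.0 for g in members})
        out = combined_classifier(expr, labels, "g0", mod)
        res = {r.metric: r.auroc for r in out["results"]}
        singles = max(res["tf_expression"], res["module_projection"])
        assert res["combined"] >= singles - 0.05

    def test_shuffled_labels_auroc_near_half(self):
        rng = np.random.default_rng(18)
        aurocs = []
        for _ in range(10):
            expr, labels = _cohort(rng, n_genes=30, n_case=40, n_control=40)
            shuffled = pd.Series(rng.permutation(labels.to_numpy()),
                                 index=labels.index)
            mod = IcaModule("m", {f"g{i}": 1.0 for i in range(1, 11)})
            out = combined_classifier(expr, shuffled, "g0", mod)
            aurocs += [r.auroc for r in out["results"]]
        assert np.all(np.abs(np.array(aurocs) - 0.5) < 0.15)
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_zscore_affine_invariance(self):
        rng = np.random.default_rng(19)
        expr, labels = _cohort(rng, n_genes=10)
        mod = IcaModule("m", {"g2": 1.0, "g3": 0.5})
        out1 = combined_classifier(expr, labels, "g0", mod)
        expr2 = expr.copy()
        expr2.loc["g0"] = 100 * expr.loc["g0"] - 7  # rescale the TF feature
        out2 = combined_classifier(expr2, labels, "g0", mod)
        s1 = next(r.scores for r in out1["results"] if r.metric == "combined")
        s2 = next(r.scores for r in out2["results"] if r.metric == "combined")
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)

    def test_planted_cohort_end_to_end(self):
        cfg = planted_config(seed=52, cohort_effect_size=1.0)
        ds = generate_dataset(cfg)
        mods = modules_from_loadings(ds.loadings)
        tf, mod, _ = cfg.planted_tf_module_pairs[0]
        out = combined_classifier(ds.cohort, ds.cohort_labels,
                                  ds.truth.tf_genes[tf], mods[mod])
        res = {r.metric: r.auroc for r in out["results"]}
        assert res["module_projection"] > 0.7
        assert res["combined"] > 0.7
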