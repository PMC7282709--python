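import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import squareform

import leptomet as lm
from leptomet.network import (
    ConditionCorrelations,
    DiffCoExParams,
    Module,
    cluster_modules,
    condition_correlations,
    diffcoex_dissimilarity,
    module_significance,
    split_submodules,
    submodule_pathway_enrichment,
)

from conftest import make_matrix


def corr_pair(c_pre, c_post):
    c_pre = np.asarray(c_pre, dtype=float)
    return ConditionCorrelations(c_pre, np.asarray(c_post, dtype=float),
                                 np.arange(c_pre.shape[0]))


class TestConditionCorrelations:
    def test_duplicate_metabolite_fully_correlated(self, toy_metadata):
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        m = make_matrix(np.column_stack([x, x, rng.normal(size=8)]),
                        toy_metadata.index, ["a", "b", "c"])
        c = condition_correlations(m, toy_metadata, DiffCoExParams())
        assert c.c_pre[0, 1] == pytest.approx(1.0)
        assert c.c_post[0, 1] == pytest.approx(1.0)

    def test_negated_metabolite_anticorrelated(self, toy_metadata):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        m = make_matrix(np.column_stack([x, -x]), toy_metadata.index, ["a", "b"])
        c = condition_correlations(m, toy_metadata, DiffCoExParams())
        assert c.c_pre[0, 1] == pytest.approx(-1.0)

    def test_spearman_equals_rank_then_pearson(self, toy_metadata):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 4))
        m = make_matrix(X, toy_metadata.index, list("abcd"))
        c = condition_correlations(m, toy_metadata, DiffCoExParams(correlation="spearman"))
        pre_rows = [k for k, s in enumerate(m.sample_ids) if s.endswith("_pre")]
        ranks = np.apply_along_axis(stats.rankdata, 0, X[pre_rows])
        oracle = np.corrcoef(ranks, rowvar=False)
        np.testing.assert_allclose(c.c_pre, oracle, atol=1e-12)

    def test_too_few_samples_rejected(self, toy_metadata):
        meta = toy_metadata.loc[["A_pre", "A_post", "B_pre", "B_post", "C_pre"]]
        m = make_matrix(np.random.default_rng(3).normal(size=(5, 2)), meta.index, ["a", "b"])
        with pytest.raises(ValueError, match="post"):
            condition_correlations(m, meta, DiffCoExParams())


class TestDiffcoexDissimilarity:
    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 5))
        C = np.corrcoef(X, rowvar=False)
        D = diffcoex_dissimilarity(corr_pair(C, C), beta=2.0)
        np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_maximal_flip_gives_one(self):
        c_pre = np.array([[1.0, 1.0], [1.0, 1.0]])
        c_post = np.array([[1.0, -1.0], [-1.0, 1.0]])
        for beta in (1.0, 2.0, 6.0):
            D = diffcoex_dissimilarity(corr_pair(c_pre, c_post), beta)
            assert D[0, 1] == pytest.approx(1.0)

    def test_hand_worked_value(self):
        c_pre = np.array([[1.0, 0.8], [0.8, 1.0]])
        c_post = np.eye(2)
        D = diffcoex_dissimilarity(corr_pair(c_pre, c_post), beta=2.0)
        assert D[0, 1] == pytest.approx(np.sqrt(0.5 * 0.64), abs=1e-12)

    def test_pseudometric_properties_and_reorder_invariance(self):
        rng = np.random.default_rng(5)
        X1, X2 = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
        C1, C2 = np.corrcoef(X1, rowvar=False), np.corrcoef(X2, rowvar=False)
        D = diffcoex_dissimilarity(corr_pair(C1, C2), beta=2.0)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert D.max() <= 1.0 and D.min() >= 0.0
        perm = rng.permutation(8)
        Dp = diffcoex_dissimilarity(corr_pair(C1[np.ix_(perm, perm)], C2[np.ix_(perm, perm)]), 2.0)
        np.testing.assert_allclose(Dp, D[np.ix_(perm, perm)], atol=1e-12)

    def test_condition_swap_invariance(self):
        rng = np.random.default_rng(6)
        X1, X2 = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        C1, C2 = np.corrcoef(X1, rowvar=False), np.corrcoef(X2, rowvar=False)
        np.testing.assert_allclose(
            diffcoex_dissimilarity(corr_pair(C1, C2), 2.0),
            diffcoex_dissimilarity(corr_pair(C2, C1), 2.0),
            atol=1e-12,
        )


class TestClusterModules:
    def _block_diss(self, sizes, within, between, rng):
        n = sum(sizes)
        D = rng.uniform(between - 0.02, between + 0.02, size=(n, n))
        start = 0
        for s in sizes:
            D[start : start + s, start : start + s] = rng.uniform(
                within - 0.02, within + 0.02, size=(s, s)
            )
            start += s
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        return D

    def test_two_planted_blocks_found_exactly(self):
        rng = np.random.default_rng(7)
        D = self._block_diss([10, 8], 0.05, 0.9, rng)
        mods = cluster_modules(D, DiffCoExParams())
        assert len(mods) == 2
        assert {frozenset(m.tolist()) for m in mods} == {
            frozenset(range(10)),
            frozenset(range(10, 18)),
        }

    def test_uniform_noise_yields_no_modules(self):
        params = DiffCoExParams(min_module_size=10)
        none = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            D = rng.uniform(0.45, 0.55, size=(40, 40))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            none += len(cluster_modules(D, params)) == 0
        assert none >= 18

    def test_small_block_goes_unassigned(self):
        rng = np.random.default_rng(8)
        D = self._block_diss([4, 20], 0.05, 0.9, rng)
        mods = cluster_modules(D, DiffCoExParams(min_module_size=5))
        assert all(not set(range(4)) & set(m.tolist()) for m in mods)

    def test_all_zero_dissimilarity(self):
        assert cluster_modules(np.zeros((10, 10)), DiffCoExParams()) == []


class TestSplitSubmodules:
    def test_anticorrelated_blocks_partitioned(self):
        C = np.ones((4, 4))
        C[:2, 2:] = -1.0
        C[2:, :2] = -1.0
        signs = split_submodules(C, np.arange(4))
        assert len(set(signs[:2])) == 1 and len(set(signs[2:])) == 1
        assert signs[0] != signs[2]

    def test_coherent_module_single_submodule(self):
        rng = np.random.default_rng(9)
        X = np.outer(rng.normal(size=6), np.ones(5)) + 0.1 * rng.normal(size=(6, 5))
        C = np.corrcoef(X, rowvar=False)
        assert (split_submodules(C, np.arange(5)) == 1).all()

    def test_matches_exhaustive_partition_oracle(self):
        # best 2-partition by (within - between) mean signed correlation
        rng = np.random.default_rng(10)
        f = rng.normal(size=6)
        signs_true = np.array([1, 1, 1, -1, -1, 1, -1, 1])
        X = np.outer(f, signs_true) + 0.4 * rng.normal(size=(6, 8))
        C = np.corrcoef(X, rowvar=False)

        best, best_val = None, -np.inf
        for assignment in itertools.product([1, -1], repeat=7):
            s = np.array((1,) + assignment)
            same = np.equal.outer(s, s)
            iu = np.triu_indices(8, 1)
            within = C[iu][same[iu]].mean()
            between = C[iu][~same[iu]].mean() if (~same[iu]).any() else 0.0
            if within - between > best_val:
                best_val, best = within - between, s
        got = split_submodules(C, np.arange(8))
        assert (got == best).all() or (got == -best).all()


class TestModuleSignificance:
    def _study(self, seed, loading):
        rng = np.random.default_rng(seed)
        n, m = 6, 15
        pre = rng.normal(0, 0.15, (n, m))
        post = rng.normal(0, 0.15, (n, m))
        if loading:
            signs = np.where(np.arange(m) < 8, 1.0, -1.0)
            post += loading * np.outer(rng.normal(size=n), signs)
        rows, data = [], []
        for i in range(n):
            for cond, x in (("pre", pre[i]), ("post", post[i])):
                rows.append(
                    {"sample_id": f"I{i}_{cond}", "individual_id": f"I{i}", "condition": cond,
                     "sex": "F", "age": 10.0, "ethnicity": "x", "run_day": "d1"}
                )
                data.append(x)
        meta = lm.dataio.validate_metadata(pd.DataFrame(rows))
        matrix = make_matrix(np.array(data), meta.index, [f"m{k}" for k in range(m)])
        return matrix, meta

    def test_null_size_is_63_for_six_individuals(self):
        matrix, meta = self._study(0, loading=0.0)
        module = Module(module_id=1, members=[f"m{k}" for k in range(15)])
        module_significance(matrix, meta, [module], DiffCoExParams())
        # p has resolution 1/64: achievable values are k/64
        assert (module.p_perm * 64) == pytest.approx(round(module.p_perm * 64))

    def test_planted_module_attains_floor(self):
        # global pre/post swap always ties the observed statistic, so the
        # smallest achievable p is 2/64; a strong post-only factor reaches it
        # in most seeds
        floor = 2 / 64
        hits = 0
        for seed in range(15):
            matrix, meta = self._study(seed, loading=0.9)
            module = Module(module_id=1, members=[f"m{k}" for k in range(15)])
            module_significance(matrix, meta, [module], DiffCoExParams())
            hits += module.p_perm <= floor + 1e-12
            assert module.gain > 0
        assert hits >= 9

    def test_null_p_uniform_over_achievable_grid(self):
        ps = []
        for seed in range(40):
            matrix, meta = self._study(100 + seed, loading=0.0)
            module = Module(module_id=1, members=[f"m{k}" for k in range(10)])
            module_significance(matrix, meta, [module], DiffCoExParams())
            ps.append(module.p_perm)
        ks = stats.kstest(ps, stats.uniform(loc=2 / 64, scale=62 / 64).cdf)
        assert ks.pvalue > 0.01


class TestSubmodulePathwayEnrichment:
    def test_pure_pathway_submodule_hypergeometric_point_mass(self):
        universe = [f"m{k}" for k in range(100)]
        ann = pd.DataFrame(
            {"metabolite_id": universe,
             "sub_pathway": ["target"] * 10 + ["other"] * 90}
        )
        out = submodule_pathway_enrichment(universe[:10], ann, universe)
        row = out.set_index("sub_pathway").loc["target"]
        from scipy.special import comb
        assert row["p_raw"] == pytest.approx(1.0 / comb(100, 10), rel=1e-9)

    def test_flat_table_no_association(self):
        universe = ["a", "b", "c", "d"]
        ann = pd.DataFrame({"metabolite_id": universe, "sub_pathway": ["p", "q", "p", "q"]})
        out = submodule_pathway_enrichment(["a", "b"], ann, universe)
        assert (out["p_raw"] == 1.0).all() or (out["odds_ratio"] == 1.0).all()

    def test_random_submodules_calibrated(self):
        rng = np.random.default_rng(12)
        universe = [f"m{k}" for k in range(200)]
        ann = pd.DataFrame(
            {"metabolite_id": universe, "sub_pathway": [f"p{k % 10}" for k in range(200)]}
        )
        ps = []
        for _ in range(60):
            sub = rng.choice(universe, 40, replace=False)
            ps.extend(submodule_pathway_enrichment(sub, ann, universe)["p_raw"])
        rate = np.mean(np.array(ps) < 0.05)
        assert rate <= 0.08  # exact test is conservative, never anti-conservative


class TestDiscoverModules:
    def test_planted_module_recovered_with_signs(self):
        config = lm.SimulationConfig.scaled_down(
            120, seed=5, missing_rate=0.0,
            sex_effect_sd=0.0, age_effect_sd=0.0, run_day_effect_sd=0.0,
        )
        matrix, annotations, metadata, truth = lm.simulate_study(config)
        mods, enr = lm.discover_modules(
            lm.impute_and_log(matrix), metadata, annotations=annotations
        )
        report = lm.recovery_report({"modules": mods}, truth)
        assert report["module_jaccard"] >= 0.8
        assert report["module_sign_accuracy"] >= 0.9
        assert report["module_p_perm"] <= 0.05
        assert enr is not None and {"module_id", "p_adj"} <= set(enr.columns)
        assert mods[-1].module_id == 0  # unassigned pseudo-module is reported
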