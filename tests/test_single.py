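import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from multifm.containers import ModelPosteriorTable
from multifm.single import (AbfContext, SingleTraitFineMapper, TagMap,
                            default_size_weights, expand_tag_models, log_abf,
                            model_prior, mpp, search_models, thin_by_ld)

from conftest import gwas_from_sample, hwe_genotypes, panel_from_R, sample_context


class TestThinByLd:
    def test_perfect_proxies_one_tag(self):
        panel = panel_from_R([[1, 1], [1, 1]], raf=[0.3, 0.2], snp_ids=["a", "b"])
        tm = thin_by_ld(panel)
        assert tm.tags == ["a"]
        assert set(tm.members["a"]) == {"a", "b"}

    def test_no_ld_every_snp_its_own_tag(self):
        panel = panel_from_R(np.eye(4), raf=[0.1, 0.2, 0.3, 0.4])
        tm = thin_by_ld(panel)
        assert len(tm.tags) == 4
        assert all(tm.members[t] == [t] for t in tm.tags)

    def test_greedy_not_transitive_chain(self):
        # r2: a-b 0.992, b-c 0.992, a-c 0.985 (PSD); maf order a > b > c
        r_ab = math.sqrt(0.992)
        r_ac = math.sqrt(0.985)
        R = [[1, r_ab, r_ac], [r_ab, 1, r_ab], [r_ac, r_ab, 1]]
        panel = panel_from_R(R, raf=[0.40, 0.35, 0.30], snp_ids=["a", "b", "c"])
        tm = thin_by_ld(panel, r2_threshold=0.99)
        assert tm.tags == ["a", "c"]
        assert set(tm.members["a"]) == {"a", "b"}
        assert tm.members["c"] == ["c"]

    def test_partition_property(self, study_pool):
        panel = study_pool.panel()
        tm = thin_by_ld(panel)
        members = [s for t in tm.tags for s in tm.members[t]]
        assert sorted(members) == sorted(panel.snp_ids)


class TestLogAbf:
    def test_null_model_is_zero(self):
        ctx = AbfContext(N=1000, var_y=1.0, r_scores=np.array([0.1]),
                         R=np.eye(1), snp_ids=["a"])
        assert log_abf((), ctx) == 0.0

    def test_single_snp_closed_form(self):
        ctx = AbfContext(N=1000, var_y=1.0, r_scores=np.array([0.1]),
                         R=np.eye(1), snp_ids=["a"])
        expected = -0.5 * (1000 * math.log(1 - 0.01) + math.log(1000))
        assert log_abf(("a",), ctx) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("size", [1, 2, 3])
    def test_matches_individual_level_bic(self, rng, size):
        """Summary-statistic ABF equals the BIC difference of explicit OLS fits."""
        import statsmodels.api as sm

        X = hwe_genotypes(rng, 500, [0.1, 0.2, 0.3, 0.4, 0.5])
        y = 0.3 * X[:, 0] - 0.2 * X[:, 3] + rng.standard_normal(500)
        ctx = sample_context(X, y)
        null_bic = sm.OLS(y, np.ones((500, 1))).fit().bic
        for model in combinations(range(5), size):
            fit = sm.OLS(y, sm.add_constant(X[:, list(model)])).fit()
            oracle = -0.5 * (fit.bic - null_bic)
            ours = log_abf([f"s{i}" for i in model], ctx)
            assert ours == pytest.approx(oracle, abs=1e-3)


class TestModelPrior:
    def test_formula(self):
        w = np.array([0.05, 0.55, 0.30, 0.10])
        assert model_prior(1, 100, w) == pytest.approx(0.55 / 100)
        assert model_prior(0, 100, w) == pytest.approx(0.05)

    def test_total_mass_is_one_by_enumeration(self):
        w = default_size_weights(3)
        total = sum(model_prior(m, 6, w) * math.comb(6, m) for m in range(4))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_size_beyond_support_errors(self):
        with pytest.raises(ValueError, match="size"):
            model_prior(4, 100, np.array([0.5, 0.5]))


def _sim_ctx_and_tagmap(rng, P=5, n=400):
    X = hwe_genotypes(rng, n, np.linspace(0.2, 0.4, P))
    y = 0.25 * X[:, 1] + rng.standard_normal(n)
    ctx = sample_context(X, y)
    tagmap = TagMap(tags=list(ctx.snp_ids),
                    members={s: [s] for s in ctx.snp_ids})
    return ctx, tagmap


class TestSearchModels:
    def test_exhaustive_counts(self, rng):
        ctx, tagmap = _sim_ctx_and_tagmap(rng)
        w = default_size_weights(2)
        out = search_models(ctx, tagmap, w, max_size=2, mode="exhaustive")
        assert len(out) == 1 + 5 + 10
        assert () in set(out["idx"])

    def test_beam_finds_exhaustive_top_model(self, rng):
        ctx, tagmap = _sim_ctx_and_tagmap(rng, P=8)
        w = default_size_weights(3)
        def top(mode):
            out = search_models(ctx, tagmap, w, max_size=3, mode=mode)
            score = out["log_abf"] + [math.log(model_prior(s, 8, w))
                                      for s in out["size"]]
            return out["idx"].iloc[int(np.argmax(score))]
        assert top("exhaustive") == top("greedy-beam")

    def test_max_size_zero_only_null(self, rng):
        ctx, tagmap = _sim_ctx_and_tagmap(rng)
        out = search_models(ctx, tagmap, default_size_weights(2), max_size=0)
        assert list(out["idx"]) == [()]


class TestExpandTagModels:
    def _ctx(self, rng, P=4):
        X = hwe_genotypes(rng, 400, [0.3] * P)
        y = 0.3 * X[:, 0] + rng.standard_normal(400)
        return sample_context(X, y)

    def test_single_tag_two_members(self, rng):
        ctx = self._ctx(rng)
        tagmap = TagMap(tags=["s0", "s2"],
                        members={"s0": ["s0", "s1"], "s2": ["s2", "s3"]})
        tag_models = pd.DataFrame({"idx": [(), (0,)], "size": [0, 1],
                                   "log_abf": [0.0, 5.0]})
        table = expand_tag_models(tag_models, tagmap, ctx,
                                  default_size_weights(2))
        models = set(table.df["snps"])
        assert models == {(), ("s0",), ("s1",)}

    def test_two_tags_two_members_each_gives_four(self, rng):
        ctx = self._ctx(rng)
        tagmap = TagMap(tags=["s0", "s2"],
                        members={"s0": ["s0", "s1"], "s2": ["s2", "s3"]})
        tag_models = pd.DataFrame({"idx": [(0, 2)], "size": [2],
                                   "log_abf": [5.0]})
        table = expand_tag_models(tag_models, tagmap, ctx,
                                  default_size_weights(2))
        assert set(table.df["snps"]) == {("s0", "s2"), ("s0", "s3"),
                                         ("s1", "s2"), ("s1", "s3")}

    def test_expanded_models_rescored_not_copied(self, rng):
        ctx = self._ctx(rng)
        tagmap = TagMap(tags=["s0"], members={"s0": ["s0", "s1"]})
        tag_models = pd.DataFrame({"idx": [(0,)], "size": [1],
                                   "log_abf": [999.0]})  # wrong on purpose
        table = expand_tag_models(tag_models, tagmap, ctx,
                                  default_size_weights(1), pp_floor=0.0)
        for snps, labf in zip(table.df["snps"], table.df["log_abf"]):
            assert labf == pytest.approx(log_abf(snps, ctx), abs=1e-10)

    def test_pps_sum_to_one(self, rng):
        ctx = self._ctx(rng)
        tagmap = TagMap(tags=list(ctx.snp_ids),
                        members={s: [s] for s in ctx.snp_ids})
        tag_models = search_models(ctx, tagmap, default_size_weights(2), 2)
        table = expand_tag_models(tag_models, tagmap, ctx, default_size_weights(2))
        assert table.df["pp"].sum() == pytest.approx(1.0, abs=1e-8)

    def test_expansion_cap(self, rng):
        ctx = self._ctx(rng)
        tagmap = TagMap(tags=["s0"], members={"s0": ["s0", "s1", "s2", "s3"]})
        tag_models = pd.DataFrame({"idx": [(0,)], "size": [1], "log_abf": [1.0]})
        with pytest.raises(ValueError, match="cap"):
            expand_tag_models(tag_models, tagmap, ctx, default_size_weights(1),
                              expansion_cap=3)


class TestMpp:
    def test_hand_computed_toy_table(self):
        df = pd.DataFrame({"snps": [("a", "b"), ("a",), ()],
                           "pp": [0.5, 0.3, 0.2]})
        table = ModelPosteriorTable(df, "t")
        m = mpp(table)
        assert m["a"] == pytest.approx(0.8)
        assert m["b"] == pytest.approx(0.5)

    def test_snp_in_every_nonnull_model(self):
        df = pd.DataFrame({"snps": [("a", "b"), ("a",), ()],
                           "pp": [0.5, 0.3, 0.2]})
        table = ModelPosteriorTable(df, "t")
        assert mpp(table)["a"] == pytest.approx(1 - table.null_pp())

    def test_absent_snp_zero(self):
        df = pd.DataFrame({"snps": [("a",), ()], "pp": [0.5, 0.5]})
        assert "z" not in mpp(ModelPosteriorTable(df, "t"))


class TestFineMapperEndToEnd:
    def test_pp_ordering_invariant_to_abf_shift(self):
        """Posterior ordering depends only on log-ABF differences."""
        df1 = pd.DataFrame({"snps": [("a",), ("b",), ()],
                            "log_abf": [3.0, 1.0, 0.0], "prior": [0.1, 0.1, 0.8]})
        for shift in (0.0, 50.0, -20.0):
            w = np.exp(df1["log_abf"] + shift - (df1["log_abf"] + shift).max())
            pp = w * df1["prior"]
            order = list(np.argsort(-pp / pp.sum()))
            assert order == [0, 2, 1]

    def test_strong_causal_attains_top_mpp(self, rng):
        """One strong causal variant (beta = 0.5 sd), no LD: the causal SNP
        has the top MPP in >= 95% of replications."""
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            X = rng.binomial(2, 0.3, size=(2000, 6)).astype(float)
            y = 0.5 * (X[:, 2] - X[:, 2].mean()) / X[:, 2].std() \
                + rng.standard_normal(2000)
            gwas = gwas_from_sample(X, y, ddof=1)
            from multifm.containers import ReferencePanel
            panel = ReferencePanel.from_dosage(X, gwas.snp_ids)
            res = SingleTraitFineMapper(gwas, panel, max_model_size=2,
                                        harmonised=True).fit()
            if res.mpp.index[0] == "s2":
                hits += 1
        assert hits / n_reps >= 0.95
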