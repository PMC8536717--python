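import math

import numpy as np
import pandas as pd
import pytest

from multifm.containers import (MissingnessDesign, ModelPosteriorTable,
                                SnpModel, TraitMoments)
from multifm.joint import (JointFineMapper, d_term, d_term_missing,
                           residual_c_hat, run_flashfm)
from multifm.prior import sharing_exponent
from multifm.single import AbfContext, default_size_weights

from conftest import gwas_from_sample, hwe_genotypes, sample_context


def _two_trait_sample(rng, n=1000, P=6, rho=0.4, betas1=None, betas2=None):
    X = hwe_genotypes(rng, n, np.linspace(0.2, 0.4, P))
    eps = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    b1 = np.zeros(P) if betas1 is None else np.asarray(betas1)
    b2 = np.zeros(P) if betas2 is None else np.asarray(betas2)
    y1 = X @ b1 + eps[:, 0]
    y2 = X @ b2 + eps[:, 1]
    ctx1, ctx2 = sample_context(X, y1), sample_context(X, y2)
    moments = TraitMoments(["t1", "t2"], np.cov(np.c_[y1, y2].T, ddof=0))
    return X, y1, y2, ctx1, ctx2, moments


class TestResidualCHat:
    def test_all_null_config_recovers_c_matrix(self, rng):
        *_, ctx1, ctx2, moments = _two_trait_sample(rng, n=500)
        c_hat = residual_c_hat([SnpModel(), SnpModel()], [ctx1, ctx2], moments)
        np.testing.assert_allclose(c_hat, moments.c_matrix, atol=1e-10)

    def test_independent_traits_off_diagonal_near_zero(self, rng):
        *_, ctx1, ctx2, moments = _two_trait_sample(
            rng, n=2000, rho=0.0, betas1=[0.3, 0, 0, 0, 0, 0])
        c_hat = residual_c_hat([SnpModel(("s0",)), SnpModel(("s1",))],
                               [ctx1, ctx2], moments)
        assert abs(c_hat[0, 1]) < 0.1
        np.testing.assert_allclose(np.diag(c_hat), 1.0, atol=1e-12)

    def test_matches_empirical_residual_covariance(self, rng):
        """C_hat from summary statistics matches the normalised empirical
        residual covariance of explicit per-trait least-squares fits."""
        X, y1, y2, ctx1, ctx2, moments = _two_trait_sample(
            rng, n=1000, betas1=[0.3, 0, 0, 0.2, 0, 0], betas2=[0.3, 0, 0.2, 0, 0, 0])
        config = [SnpModel(("s0", "s3")), SnpModel(("s0", "s2"))]
        resids = []
        for y, model in zip((y1, y2), config):
            idx = [int(s[1:]) for s in model.snps]
            A = np.c_[np.ones(len(y)), X[:, idx]]
            resids.append(y - A @ np.linalg.lstsq(A, y, rcond=None)[0])
        RC = np.cov(np.c_[resids[0], resids[1]].T, ddof=0)
        oracle = RC / np.diag(RC)[:, None]
        ours = residual_c_hat(config, [ctx1, ctx2], moments)
        np.testing.assert_allclose(ours, oracle, atol=0.02)


class TestDTerm:
    def test_zero_when_residual_structure_matches_traits(self, rng):
        *_, ctx1, ctx2, moments = _two_trait_sample(rng, n=500)
        assert d_term([SnpModel(), SnpModel()], [ctx1, ctx2], moments,
                      500) == pytest.approx(0.0, abs=1e-10)

    def test_formula_arithmetic(self):
        """|C| = 0.84, |C_hat| = 0.96, N = 1000 -> -500 (log 0.96 - log 0.84)."""
        ctx1 = AbfContext(N=1000, var_y=1.0, r_scores=np.array([0.6, 0.0]),
                          R=np.eye(2), snp_ids=["a", "b"])
        ctx2 = AbfContext(N=1000, var_y=1.0, r_scores=np.array([0.4, 0.0]),
                          R=np.eye(2), snp_ids=["a", "b"])
        moments = TraitMoments(["t1", "t2"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        # config ({a}, null): u = (0.4 - 0.6*0.4)/sqrt(1-0.36) = 0.2
        D = d_term([SnpModel(("a",)), SnpModel()], [ctx1, ctx2], moments, 1000)
        assert D == pytest.approx(-500 * (math.log(0.96) - math.log(0.84)),
                                  rel=1e-9)

    def test_joint_abf_matches_multivariate_bic_oracle(self, rng):
        """log ABF^M via the D-term equals the multivariate-regression BIC
        difference on individual-level data."""
        from multifm.single import log_abf

        X, y1, y2, ctx1, ctx2, moments = _two_trait_sample(
            rng, n=800, betas1=[0.25, 0, 0, 0, 0, 0.2],
            betas2=[0.25, 0.2, 0, 0, 0, 0])
        n = 800
        Y = np.c_[y1, y2]
        null_rss = np.cov(Y.T, ddof=0) * n

        def mv_bic(idx1, idx2):
            rss = []
            for y, idx in ((y1, idx1), (y2, idx2)):
                A = np.c_[np.ones(n), X[:, idx]] if idx else np.ones((n, 1))
                resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
                rss.append(resid)
            RC = np.cov(np.c_[rss[0], rss[1]].T, ddof=0) * n
            m = len(idx1) + len(idx2)
            return (n * (np.linalg.slogdet(RC / n)[1]
                         - np.linalg.slogdet(null_rss / n)[1]) + m * math.log(n))

        for idx1, idx2 in ([(0,), (0,)], [(0, 5), (0, 1)], [(2,), ()],
                           [(0, 5), (3,)]):
            c1 = [f"s{i}" for i in idx1]
            c2 = [f"s{i}" for i in idx2]
            config = [SnpModel(c1), SnpModel(c2)]
            ours = (log_abf(c1, ctx1) + log_abf(c2, ctx2)
                    + d_term(config, [ctx1, ctx2], moments, n))
            oracle = -0.5 * mv_bic(list(idx1), list(idx2))
            assert ours == pytest.approx(oracle, abs=0.1 * abs(oracle) + 0.5)


class TestDTermMissing:
    def _setup(self, rng):
        *_, ctx1, ctx2, moments = _two_trait_sample(
            rng, n=1000, betas1=[0.3, 0, 0, 0, 0, 0])
        config = [SnpModel(("s0",)), SnpModel(("s1",))]
        return config, [ctx1, ctx2], moments

    def test_complete_data_single_stratum(self, rng):
        config, ctxs, moments = self._setup(rng)
        miss = MissingnessDesign.complete(["t1", "t2"], 1000)
        assert d_term_missing(config, ctxs, ["t1", "t2"], moments, miss) == \
            pytest.approx(d_term(config, ctxs, moments, 1000))

    def test_no_shared_individuals_gives_zero(self, rng):
        config, ctxs, moments = self._setup(rng)
        ctxs[0].N, ctxs[1].N = 600, 400
        miss = MissingnessDesign({("t1",): 600, ("t2",): 400}, ["t1", "t2"])
        assert d_term_missing(config, ctxs, ["t1", "t2"], moments, miss) == 0.0

    def test_half_overlap_scales_n(self, rng):
        config, ctxs, moments = self._setup(rng)
        ctxs[0].N, ctxs[1].N = 1000, 500
        miss = MissingnessDesign({("t1", "t2"): 500, ("t1",): 500},
                                 ["t1", "t2"])
        assert d_term_missing(config, ctxs, ["t1", "t2"], moments, miss) == \
            pytest.approx(d_term(config, ctxs, moments, 500))

    def test_inconsistent_pattern_counts_rejected(self, rng):
        config, ctxs, moments = self._setup(rng)
        miss = MissingnessDesign({("t1", "t2"): 400}, ["t1", "t2"])
        with pytest.raises(ValueError, match="pattern counts"):
            d_term_missing(config, ctxs, ["t1", "t2"], moments, miss)


def _null_ctx(snp_ids, N=1000):
    return AbfContext(N=N, var_y=1.0, r_scores=np.zeros(len(snp_ids)),
                      R=np.eye(len(snp_ids)), snp_ids=list(snp_ids))


def _table(trait, models, pps):
    return ModelPosteriorTable(
        pd.DataFrame({"snps": models, "pp": pps}), trait)


class TestTraitAdjustedPP:
    def test_kappa_one_reduces_to_single_trait(self, rng):
        *_, ctx1, ctx2, moments = _two_trait_sample(
            rng, n=600, betas1=[0.3, 0, 0, 0, 0, 0], betas2=[0.3, 0, 0, 0, 0, 0])
        t1 = _table("t1", [("s0",), ("s1",), ()], [0.6, 0.25, 0.15])
        t2 = _table("t2", [("s0",), ("s2",), ()], [0.5, 0.3, 0.2])
        res = JointFineMapper({"t1": t1, "t2": t2}, {"t1": ctx1, "t2": ctx2},
                              moments, kappa=1.0, cpp=1.0).fit()
        for trait, table in (("t1", t1), ("t2", t2)):
            for snps, pp in zip(table.df["snps"], table.df["pp"]):
                assert res.trait_tables[trait].pp_of(snps) == \
                    pytest.approx(pp, abs=1e-12)

    def test_hand_enumerated_four_config_example(self):
        """Two traits x two single-SNP models, delta = tau = 1 (null scores,
        equal sizes), kappa = 2: adjusted pp follows PP_i (1 + share_i)."""
        ids = ["a", "b", "c"]
        ctx1, ctx2 = _null_ctx(ids), _null_ctx(ids)
        moments = TraitMoments(["t1", "t2"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        t1 = _table("t1", [("a",), ("b",)], [0.7, 0.3])
        t2 = _table("t2", [("a",), ("c",)], [0.4, 0.6])
        res = JointFineMapper({"t1": t1, "t2": t2}, {"t1": ctx1, "t2": ctx2},
                              moments, kappa=2.0, cpp=1.0).fit()
        # trait 1: model a shares with t2's a (pp 0.4): 0.7*(1+0.4); b: 0.3
        exp_a = 0.7 * 1.4 / (0.7 * 1.4 + 0.3)
        assert res.trait_tables["t1"].pp_of(("a",)) == pytest.approx(exp_a, rel=1e-12)
        # trait 2: model a shares with t1's a (pp 0.7)
        exp_a2 = 0.4 * 1.7 / (0.4 * 1.7 + 0.6)
        assert res.trait_tables["t2"].pp_of(("a",)) == pytest.approx(exp_a2, rel=1e-12)

    def _random_instance(self, rng):
        P = 6
        betas1 = np.zeros(P); betas1[rng.integers(P)] = 0.3
        betas2 = np.zeros(P); betas2[rng.integers(P)] = 0.3
        X, y1, y2, ctx1, ctx2, moments = _two_trait_sample(
            rng, n=400, rho=0.3, betas1=betas1, betas2=betas2)
        snps = ctx1.snp_ids

        def random_table(trait):
            models = [()]
            while len(models) < 4:
                m = tuple(sorted(rng.choice(snps, size=rng.integers(1, 3),
                                            replace=False)))
                if m not in models:
                    models.append(m)
            pps = rng.dirichlet(np.ones(len(models)))
            return _table(trait, models, pps)

        return (random_table("t1"), random_table("t2"),
                {"t1": ctx1, "t2": ctx2}, moments)

    def test_closed_form_equals_explicit_enumeration(self, rng):
        """The vectorised two-trait closed form agrees with a scalar
        configuration-by-configuration enumeration oracle."""
        for _ in range(100):
            t1, t2, ctxs, moments = self._random_instance(rng)
            kappa = float(rng.uniform(1.0, 40.0))
            jm = JointFineMapper({"t1": t1, "t2": t2}, ctxs, moments,
                                 kappa=kappa, cpp=1.0)
            res = jm.fit()
            miss = jm.missingness
            for this, other, ctx_pair, names in (
                    (t1, t2, [ctxs["t1"], ctxs["t2"]], ["t1", "t2"]),
                    (t2, t1, [ctxs["t2"], ctxs["t1"]], ["t2", "t1"])):
                adj = []
                for mi, pi in zip(this.df["snps"], this.df["pp"]):
                    w_k, w_1 = 0.0, 0.0
                    for mj, pj in zip(other.df["snps"], other.df["pp"]):
                        cfg = [SnpModel(mi), SnpModel(mj)]
                        mo = moments if names[0] == "t1" else moments.subset(names)
                        D = d_term_missing(cfg, ctx_pair, names, mo, miss)
                        tau = jm.sharing.tau((len(mi), len(mj)))
                        e = sharing_exponent(cfg)
                        w = math.exp(D) * tau * pj
                        w_1 += w
                        w_k += w * kappa ** e
                    adj.append(pi * w_k / w_1)
                adj = np.array(adj) / np.sum(adj)
                for m, a in zip(this.df["snps"], adj):
                    assert res.trait_tables[this.trait_name].pp_of(m) == \
                        pytest.approx(a, rel=1e-6, abs=1e-12)

    def test_two_trait_paths_agree(self, rng):
        """The M=2 closed form and the general-M grid route give identical
        adjusted posteriors."""
        for _ in range(20):
            t1, t2, ctxs, moments = self._random_instance(rng)
            jm = JointFineMapper({"t1": t1, "t2": t2}, ctxs, moments,
                                 kappa=float(rng.uniform(1, 30)), cpp=1.0)
            fits = jm._truncated_fits()
            two = jm._fit_two(fits)
            multi = jm._fit_multi(fits)
            for trait in two:
                np.testing.assert_allclose(two[trait], multi[trait],
                                           rtol=1e-9, atol=1e-12)

    def test_six_traits_capacity_and_reduction(self):
        ids = [f"s{i}" for i in range(8)]
        moments = TraitMoments([f"t{k}" for k in range(6)],
                               0.3 * np.ones((6, 6)) + 0.7 * np.eye(6))
        tables, ctxs = {}, {}
        for k in range(6):
            name = f"t{k}"
            tables[name] = _table(name, [(ids[k],), (ids[(k + 1) % 8],), ()],
                                  [0.5, 0.3, 0.2])
            ctxs[name] = _null_ctx(ids)
        res = JointFineMapper(tables, ctxs, moments, kappa=1.0, cpp=1.0).fit()
        assert res.diagnostics["n_configs"] == 3 ** 6
        for name, table in tables.items():
            for snps, pp in zip(table.df["snps"], table.df["pp"]):
                assert res.trait_tables[name].pp_of(snps) == pytest.approx(pp,
                                                                           abs=1e-12)

    def test_config_cap_enforced(self):
        ids = [f"s{i}" for i in range(4)]
        moments = TraitMoments(["t1", "t2"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        tables = {t: _table(t, [(s,) for s in ids], [0.25] * 4)
                  for t in ("t1", "t2")}
        ctxs = {t: _null_ctx(ids) for t in ("t1", "t2")}
        with pytest.raises(ValueError, match="cap"):
            JointFineMapper(tables, ctxs, moments, kappa=2.0, cpp=1.0,
                            config_cap=10).fit()


class TestRunFlashfm:
    def test_no_shared_signal_leaves_posteriors_unchanged(self, rng, study_pool):
        """Traits without shared causal variants: joint and single-trait
        posteriors agree to within mean |dPP| 0.05."""
        from multifm.simulate import distinct_design, gwas_scan, simulate_traits

        d = distinct_design(n=4000)
        X = study_pool.sample(4000, rng)
        traits = simulate_traits(X, study_pool.region, d.causal, 0.4, {}, rng)
        gwas = list(gwas_scan(X, traits, study_pool.region).values())
        moments = TraitMoments.from_traits(traits)
        res = run_flashfm(gwas, study_pool.panel(), moments,
                          max_model_size=3)
        for trait in ("trait1", "trait2"):
            adj = res.trait_tables[trait]
            single = res.single_tables[trait]
            norm = single.df["pp"].sum()
            diffs = [abs(adj.pp_of(m) - pp / norm)
                     for m, pp in zip(single.df["snps"], single.df["pp"])]
            assert np.mean(diffs) <= 0.05

    def test_null_trait_keeps_null_model_support(self, rng, study_pool):
        from multifm.simulate import calibration_design, gwas_scan, simulate_traits

        d = calibration_design(n=3000)
        X = study_pool.sample(3000, rng)
        traits = simulate_traits(X, study_pool.region, d.causal, 0.4, {}, rng)
        gwas = list(gwas_scan(X, traits, study_pool.region).values())
        moments = TraitMoments.from_traits(traits)
        res = run_flashfm(gwas, study_pool.panel(), moments, max_model_size=3)
        single = res.single_tables["trait2"]
        single_null = single.df.loc[single.df["snps"] == (), "pp"].sum() \
            / single.df["pp"].sum()
        assert res.trait_tables["trait2"].null_pp() >= single_null - 0.02
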