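"""Joint multi-trait fine-mapping from single-trait model posteriors.

The joint log Bayes factor of a cross-trait model configuration decomposes
as the sum of the marginal log ABFs plus a correction

    D_M = -N/2 * ( log|C_hat_M| - log|C_M| ),

where C_M is the row-normalised trait covariance (entry (i,j) =
Cov(i,j)/Var(i)) and C_hat_M is the same normalisation of the
configuration-specific residual covariance, reconstructed from summary
statistics: with standardised joint effects b_k = R_gk^-1 r_gk per trait,

    RC(k,l)/ (sd_k sd_l) = rho_kl - b_k' r^(l)_gk - b_l' r^(k)_gl
                           + b_k' R_{gk,gl} b_l ,

r^(l) being trait l's marginal score vector.  Determinant ratios only ever
involve the residual *correlation*, so trait scales cancel.

With missing trait measurements, D decomposes over missingness strata:
individuals observed for exactly the trait subset S contribute a D_S term
on the sub-configuration restricted to S, each individual entering exactly
one term; marginal ABFs are untouched.

Trait-adjusted model posteriors upweight configurations that share causal
variants.  For trait k, model i,

    PP_i^k  propto  PP_i * W_i(kappa) / W_i(1),
    W_i(kappa) = sum over configs with model i for trait k of
                 delta * tau * kappa^e * prod_{l != k} PP_l,

with delta = exp(D) and e the sharing exponent.  For two traits this is the
closed form PP_i * {1 + (kappa-1) * sum_{j sharing} delta tau PP_j /
sum_j delta tau PP_j}; at kappa = 1 the adjusted posteriors equal the
single-trait posteriors of the evaluated models exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import (MissingnessDesign, ModelPosteriorTable, ReferencePanel,
                         SnpModel, TraitMoments)
from .prior import SharingPrior, sharing_exponent
from .single import AbfContext, RIDGE, _fit_batch, default_size_weights

logger = logging.getLogger("multifm")

U_CLIP = 0.999


# ---------------------------------------------------------------------------
# per-configuration residual covariance and D term


def _joint_effects(model, ctx: AbfContext):
    """(indices, b_hat, explained fraction s) for one model under one trait."""
    snps = getattr(model, "snps", model)
    idx = np.asarray(ctx.index(snps), dtype=int)
    if idx.size == 0:
        return idx, np.zeros(0), 0.0
    b, s = _fit_batch(idx[None, :], ctx.R, ctx.r_scores)
    return idx, b[0], float(s[0])


def residual_c_hat(config, ctxs, trait_moments: TraitMoments) -> np.ndarray:
    """Configuration-specific residual analogue of C_M.

    ``config`` is one SnpModel per trait, ``ctxs`` the matching AbfContexts
    (all built on the same harmonised panel).  Returns the M x M matrix with
    entry (k,l) = RC(k,l) / RC(k,k); its diagonal is 1 and for the all-null
    configuration it equals C_M's correlation normalisation.
    """
    rc = residual_correlation(config, ctxs, trait_moments)
    sd = np.sqrt(np.diag(trait_moments.sigma))
    RC = rc * np.outer(sd, sd)
    return RC / np.diag(RC)[:, None]


def residual_correlation(config, ctxs, trait_moments: TraitMoments) -> np.ndarray:
    """Residual cross-trait covariance on the standardised-trait scale."""
    M = len(config)
    rho = trait_moments.correlation
    fits = [_joint_effects(m, ctx) for m, ctx in zip(config, ctxs)]
    rc = np.empty((M, M))
    for k in range(M):
        idx_k, b_k, s_k = fits[k]
        rc[k, k] = 1.0 - s_k
        for l in range(k + 1, M):
            idx_l, b_l, _ = fits[l]
            val = rho[k, l]
            if idx_k.size:
                val -= b_k @ ctxs[l].r_scores[idx_k]
            if idx_l.size:
                val -= b_l @ ctxs[k].r_scores[idx_l]
            if idx_k.size and idx_l.size:
                val += b_k @ ctxs[k].R[np.ix_(idx_k, idx_l)] @ b_l
            rc[k, l] = rc[l, k] = val
    w = np.linalg.eigvalsh(rc)
    if w.min() <= 0:
        logger.warning("residual covariance not positive-definite "
                       "(min eigenvalue %.3g); projecting", w.min())
        wc, V = np.linalg.eigh(rc)
        rc = (V * np.clip(wc, 1e-10, None)) @ V.T
    return rc


def d_term(config, ctxs, trait_moments: TraitMoments, n_overlap: float) -> float:
    """D = -N/2 (log|C_hat| - log|C|) for one configuration, N the count of
    individuals observed for all the configuration's traits."""
    rc = residual_correlation(config, ctxs, trait_moments)
    u = rc / np.sqrt(np.outer(np.diag(rc), np.diag(rc)))
    sign_h, logdet_h = np.linalg.slogdet(u)
    sign_c, logdet_c = np.linalg.slogdet(trait_moments.correlation)
    if sign_h <= 0 or sign_c <= 0:
        raise np.linalg.LinAlgError("non-positive determinant in D term")
    return -0.5 * n_overlap * (logdet_h - logdet_c)


def d_term_missing(config, ctxs, trait_names, trait_moments: TraitMoments,
                   missingness: MissingnessDesign) -> float:
    """Missing-data decomposition: D_total = sum over trait subsets S with
    |S| >= 2 of D_S at the count of individuals observed for exactly S."""
    missingness.validate_against({t: ctx.N for t, ctx in zip(trait_names, ctxs)})
    pos = {t: i for i, t in enumerate(trait_names)}
    total = 0.0
    for subset, n_s in missingness.patterns.items():
        names = sorted(subset & set(trait_names), key=pos.get)
        if len(names) < 2 or n_s == 0:
            continue
        sel = [pos[t] for t in names]
        total += d_term([config[i] for i in sel], [ctxs[i] for i in sel],
                        trait_moments.subset(names), n_s)
    return total


# ---------------------------------------------------------------------------
# vectorised per-pair grids over truncated model tables


@dataclass
class _TraitFit:
    name: str
    table: ModelPosteriorTable
    ctx: AbfContext
    idxs: list
    sizes: np.ndarray
    pp: np.ndarray
    s: np.ndarray        # explained fraction per model
    Wb: np.ndarray       # (n_models, P): joint effects scattered to panel slots
    V: np.ndarray        # (n_models, P): R @ b_hat per model
    member: np.ndarray   # (n_models, P) bool: SNP membership


def _fit_trait(name: str, table: ModelPosteriorTable, ctx: AbfContext) -> _TraitFit:
    n = len(table)
    P = len(ctx.snp_ids)
    idxs = [np.asarray(ctx.index(s), dtype=int) for s in table.df["snps"]]
    sizes = np.array([len(i) for i in idxs])
    s = np.zeros(n)
    Wb = np.zeros((n, P))
    member = np.zeros((n, P), dtype=bool)
    for m in np.unique(sizes):
        rows = np.where(sizes == m)[0]
        if m == 0:
            continue
        idx = np.stack([idxs[i] for i in rows])
        b, sv = _fit_batch(idx, ctx.R, ctx.r_scores)
        s[rows] = sv
        for r, row in enumerate(rows):
            Wb[row, idx[r]] = b[r]
            member[row, idx[r]] = True
    V = Wb @ ctx.R
    return _TraitFit(name, table, ctx, idxs, sizes,
                     table.df["pp"].to_numpy(dtype=float), s, Wb, V, member)


def _pair_residual_u(fk: _TraitFit, fl: _TraitFit, rho_kl: float) -> np.ndarray:
    """Residual correlation u for every (model_k, model_l) pair of models."""
    A_kl = fk.Wb @ fl.ctx.r_scores          # b_k . r^(l) over gamma_k
    A_lk = fl.Wb @ fk.ctx.r_scores
    cross = fk.V @ fl.Wb.T
    rc = rho_kl - A_kl[:, None] - A_lk[None, :] + cross
    d = np.sqrt(np.outer(1.0 - fk.s, 1.0 - fl.s))
    return np.clip(rc / d, -U_CLIP, U_CLIP)


def _pair_share(fk: _TraitFit, fl: _TraitFit) -> np.ndarray:
    return (fk.member.astype(np.uint8) @ fl.member.astype(np.uint8).T) > 0


def _strata(missingness: MissingnessDesign, trait_names) -> list[tuple[list[int], int]]:
    pos = {t: i for i, t in enumerate(trait_names)}
    out = []
    for subset, n_s in missingness.patterns.items():
        names = sorted(subset & set(trait_names), key=pos.get)
        if len(names) >= 2 and n_s > 0:
            out.append(([pos[t] for t in names], n_s))
    return out


# ---------------------------------------------------------------------------
# results object


class JointResults:
    """Trait-adjusted fine-mapping output for M jointly analysed traits."""

    def __init__(self, trait_tables: dict[str, ModelPosteriorTable],
                 single_tables: dict[str, ModelPosteriorTable],
                 diagnostics: dict):
        self.trait_tables = trait_tables
        self.single_tables = single_tables
        self.diagnostics = diagnostics
        self.mpp = {t: tab.mpp() for t, tab in trait_tables.items()}

    @property
    def model_tables(self) -> dict[str, ModelPosteriorTable]:
        return self.trait_tables

    @property
    def kappa(self) -> float:
        return self.diagnostics["kappa"]

    def adjusted_pp(self, trait: str, model) -> float:
        return self.trait_tables[trait].pp_of(model)

    def comparison(self, trait: str) -> pd.DataFrame:
        """Side-by-side single-trait vs adjusted posteriors for one trait."""
        adj = self.trait_tables[trait].df
        single = {s: p for s, p in
                  zip(self.single_tables[trait].df["snps"],
                      self.single_tables[trait].df["pp"])}
        out = adj.copy()
        out["single_pp"] = out["snps"].map(lambda s: single.get(s, 0.0))
        out = out.rename(columns={"pp": "adjusted_pp"})
        out["model"] = out["snps"].map(lambda s: "+".join(s) if s else "(null)")
        return out[["model", "size", "single_pp", "adjusted_pp"]]

    def summary(self, top: int = 5) -> pd.DataFrame:
        frames = []
        for trait in self.trait_tables:
            df = self.comparison(trait).head(top)
            df.insert(0, "trait", trait)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def __repr__(self):
        return (f"<JointResults traits={list(self.trait_tables)} "
                f"kappa={self.kappa:.3g} configs={self.diagnostics['n_configs']}>")


FlashfmOutput = JointResults


# ---------------------------------------------------------------------------
# the model object


class JointFineMapper:
    """Joint fine-mapping of 2-6 traits from single-trait model posteriors.

    Parameters
    ----------
    tables : mapping trait name -> ModelPosteriorTable (full single-trait
        posteriors; truncated internally at cumulative pp ``cpp``).
    ctxs : mapping trait name -> AbfContext on the shared harmonised panel.
    trait_moments : TraitMoments covering the traits.
    missingness : MissingnessDesign; defaults to complete overlap at the
        smallest trait sample size.
    target_odds : prior odds of no-sharing vs sharing used to calibrate
        kappa (default 1.0 = 50/50); ignored when ``kappa`` is given.
    """

    MAX_TRAITS = 6

    def __init__(self, tables: dict[str, ModelPosteriorTable],
                 ctxs: dict[str, AbfContext],
                 trait_moments: TraitMoments, *,
                 missingness: MissingnessDesign | None = None,
                 target_odds: float = 1.0, kappa: float | None = None,
                 size_priors=None, cpp: float = 0.99,
                 max_models_per_trait: int = 1000,
                 config_cap: int = 10 ** 7):
        self.trait_names = list(tables)
        M = len(self.trait_names)
        if not 2 <= M <= self.MAX_TRAITS:
            raise ValueError(f"joint fine-mapping supports 2-{self.MAX_TRAITS} traits")
        self.tables = tables
        self.ctxs = [ctxs[t] for t in self.trait_names]
        snp_ids = self.ctxs[0].snp_ids
        for ctx in self.ctxs[1:]:
            if ctx.snp_ids != snp_ids:
                raise ValueError("all traits must share one harmonised SNP panel")
        self.trait_moments = trait_moments.subset(self.trait_names)
        if missingness is None:
            n_min = int(min(ctx.N for ctx in self.ctxs))
            missingness = MissingnessDesign.complete(self.trait_names, n_min)
        self.missingness = missingness
        self.cpp = cpp
        self.max_models_per_trait = max_models_per_trait
        self.config_cap = config_cap
        self.P = len(snp_ids)
        if size_priors is None:
            max_size = max(int(tab.df["size"].max()) for tab in tables.values())
            size_priors = [default_size_weights(max(max_size, 1))] * M
        if kappa is not None:
            self.sharing = SharingPrior(kappa=kappa, P=self.P,
                                        size_priors=list(size_priors),
                                        target_odds=None)
        else:
            self.sharing = SharingPrior.from_target_odds(
                target_odds, size_priors, self.P, n_traits=M)

    # -- internals ---------------------------------------------------------

    def _truncated_fits(self) -> list[_TraitFit]:
        fits = []
        for name, ctx in zip(self.trait_names, self.ctxs):
            trunc = self.tables[name].cpp_truncate(self.cpp, self.max_models_per_trait)
            fits.append(_fit_trait(name, trunc, ctx))
        n_configs = math.prod(len(f.table) for f in fits)
        if n_configs > self.config_cap:
            raise ValueError(f"{n_configs} joint configurations exceed the cap "
                             f"{self.config_cap}; lower cpp or max_models_per_trait")
        return fits

    def _log_tau_grid(self, fits) -> np.ndarray:
        """log tau broadcast over the configuration grid (depends on sizes only)."""
        M = len(fits)
        shape = tuple(len(f.table) for f in fits)
        out = np.zeros(shape)
        if self.sharing.kappa == 1.0:
            return out
        from itertools import product as iproduct
        for sizes in iproduct(*(np.unique(f.sizes) for f in fits)):
            val = math.log(self.sharing.tau(sizes))
            mask = np.ones(shape, dtype=bool)
            for k, (f, m) in enumerate(zip(fits, sizes)):
                sel = np.expand_dims(f.sizes == m,
                                     tuple(i for i in range(M) if i != k))
                mask &= sel
            out[mask] = val
        return out

    def _pairwise(self, fits):
        M = len(fits)
        rho = self.trait_moments.correlation
        u = {}
        share = {}
        for k in range(M):
            for l in range(k + 1, M):
                u[(k, l)] = _pair_residual_u(fits[k], fits[l], rho[k, l])
                share[(k, l)] = _pair_share(fits[k], fits[l])
        return u, share

    def _d_grid_two(self, u12: np.ndarray) -> np.ndarray:
        rho = float(self.trait_moments.correlation[0, 1])
        base = math.log1p(-rho ** 2)
        d = np.zeros_like(u12)
        for sel, n_s in _strata(self.missingness, self.trait_names):
            d += -0.5 * n_s * (np.log1p(-u12 ** 2) - base)
        return d

    def _fit_two(self, fits) -> dict[str, np.ndarray]:
        f1, f2 = fits
        u, share = self._pairwise(fits)
        d = self._d_grid_two(u[(0, 1)])
        log_tau = self._log_tau_grid(fits)
        kappa = self.sharing.kappa
        logw = d + log_tau  # log(delta * tau) per configuration
        out = {}
        with np.errstate(divide="ignore"):
            lpp1 = np.log(f1.pp)
            lpp2 = np.log(f2.pp)
        sh = share[(0, 1)]
        neg = np.where(sh, 0.0, -np.inf)
        # trait 1: sums over j
        den1 = logsumexp(logw + lpp2[None, :], axis=1)
        num1 = logsumexp(logw + lpp2[None, :] + neg, axis=1)
        adj1 = f1.pp * (1.0 + (kappa - 1.0) * np.exp(num1 - den1))
        den2 = logsumexp(logw + lpp1[:, None], axis=0)
        num2 = logsumexp(logw + lpp1[:, None] + neg, axis=0)
        adj2 = f2.pp * (1.0 + (kappa - 1.0) * np.exp(num2 - den2))
        out[f1.name] = adj1 / adj1.sum()
        out[f2.name] = adj2 / adj2.sum()
        self._n_configs = sh.size
        return out

    def _fit_multi(self, fits) -> dict[str, np.ndarray]:
        """General-M route: explicit enumeration of the configuration grid."""
        M = len(fits)
        shape = tuple(len(f.table) for f in fits)
        u, share = self._pairwise(fits)

        def expand(mat, k, l):
            ax = [i for i in range(M) if i not in (k, l)]
            return np.expand_dims(mat, tuple(ax))

        # sharing exponent e = M_S - number of connected components, built
        # from boolean reachability over the trait graph
        adj = np.zeros(shape + (M, M), dtype=bool)
        for (k, l), sh in share.items():
            adj[..., k, l] = adj[..., l, k] = expand(sh, k, l)
        reach = adj | np.eye(M, dtype=bool)
        for _ in range(int(math.ceil(math.log2(max(M, 2))))):
            r8 = reach.astype(np.uint8)
            reach = reach | (np.matmul(r8, r8) > 0)
        comp = np.sum(1.0 / reach.sum(axis=-1), axis=-1)
        e = M - np.rint(comp).astype(int)

        # D over missingness strata
        d = np.zeros(shape)
        rho = self.trait_moments.correlation
        for sel, n_s in _strata(self.missingness, self.trait_names):
            mS = len(sel)
            if mS == 2:
                k, l = sel
                base = math.log1p(-float(rho[k, l]) ** 2)
                d += -0.5 * n_s * (np.log1p(-expand(u[(k, l)], k, l) ** 2) - base)
                continue
            U = np.zeros(shape + (mS, mS))
            U[..., np.arange(mS), np.arange(mS)] = 1.0
            for a in range(mS):
                for b in range(a + 1, mS):
                    k, l = sel[a], sel[b]
                    U[..., a, b] = U[..., b, a] = expand(u[(k, l)], k, l)
            sign, logdet = np.linalg.slogdet(U)
            bad = sign <= 0
            if bad.any():
                logger.warning("%d configurations needed PSD repair in D term",
                               int(bad.sum()))
                wv = np.linalg.eigvalsh(U[bad])
                logdet[bad] = np.log(np.clip(wv, 1e-10, None)).sum(axis=-1)
            base = np.linalg.slogdet(rho[np.ix_(sel, sel)])[1]
            d += -0.5 * n_s * (logdet - base)

        log_tau = self._log_tau_grid(fits)
        with np.errstate(divide="ignore"):
            lpps = [np.log(f.pp) for f in fits]
        logw = d + log_tau
        for k, lpp in enumerate(lpps):
            logw = logw + np.expand_dims(lpp, tuple(i for i in range(M) if i != k))
        kappa = self.sharing.kappa
        log_kappa_e = e * math.log(kappa) if kappa != 1.0 else np.zeros(shape)
        out = {}
        for k, f in enumerate(fits):
            # W_i(kappa) / W_i(1): sums over the other traits' models
            rest = logw - np.expand_dims(lpps[k], tuple(i for i in range(M) if i != k))
            axes = tuple(i for i in range(M) if i != k)
            den = logsumexp(rest, axis=axes)
            num = logsumexp(rest + log_kappa_e, axis=axes)
            adj = f.pp * np.exp(num - den)
            out[f.name] = adj / adj.sum()
        self._n_configs = int(np.prod(shape))
        return out

    # -- public API --------------------------------------------------------

    def fit(self) -> JointResults:
        fits = self._truncated_fits()
        if len(fits) == 2:
            adjusted = self._fit_two(fits)
        else:
            adjusted = self._fit_multi(fits)
        trait_tables = {}
        single_tables = {}
        retained = {}
        for f in fits:
            df = f.table.df.copy()
            df["pp"] = adjusted[f.name]
            trait_tables[f.name] = ModelPosteriorTable(df, f.name, self.cpp)
            single_tables[f.name] = f.table
            retained[f.name] = getattr(f.table, "retained_pp", float(f.pp.sum()))
        diagnostics = {
            "kappa": self.sharing.kappa,
            "target_odds": self.sharing.target_odds,
            "n_configs": self._n_configs,
            "cpp": self.cpp,
            "retained_pp": retained,
            "unallocated_pp": {t: 1.0 - v for t, v in retained.items()},
            "n_models": {f.name: len(f.table) for f in fits},
        }
        logger.info("joint fit: %d configurations, kappa=%.4g",
                    self._n_configs, self.sharing.kappa)
        return JointResults(trait_tables, single_tables, diagnostics)


# ---------------------------------------------------------------------------
# orchestration


def run_flashfm(gwas_tables, panel: ReferencePanel,
                trait_moments: TraitMoments, *,
                single_tables: dict[str, ModelPosteriorTable] | None = None,
                missingness: MissingnessDesign | None = None,
                n_eff: dict[str, float] | str | None = None,
                target_odds: float = 1.0, kappa: float | None = None,
                cpp: float = 0.99, max_model_size: int = 4,
                size_weights=None, max_models_per_trait: int = 1000,
                search_mode: str = "auto") -> JointResults:
    """End-to-end joint fine-mapping from per-trait GWAS summary tables.

    Harmonises every table with the panel, runs single-trait fine-mapping
    where tables are not supplied, calibrates the sharing prior and returns
    trait-adjusted posteriors.  ``n_eff`` may be a per-trait mapping,
    ``"estimate"`` (median per-SNP effective N from the summary statistics)
    or None (use each table's nominal n).
    """
    from .io import harmonise
    from .neff import neff_trait
    from .single import SingleTraitFineMapper

    harmonised = [harmonise(g, panel) for g in gwas_tables]
    shared = set(harmonised[0][1].snp_ids)
    for _, p in harmonised[1:]:
        shared &= set(p.snp_ids)
    if not shared:
        raise ValueError("no SNPs shared across all traits and the panel")
    order = [s for s in panel.snp_ids if s in shared]
    sub_panel = panel.subset(order)
    gwas_list = []
    for g, _ in harmonised:
        gwas_list.append(g.subset(order))

    ctxs = {}
    tables = {}
    size_weights = (np.asarray(size_weights, dtype=float) if size_weights is not None
                    else default_size_weights(max_model_size))
    for g in gwas_list:
        if isinstance(n_eff, str) and n_eff == "estimate":
            ne = neff_trait(g).n_eff
        elif isinstance(n_eff, dict):
            ne = n_eff[g.trait_name]
        else:
            ne = None
        ctxs[g.trait_name] = AbfContext.from_gwas(g, sub_panel, n_eff=ne)
        if single_tables is not None and g.trait_name in single_tables:
            tables[g.trait_name] = single_tables[g.trait_name]
        else:
            mapper = SingleTraitFineMapper(
                g, sub_panel, n_eff=ne, size_weights=size_weights,
                max_model_size=max_model_size, harmonised=True)
            tables[g.trait_name] = mapper.fit(mode=search_mode).table
    model = JointFineMapper(tables, ctxs, trait_moments,
                            missingness=missingness, target_odds=target_odds,
                            kappa=kappa, size_priors=[size_weights] * len(gwas_list),
                            cpp=cpp, max_models_per_trait=max_models_per_trait)
    return model.fit()
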