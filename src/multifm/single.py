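"""Single-trait multi-SNP fine-mapping from GWAS summary statistics.

The engine mirrors the expanded-JAM workflow: the reference panel is
tag-thinned at r^2 = 0.99, multi-SNP models over the tags are scored by a
BIC-based approximate log Bayes factor against the null model, each tag
model is expanded by interchanging tags with their tagged SNPs, and every
expanded model is re-scored individually.  Posterior probabilities combine
the ABFs with a size-structured model prior that is uniform over models of
the same size.

The log-ABF is computed on the standardised scale: with per-SNP marginal
score r_j = beta_j * sd(x_j) / sd(y), sd(x_j) = sqrt(2 f_j (1 - f_j)), a
model gamma has RSS_gamma / RSS_0 = 1 - r' R^-1 r over its SNPs, and

    log ABF(gamma) = -1/2 * ( N * log(1 - r' R^-1 r) + m * log N ),

the difference of BIC/2 between gamma and the null model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd

from .containers import GwasTable, ModelPosteriorTable, ReferencePanel

logger = logging.getLogger("multifm")

RIDGE = 1e-6
R_CLIP = 0.999


@dataclass
class TagMap:
    """Partition of the SNP set into tag SNPs and their tagged members."""

    tags: list[str]
    members: dict[str, list[str]]
    r2_threshold: float = 0.99

    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())


def thin_by_ld(panel: ReferencePanel, r2_threshold: float = 0.99) -> TagMap:
    """Greedy LD thinning: descending-MAF order (ties by snp_id), each new tag
    absorbs all still-unassigned SNPs with r^2 >= threshold."""
    maf = panel.maf()
    order = sorted(range(len(panel)), key=lambda i: (-maf[i], panel.snp_ids[i]))
    r2 = panel.r2()
    unassigned = np.ones(len(panel), dtype=bool)
    tags: list[str] = []
    members: dict[str, list[str]] = {}
    for i in order:
        if not unassigned[i]:
            continue
        absorbed = np.where(unassigned & (r2[i] >= r2_threshold))[0]
        unassigned[absorbed] = False
        tag = panel.snp_ids[i]
        tags.append(tag)
        members[tag] = [panel.snp_ids[j] for j in absorbed]
    return TagMap(tags=tags, members=members, r2_threshold=r2_threshold)


@dataclass
class AbfContext:
    """Summary-statistic inputs to the BIC-based ABF for one trait."""

    N: float
    var_y: float
    r_scores: np.ndarray  # standardised marginal scores, aligned to snp_ids
    R: np.ndarray
    snp_ids: list[str]
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.r_scores = np.clip(np.asarray(self.r_scores, dtype=float), -R_CLIP, R_CLIP)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def from_gwas(cls, gwas: GwasTable, panel: ReferencePanel,
                  n_eff: float | None = None,
                  genotype_var: np.ndarray | None = None) -> "AbfContext":
        """Build the scoring context from a harmonised GWAS table and panel.

        ``genotype_var`` optionally overrides the Hardy-Weinberg variance
        2 f (1 - f) with in-sample genotype variances (aligned to the panel).
        """
        if gwas.snp_ids != panel.snp_ids:
            raise ValueError("GWAS and panel must be harmonised (same SNPs, same order)")
        f = gwas.df["eaf"].to_numpy(dtype=float)
        v_x = 2.0 * f * (1.0 - f) if genotype_var is None else np.asarray(genotype_var, float)
        beta = gwas.df["beta"].to_numpy(dtype=float)
        r = beta * np.sqrt(v_x) / math.sqrt(gwas.trait_variance)
        N = float(n_eff) if n_eff is not None else gwas.n_trait
        return cls(N=N, var_y=gwas.trait_variance, r_scores=r, R=panel.R,
                   snp_ids=list(panel.snp_ids))

    def index(self, snps) -> tuple[int, ...]:
        return tuple(self._index[s] for s in snps)


def _fit_batch(idx: np.ndarray, R: np.ndarray, r: np.ndarray,
               ridge: float = RIDGE) -> tuple[np.ndarray, np.ndarray]:
    """Joint effects and explained fractions for a batch of same-size models.

    ``idx`` is (k, m) SNP indices.  Returns (b_hat (k, m), s (k,)) with
    b_hat = R_gamma^-1 r_gamma and s = r_gamma' b_hat, s clipped below 1.
    """
    if idx.size == 0:
        return np.zeros((idx.shape[0], 0)), np.zeros(idx.shape[0])
    m = idx.shape[1]
    if m == 1:  # unit diagonal: no ridge needed
        rsub = r[idx]
        return rsub.copy(), np.clip(rsub[:, 0] ** 2, None, 1.0 - 1e-12)
    Rsub = R[idx[:, :, None], idx[:, None, :]].copy()
    Rsub[:, np.arange(m), np.arange(m)] += ridge
    rsub = r[idx]
    try:
        b = np.linalg.solve(Rsub, rsub[..., None])[..., 0]
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular LD submatrix after ridge {ridge}: {err}") from err
    s = np.einsum("km,km->k", rsub, b)
    return b, np.clip(s, None, 1.0 - 1e-12)


def log_abf_batch(idx: np.ndarray, ctx: AbfContext) -> np.ndarray:
    """BIC-based log ABF vs the null for a (k, m) batch of same-size models."""
    k, m = idx.shape
    if m == 0:
        return np.zeros(k)
    _, s = _fit_batch(idx, ctx.R, ctx.r_scores)
    return -0.5 * (ctx.N * np.log1p(-s) + m * math.log(ctx.N))


def log_abf(model, ctx: AbfContext) -> float:
    """Approximate log Bayes factor of a SNP model against the null model.

    ``model`` is a SnpModel or an iterable of snp_ids; the null model returns
    exactly 0.
    """
    snps = getattr(model, "snps", model)
    idx = np.array([ctx.index(snps)], dtype=int)
    if idx.shape[1] == 0:
        return 0.0
    if idx.shape[1] >= ctx.N - 2:
        raise ValueError("model size too large for the effective sample size")
    return float(log_abf_batch(idx, ctx)[0])


def default_size_weights(max_size: int = 4, mean: float = 1.0) -> np.ndarray:
    """Truncated-Poisson prior weights over model sizes 0..max_size.

    The default mean of 1 encodes the expectation of roughly one causal
    variant in the region.
    """
    m = np.arange(max_size + 1)
    w = np.exp(-mean) * mean ** m / np.array([math.factorial(int(i)) for i in m])
    return w / w.sum()


def model_prior(size: int, P: int, size_weights: np.ndarray) -> float:
    """Prior probability of one specific model of ``size`` SNPs among P.

    p = w_size / C(P, size): uniform over models within each size class.
    """
    size_weights = np.asarray(size_weights, dtype=float)
    if abs(size_weights.sum() - 1.0) > 1e-8:
        raise ValueError("size_weights must sum to 1")
    if size >= len(size_weights):
        raise ValueError(f"model size {size} exceeds size prior support "
                         f"(max {len(size_weights) - 1})")
    return float(size_weights[size] / math.comb(P, size))


def search_models(ctx: AbfContext, tagmap: TagMap, size_weights: np.ndarray,
                  max_size: int, mode: str = "auto", beam_width: int = 50,
                  admission_log_window: float = math.log(1e6),
                  exhaustive_limit: int = 10 ** 6) -> pd.DataFrame:
    """Score candidate tag models up to ``max_size`` SNPs.

    Exhaustive mode scores every tag model; beam mode grows models from the
    top ``beam_width`` single-SNP models, keeping any model whose
    log(prior * ABF) is within ``admission_log_window`` of the running best.
    The null model is always present.  Returns a frame with columns
    ``idx`` (tuple of panel indices), ``size``, ``log_abf``.
    """
    tag_idx = np.array([ctx.index([t])[0] for t in tagmap.tags], dtype=int)
    n_tags = len(tag_idx)
    max_size = min(max_size, n_tags)
    if mode == "auto":
        mode = ("exhaustive" if math.comb(n_tags, max_size) <= exhaustive_limit
                else "greedy-beam")
    P = len(ctx.snp_ids)
    rows_idx: list[tuple[int, ...]] = [()]
    rows_abf: list[float] = [0.0]

    if mode == "exhaustive":
        for m in range(1, max_size + 1):
            combos = np.array(list(combinations(range(n_tags), m)), dtype=int)
            if combos.size == 0:
                continue
            idx = tag_idx[combos]
            abf = log_abf_batch(idx, ctx)
            rows_idx.extend(map(tuple, idx))
            rows_abf.extend(abf)
    elif mode == "greedy-beam":
        singles = tag_idx[:, None]
        abf1 = log_abf_batch(singles, ctx)
        score1 = abf1 + math.log(model_prior(1, P, size_weights))
        rows_idx.extend((int(i),) for i in tag_idx)
        rows_abf.extend(abf1)
        order = np.argsort(-score1)
        frontier = [(int(tag_idx[i]),) for i in order[:beam_width]]
        best = max(float(np.max(score1)), math.log(model_prior(0, P, size_weights)))
        seen = set(rows_idx)
        for m in range(2, max_size + 1):
            cand = set()
            for mod in frontier:
                for t in tag_idx:
                    t = int(t)
                    if t not in mod:
                        cand.add(tuple(sorted(mod + (t,))))
            cand = [c for c in cand if c not in seen]
            if not cand:
                break
            idx = np.array(cand, dtype=int)
            abf = log_abf_batch(idx, ctx)
            score = abf + math.log(model_prior(m, P, size_weights))
            best = max(best, float(np.max(score)))
            keep = score >= best - admission_log_window
            frontier = [cand[i] for i in np.where(keep)[0]]
            rows_idx.extend(frontier)
            rows_abf.extend(abf[keep])
            seen.update(frontier)
    else:
        raise ValueError(f"unknown search mode {mode!r}")

    return pd.DataFrame({"idx": rows_idx,
                         "size": [len(i) for i in rows_idx],
                         "log_abf": rows_abf})


def expand_tag_models(tag_models: pd.DataFrame, tagmap: TagMap, ctx: AbfContext,
                      size_weights: np.ndarray, expansion_cap: int = 5 * 10 ** 6,
                      pp_floor: float = 1e-12,
                      trait_name: str = "trait") -> ModelPosteriorTable:
    """Expand tag models over their tagged members and score every expansion.

    Every Cartesian substitution of members for tags yields a distinct model;
    the expanded set is deduplicated and each model is re-scored with the
    BIC ABF (not copied from its tag model).  Posteriors are
    PP_i \\propto prior_i * ABF_i, normalised over the expanded set; rows with
    relative posterior mass below ``pp_floor`` are dropped before the final
    renormalisation.
    """
    member_idx = {ctx.index([t])[0]: ctx.index(tagmap.members[t])
                  for t in tagmap.tags}
    total = 0
    for mod in tag_models["idx"]:
        n = 1
        for t in mod:
            n *= len(member_idx[t])
        total += n
        if total > expansion_cap:
            raise ValueError(
                f"tag-model expansion exceeds cap {expansion_cap}; "
                "raise the thinning r2_threshold")
    expanded: set[tuple[int, ...]] = set()
    for mod in tag_models["idx"]:
        if not mod:
            expanded.add(())
            continue
        for combo in product(*(member_idx[t] for t in mod)):
            expanded.add(tuple(sorted(combo)))
    by_size: dict[int, list[tuple[int, ...]]] = {}
    for mod in expanded:
        by_size.setdefault(len(mod), []).append(mod)
    P = len(ctx.snp_ids)
    logN = math.log(ctx.N)
    all_idx: list[tuple[int, ...]] = []
    all_abf: list[np.ndarray] = []
    all_logprior: list[np.ndarray] = []
    for m, mods in sorted(by_size.items()):
        arr = np.array(mods, dtype=int).reshape(len(mods), m)
        abf = log_abf_batch(arr, ctx)
        all_idx.extend(mods)
        all_abf.append(abf)
        all_logprior.append(np.full(len(mods), math.log(model_prior(m, P, size_weights))))
    abf = np.concatenate(all_abf)
    score = abf + np.concatenate(all_logprior)
    score -= score.max()
    w = np.exp(score)
    pp = w / w.sum()
    keep = pp >= pp_floor * pp.max()
    ids = np.array(ctx.snp_ids, dtype=object)
    df = pd.DataFrame({
        "snps": [tuple(sorted(ids[list(mod)])) for mod, k in zip(all_idx, keep) if k],
        "log_abf": abf[keep],
        "prior": np.exp(np.concatenate(all_logprior))[keep],
        "pp": pp[keep],
    })
    return ModelPosteriorTable(df, trait_name)


def mpp(table: ModelPosteriorTable) -> pd.Series:
    """Per-SNP marginal posterior probability MPP(s) = sum of PPs of models
    containing s."""
    return table.mpp()


class SingleTraitResults:
    """Fitted single-trait fine-mapping result."""

    def __init__(self, model: "SingleTraitFineMapper", table: ModelPosteriorTable,
                 tagmap: TagMap, n_tag_models: int):
        self.model = model
        self.table = table
        self.tagmap = tagmap
        self.n_tag_models = n_tag_models
        self.mpp = table.mpp()

    @property
    def trait_name(self) -> str:
        return self.table.trait_name

    def null_pp(self) -> float:
        return self.table.null_pp()

    def summary(self, top: int = 10) -> pd.DataFrame:
        df = self.table.df.head(top).copy()
        df["model"] = df["snps"].map(lambda s: "+".join(s) if s else "(null)")
        return df[["model", "size", "log_abf", "prior", "pp"]]

    def __repr__(self):
        best = self.table.df.iloc[0]
        lab = "+".join(best["snps"]) or "(null)"
        return (f"<SingleTraitResults {self.trait_name}: {len(self.table)} models, "
                f"top {lab} (pp={best['pp']:.3f})>")


class SingleTraitFineMapper:
    """Multi-SNP Bayesian fine-mapping of one quantitative trait.

    Parameters
    ----------
    gwas : GwasTable
        Marginal summary statistics; harmonised to ``panel`` on construction.
    panel : ReferencePanel
        Source of LD and reference allele frequencies.
    n_eff : effective sample size to use in the ABFs (e.g. from
        :func:`multifm.neff.neff_trait`); defaults to the table's n_trait.
    size_weights : prior weights over model sizes; default truncated
        Poisson(1) up to ``max_model_size``.
    max_model_size : largest number of causal variants considered (default 4).
    r2_thin : tag-thinning threshold (default 0.99).
    """

    def __init__(self, gwas: GwasTable, panel: ReferencePanel, *,
                 n_eff: float | None = None, size_weights=None,
                 max_model_size: int = 4, r2_thin: float = 0.99,
                 harmonised: bool = False):
        if harmonised:
            self.gwas, self.panel = gwas, panel
        else:
            from .io import harmonise
            self.gwas, self.panel = harmonise(gwas, panel)
        self.max_model_size = max_model_size
        self.size_weights = (np.asarray(size_weights, dtype=float)
                             if size_weights is not None
                             else default_size_weights(max_model_size))
        if len(self.size_weights) < max_model_size + 1:
            raise ValueError("size_weights must cover sizes 0..max_model_size")
        self.r2_thin = r2_thin
        self.n_eff = n_eff
        self.ctx = AbfContext.from_gwas(self.gwas, self.panel, n_eff=n_eff)

    def fit(self, mode: str = "auto", beam_width: int = 50) -> SingleTraitResults:
        tagmap = thin_by_ld(self.panel, self.r2_thin)
        tag_models = search_models(self.ctx, tagmap, self.size_weights,
                                   self.max_model_size, mode=mode,
                                   beam_width=beam_width)
        table = expand_tag_models(tag_models, tagmap, self.ctx, self.size_weights,
                                  trait_name=self.gwas.trait_name)
        return SingleTraitResults(self, table, tagmap, len(tag_models))
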