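"""The joint-model sharing prior.

Joint configurations across traits receive prior mass

    Pr(C) = prod_k p_k  *  kappa^e  *  tau(sizes),

where p_k are the per-trait marginal model priors, e is the sharing
exponent (for two traits the 0/1 indicator of a shared SNP), kappa >= 1
upweights sharing, and tau anchors the prior so that the total mass on each
model-size combination is identical for every kappa.  Under uniform
within-size model priors the anchoring requirement forces

    tau(sizes) = 1 / E[kappa^e]

with the expectation over uniformly drawn size-conditioned model tuples;
for two traits this is the closed form 1 / (1 + (kappa - 1) q) with q the
hypergeometric overlap probability.  kappa itself is calibrated from a
target odds (TO) of no-sharing versus sharing; TO = 1 asks for a 50/50
prior chance of at least one shared causal variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy.optimize import brentq

from .containers import SnpModel

logger = logging.getLogger("multifm")

KAPPA_MAX = 1e6
_MC_DRAWS = 10 ** 5
_ENUM_P_MAX = 12
_ENUM_TUPLE_CAP = 2 * 10 ** 6
_MC_SEED = 632911  # fixed: tau must be deterministic


def overlap_probability(m1: int, m2: int, P: int) -> float:
    """Probability that two uniform models of sizes m1, m2 among P SNPs share
    at least one SNP: q = 1 - C(P-m1, m2) / C(P, m2)."""
    if not (0 <= m1 <= P and 0 <= m2 <= P):
        raise ValueError("model sizes must lie in [0, P]")
    if m1 == 0 or m2 == 0:
        return 0.0
    if P - m1 < m2:
        return 1.0
    return 1.0 - math.comb(P - m1, m2) / math.comb(P, m2)


def _components_exponent(masks: tuple[int, ...]) -> int:
    """Sharing exponent of a configuration given per-trait SNP bitmasks:
    sum over connected components of (size - 1) in the trait graph with an
    edge where two models share a SNP."""
    M = len(masks)
    parent = list(range(M))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(M):
        if not masks[i]:
            continue
        for j in range(i + 1, M):
            if masks[i] & masks[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    roots = {find(i) for i in range(M)}
    return M - len(roots)


def sharing_exponent(config) -> int:
    """Sharing exponent e of a cross-trait model configuration.

    Traits form a graph with an edge whenever two models share >= 1 SNP;
    e = sum over connected components of (component size - 1).  For two
    traits this is the 0/1 shared-variant indicator.
    """
    models = [m.snps if isinstance(m, SnpModel) else tuple(m) for m in config]
    if len(models) < 2:
        raise ValueError("a configuration needs at least two traits")
    universe: dict[str, int] = {}
    masks = []
    for snps in models:
        mask = 0
        for s in snps:
            if s not in universe:
                universe[s] = len(universe)
            mask |= 1 << universe[s]
        masks.append(mask)
    return _components_exponent(tuple(masks))


def _exponent_histogram(sizes: tuple[int, ...], P: int) -> dict[int, float]:
    """Distribution of the sharing exponent for uniform size-conditioned
    model tuples: exact enumeration for small problems, seeded Monte Carlo
    otherwise.  Returns {e: probability}."""
    sizes = tuple(int(m) for m in sizes)
    if len(sizes) == 2:
        q = overlap_probability(sizes[0], sizes[1], P)
        return {0: 1.0 - q, 1: q}
    n_tuples = math.prod(math.comb(P, m) for m in sizes)
    if P <= _ENUM_P_MAX and n_tuples <= _ENUM_TUPLE_CAP:
        counts: dict[int, int] = {}
        model_sets = [
            [sum(1 << i for i in c) for c in combinations(range(P), m)]
            for m in sizes
        ]
        for masks in product(*model_sets):
            e = _components_exponent(masks)
            counts[e] = counts.get(e, 0) + 1
        total = sum(counts.values())
        return {e: c / total for e, c in counts.items()}
    rng = np.random.default_rng(_MC_SEED)
    counts = {}
    draws = _MC_DRAWS
    picks = [
        np.array([sum(1 << int(i) for i in rng.choice(P, size=m, replace=False))
                  if m else 0 for _ in range(draws)], dtype=object)
        for m in sizes
    ]
    for masks in zip(*picks):
        e = _components_exponent(tuple(int(x) for x in masks))
        counts[e] = counts.get(e, 0) + 1
    return {e: c / draws for e, c in counts.items()}


def expected_kappa_power(sizes: tuple[int, ...], P: int, kappa: float,
                         hist: dict[int, float] | None = None) -> float:
    hist = hist if hist is not None else _exponent_histogram(sizes, P)
    return sum(p * kappa ** e for e, p in hist.items())


def tau(m_tuple, P: int, kappa: float) -> float:
    """Anchoring correction for one model-size combination.

    tau = 1 / E[kappa^e]; for two traits 1 / (1 + (kappa - 1) q).  kappa = 1
    gives tau = 1 for every size tuple.
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1 (sharing is only ever upweighted)")
    if kappa == 1.0:
        return 1.0
    return 1.0 / expected_kappa_power(tuple(m_tuple), P, kappa)


def prior_sharing_probability(kappa: float, size_priors, P: int,
                              conditional: bool = True) -> float:
    """Prior probability that >= 1 causal variant is shared between >= 2 traits,
    under the kappa-weighted, tau-anchored joint prior.

    Per size tuple the sharing fraction is E[kappa^e 1(e>=1)] / E[kappa^e]
    (for two traits the closed form kappa q / (1 + (kappa - 1) q)); the
    overall probability averages over the size-tuple prior.  By default the
    probability is conditional on sharing being possible at all (at least
    two traits with a non-null model): size priors place mass on the null
    model, and no finite kappa can make traits share a variant one of them
    does not have.
    """
    size_priors = [np.asarray(w, dtype=float) for w in size_priors]
    total = 0.0
    possible_mass = 0.0
    for sizes in product(*(range(len(w)) for w in size_priors)):
        w = math.prod(float(size_priors[k][m]) for k, m in enumerate(sizes))
        if w == 0.0:
            continue
        if sum(m >= 1 for m in sizes) < 2:
            continue
        possible_mass += w
        hist = _exponent_histogram(sizes, P)
        num = sum(p * kappa ** e for e, p in hist.items() if e >= 1)
        den = sum(p * kappa ** e for e, p in hist.items())
        total += w * num / den
    if conditional:
        if possible_mass == 0.0:
            return 0.0
        return total / possible_mass
    return total


def kappa_from_target_odds(target_odds: float, size_priors, P: int,
                           n_traits: int | None = None,
                           odds_tol: float = 1e-8) -> float:
    """Solve for the kappa whose induced prior gives
    Pr(no sharing) / Pr(sharing) = target_odds.

    The sharing probability is monotone increasing in kappa, so the root is
    unique.  If the requested odds exceed the kappa=1 odds (sharing can only
    be upweighted) kappa=1 is returned with a warning; if they lie below
    what kappa -> infinity can reach, KAPPA_MAX is returned with a warning.
    """
    if target_odds <= 0:
        raise ValueError("target odds must be positive")
    size_priors = _as_per_trait(size_priors, n_traits)
    target_p = 1.0 / (1.0 + target_odds)

    def f(kappa):
        return prior_sharing_probability(kappa, size_priors, P) - target_p

    f1 = f(1.0)
    if f1 >= 0:
        if f1 > odds_tol:
            logger.warning("target odds %.3g already exceeded at kappa=1; "
                           "returning kappa=1", target_odds)
        return 1.0
    fmax = f(KAPPA_MAX)
    if fmax <= 0:
        logger.warning("target odds %.3g unreachable even at kappa=%.0e; "
                       "returning kappa_max", target_odds, KAPPA_MAX)
        return KAPPA_MAX
    return float(brentq(f, 1.0, KAPPA_MAX, xtol=odds_tol, rtol=8.9e-16))


def _as_per_trait(size_priors, n_traits: int | None = None):
    """Accept one shared weight vector (with ``n_traits``) or a per-trait list."""
    first = size_priors[0]
    if np.ndim(first) == 0:  # a single weight vector was passed
        if n_traits is None:
            raise ValueError("a single size-weight vector needs n_traits")
        return [np.asarray(size_priors, dtype=float)] * n_traits
    out = [np.asarray(w, dtype=float) for w in size_priors]
    if n_traits is not None and len(out) != n_traits:
        raise ValueError("one size-weight vector per trait expected")
    return out


def joint_prior(config, size_priors, kappa: float, P: int) -> float:
    """Prior mass of a cross-trait configuration:
    prod_k p_k * kappa^e * tau(sizes)."""
    from .single import model_prior

    models = [m if isinstance(m, SnpModel) else SnpModel(m) for m in config]
    size_priors = _as_per_trait(size_priors, len(models))
    sizes = tuple(m.size for m in models)
    base = math.prod(model_prior(m, P, w) for m, w in zip(sizes, size_priors))
    e = sharing_exponent(models)
    return base * kappa ** e * tau(sizes, P, kappa)


@dataclass
class SharingPrior:
    """Calibrated sharing prior for a region of P SNPs and M traits."""

    kappa: float
    P: int
    size_priors: list
    target_odds: float | None = None
    _tau_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_target_odds(cls, target_odds: float, size_priors, P: int,
                         n_traits: int | None = None) -> "SharingPrior":
        size_priors = _as_per_trait(size_priors, n_traits)
        kappa = kappa_from_target_odds(target_odds, size_priors, P)
        logger.info("calibrated kappa=%.4g for target odds %.3g (P=%d)",
                    kappa, target_odds, P)
        return cls(kappa=kappa, P=P, size_priors=size_priors, target_odds=target_odds)

    def tau(self, m_tuple) -> float:
        key = tuple(int(m) for m in m_tuple)
        if key not in self._tau_cache:
            self._tau_cache[key] = tau(key, self.P, self.kappa)
        return self._tau_cache[key]

    def joint_prior(self, config) -> float:
        return joint_prior(config, self.size_priors, self.kappa, self.P)
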