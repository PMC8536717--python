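"""Core in-memory containers shared across the fine-mapping pipeline.

Conventions used throughout the package:

* All allele frequencies are effect-allele frequencies; after harmonisation
  the effect allele is the reference panel's counted (reference) allele.
* SNP correlation matrices ``R`` are Pearson correlations of genotype
  dosages (0/1/2 counts), symmetric with unit diagonal.
* ``SnpModel`` is an unordered set of SNP identifiers; the empty model is
  the null model of no causal variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("multifm")

GWAS_COLUMNS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n")

_VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class GwasRecord:
    """Marginal association summary for one SNP."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n: float

    def __post_init__(self):
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: alleles must be A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.snp_id}: eaf must lie strictly in (0,1)")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be positive")
        if not (self.n > 0):
            raise ValueError(f"{self.snp_id}: n must be positive")


class GwasTable:
    """Per-trait GWAS summary table.

    Parameters
    ----------
    df : DataFrame with columns ``snp_id, effect_allele, other_allele,
        eaf, beta, se, n`` (one row per SNP; snp_ids unique).
    trait_name : name of the trait.
    trait_variance : variance of the trait on the scale the betas refer to.
        Defaults to 1.0 (standardised trait) with a logged assumption.
    n_trait : nominal trait sample size; defaults to the maximum per-SNP n.
    """

    def __init__(self, df: pd.DataFrame, trait_name: str,
                 trait_variance: float | None = None,
                 n_trait: float | None = None):
        missing = [c for c in GWAS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"GwasTable missing columns: {missing}")
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_ids in GWAS table: {dups[:5]}")
        self.df = df.reset_index(drop=True)
        self.trait_name = trait_name
        if trait_variance is None:
            logger.info("trait %s: trait_variance not supplied, assuming 1.0 "
                        "(standardised trait)", trait_name)
            trait_variance = 1.0
        if trait_variance <= 0:
            raise ValueError("trait_variance must be positive")
        self.trait_variance = float(trait_variance)
        self.n_trait = float(n_trait) if n_trait is not None else float(df["n"].max())

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterable[GwasRecord]:
        for row in self.df.itertuples(index=False):
            yield GwasRecord(row.snp_id, row.effect_allele, row.other_allele,
                             float(row.eaf), float(row.beta), float(row.se), float(row.n))

    def subset(self, snp_ids: Sequence[str]) -> "GwasTable":
        sub = self.df.set_index("snp_id").loc[list(snp_ids)].reset_index()
        return GwasTable(sub, self.trait_name, self.trait_variance, self.n_trait)


def regularise_correlation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Project a near-correlation matrix to the PSD cone and reset unit diagonal."""
    R = np.asarray(R, dtype=float)
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() < -tol:
        logger.warning("correlation matrix has eigenvalue %.3g < -%.1g; "
                       "projecting to nearest PSD matrix", w.min(), tol)
    if w.min() < 0:
        w = np.clip(w, 0.0, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        d[d == 0] = 1.0
        R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


class ReferencePanel:
    """SNP correlation matrix plus reference allele frequencies.

    Optionally backed by the dosage matrix (individuals x SNPs, values in
    [0,2]) it was computed from, and by an allele table giving the counted
    (effect) allele and the other allele for each SNP.
    """

    def __init__(self, snp_ids: Sequence[str], R: np.ndarray, raf: np.ndarray,
                 dosage: np.ndarray | None = None,
                 alleles: pd.DataFrame | None = None):
        self.snp_ids = list(snp_ids)
        R = np.asarray(R, dtype=float)
        if R.shape != (len(self.snp_ids),) * 2:
            raise ValueError("R shape does not match snp_ids")
        if np.max(np.abs(R - R.T)) > 1e-6:
            raise ValueError("correlation matrix is asymmetric beyond 1e-6")
        self.R = regularise_correlation(R)
        raf = np.asarray(raf, dtype=float)
        if raf.shape != (len(self.snp_ids),):
            raise ValueError("raf length does not match snp_ids")
        if np.any(raf <= 0) or np.any(raf >= 1):
            raise ValueError("reference allele frequencies must be in (0,1)")
        self.raf = raf
        self.dosage = None if dosage is None else np.asarray(dosage)
        if alleles is not None:
            alleles = alleles.set_index("snp_id") if "snp_id" in alleles.columns else alleles
        self.alleles = alleles
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def from_dosage(cls, dosage: np.ndarray, snp_ids: Sequence[str],
                    alleles: pd.DataFrame | None = None) -> "ReferencePanel":
        dosage = np.asarray(dosage, dtype=float)
        if dosage.ndim != 2 or dosage.shape[1] != len(snp_ids):
            raise ValueError("dosage must be individuals x SNPs")
        if dosage.min() < 0 or dosage.max() > 2:
            raise ValueError("dosage values must lie in [0,2]")
        sd = dosage.std(axis=0)
        if np.any(sd == 0):
            bad = [snp_ids[i] for i in np.where(sd == 0)[0]]
            raise ValueError(f"monomorphic SNPs in dosage matrix: {bad[:5]}")
        R = np.corrcoef(dosage, rowvar=False)
        raf = dosage.mean(axis=0) / 2.0
        return cls(snp_ids, R, raf, dosage=dosage, alleles=alleles)

    def index(self, snp_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._index[s] for s in snp_ids], dtype=int)

    def maf(self) -> np.ndarray:
        return np.minimum(self.raf, 1.0 - self.raf)

    def subset(self, snp_ids: Sequence[str]) -> "ReferencePanel":
        idx = self.index(snp_ids)
        alleles = None if self.alleles is None else self.alleles.loc[list(snp_ids)]
        dosage = None if self.dosage is None else self.dosage[:, idx]
        return ReferencePanel([self.snp_ids[i] for i in idx], self.R[np.ix_(idx, idx)],
                              self.raf[idx], dosage=dosage, alleles=alleles)

    def r2(self) -> np.ndarray:
        return self.R ** 2

    def __len__(self) -> int:
        return len(self.snp_ids)


class TraitMoments:
    """Trait covariance matrix and the row-normalised matrix C_M.

    ``c_matrix`` has entry (i, j) = Cov(trait i, trait j) / Var(trait i),
    the form whose determinant enters the joint-model correction D_M.
    """

    def __init__(self, names: Sequence[str], sigma: np.ndarray):
        self.names = list(names)
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (len(self.names),) * 2:
            raise ValueError("sigma shape does not match trait names")
        if np.max(np.abs(sigma - sigma.T)) > 1e-8:
            raise ValueError("trait covariance matrix must be symmetric")
        w = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
        if w.min() <= 0:
            raise ValueError("trait covariance matrix must be positive-definite")
        self.sigma = 0.5 * (sigma + sigma.T)
        sd = np.sqrt(np.diag(self.sigma))
        corr = self.sigma / np.outer(sd, sd)
        off = corr[~np.eye(len(sd), dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1.0:
            raise ValueError("implied trait correlations must lie in (-1,1)")
        self.correlation = corr
        self._index = {t: i for i, t in enumerate(self.names)}

    @property
    def c_matrix(self) -> np.ndarray:
        v = np.diag(self.sigma)
        return self.sigma / v[:, None]

    def subset(self, names: Sequence[str]) -> "TraitMoments":
        idx = [self._index[t] for t in names]
        return TraitMoments(list(names), self.sigma[np.ix_(idx, idx)])

    @classmethod
    def from_traits(cls, traits: pd.DataFrame) -> "TraitMoments":
        """Pairwise-complete covariance of an individuals x traits frame (NaN = missing)."""
        sigma = traits.cov().to_numpy()
        return cls(list(traits.columns), sigma)


@dataclass(frozen=True, order=True)
class SnpModel:
    """A causal-variant model: an unordered set of SNP ids (empty = null model)."""

    snps: tuple[str, ...]

    def __init__(self, snps: Iterable[str] = ()):
        snps = tuple(sorted(set(snps)))
        object.__setattr__(self, "snps", snps)

    @property
    def size(self) -> int:
        return len(self.snps)

    def shares_snp(self, other: "SnpModel") -> bool:
        return bool(set(self.snps) & set(other.snps))

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.snps

    def __repr__(self) -> str:
        return "SnpModel(null)" if not self.snps else f"SnpModel({'+'.join(self.snps)})"


NULL_MODEL = SnpModel(())


class ModelPosteriorTable:
    """Per-trait list of SNP models with prior, log-ABF and posterior probability.

    The underlying frame has columns ``snps`` (tuple of snp ids), ``size``,
    ``log_abf`` (may be NaN for imported posteriors), ``prior`` and ``pp``;
    rows are sorted by ``pp`` descending and pps sum to one.
    """

    def __init__(self, df: pd.DataFrame, trait_name: str, cpp_threshold: float = 0.99,
                 normalise: bool = True):
        required = {"snps", "pp"}
        if not required.issubset(df.columns):
            raise ValueError(f"model table needs columns {required}")
        df = df.copy()
        df["snps"] = df["snps"].map(lambda s: tuple(sorted(s)))
        if "size" not in df.columns:
            df["size"] = df["snps"].map(len)
        for col in ("log_abf", "prior"):
            if col not in df.columns:
                df[col] = np.nan
        if (df["pp"] < -1e-12).any():
            raise ValueError("posterior probabilities must be nonnegative")
        df["pp"] = df["pp"].clip(lower=0.0)
        total = df["pp"].sum()
        if normalise:
            if total <= 0:
                raise ValueError("posterior probabilities sum to zero")
            df["pp"] = df["pp"] / total
        elif abs(total - 1.0) > 1e-8:
            raise ValueError("posterior probabilities must sum to 1")
        df = df.sort_values("pp", ascending=False, kind="mergesort").reset_index(drop=True)
        self.df = df[["snps", "size", "log_abf", "prior", "pp"]]
        self.trait_name = trait_name
        self.cpp_threshold = cpp_threshold

    def __len__(self) -> int:
        return len(self.df)

    def models(self) -> list[SnpModel]:
        return [SnpModel(s) for s in self.df["snps"]]

    def pp_of(self, model: SnpModel | Iterable[str]) -> float:
        key = tuple(sorted(model.snps if isinstance(model, SnpModel) else model))
        hit = self.df.loc[self.df["snps"] == key, "pp"]
        return float(hit.iloc[0]) if len(hit) else 0.0

    def null_pp(self) -> float:
        return self.pp_of(NULL_MODEL)

    def cpp_truncate(self, cpp: float | None = None,
                     max_models: int | None = None) -> "ModelPosteriorTable":
        """Keep the smallest top set of models whose cumulative pp >= cpp."""
        cpp = self.cpp_threshold if cpp is None else cpp
        cum = self.df["pp"].cumsum()
        keep = int(np.searchsorted(cum.to_numpy(), cpp) + 1)
        keep = min(keep, len(self.df))
        if max_models is not None:
            keep = min(keep, max_models)
        out = ModelPosteriorTable(self.df.iloc[:keep], self.trait_name,
                                  self.cpp_threshold)
        # keep the un-normalised pps: downstream weighting uses the raw values
        out.df = self.df.iloc[:keep].reset_index(drop=True)
        out.retained_pp = float(self.df["pp"].iloc[:keep].sum())
        return out

    def mpp(self) -> pd.Series:
        """Marginal posterior probability that each SNP appears in any model."""
        acc: dict[str, float] = {}
        for snps, pp in zip(self.df["snps"], self.df["pp"]):
            for s in snps:
                acc[s] = acc.get(s, 0.0) + pp
        return pd.Series(acc, dtype=float).sort_values(ascending=False)


class MissingnessDesign:
    """Counts of individuals observed for each exact subset of traits.

    ``patterns`` maps a frozenset of trait names to the number of individuals
    measured for exactly those traits (and no others).
    """

    def __init__(self, patterns: Mapping[frozenset, int] | Mapping[tuple, int],
                 trait_names: Sequence[str], total: int | None = None):
        self.trait_names = list(trait_names)
        pats: dict[frozenset, int] = {}
        for key, count in patterns.items():
            key = frozenset(key)
            if count < 0:
                raise ValueError("pattern counts must be nonnegative")
            if not key.issubset(set(self.trait_names)):
                raise ValueError(f"pattern {set(key)} mentions unknown traits")
            pats[key] = pats.get(key, 0) + int(count)
        self.patterns = pats
        if total is not None and sum(pats.values()) != total:
            raise ValueError("pattern counts do not sum to the cohort size")

    def n_trait(self, trait: str) -> int:
        return sum(c for s, c in self.patterns.items() if trait in s)

    def n_exact(self, traits: Iterable[str]) -> int:
        return self.patterns.get(frozenset(traits), 0)

    def n_overlap(self, traits: Iterable[str]) -> int:
        """Individuals observed for at least all of ``traits``."""
        traits = frozenset(traits)
        return sum(c for s, c in self.patterns.items() if traits.issubset(s))

    def validate_against(self, trait_ns: Mapping[str, float], rtol: float = 0.01):
        for t, n in trait_ns.items():
            have = self.n_trait(t)
            if n > 0 and abs(have - n) > max(1.0, rtol * n):
                raise ValueError(
                    f"pattern counts give n={have} for trait {t}, expected {n:.0f}")

    @classmethod
    def complete(cls, trait_names: Sequence[str], n: int) -> "MissingnessDesign":
        return cls({frozenset(trait_names): int(n)}, trait_names)

    @classmethod
    def from_masks(cls, masks: Mapping[str, np.ndarray]) -> "MissingnessDesign":
        """Build from per-trait boolean observed-masks over the same individuals."""
        names = list(masks)
        stacked = np.column_stack([np.asarray(masks[t], dtype=bool) for t in names])
        codes = stacked @ (1 << np.arange(len(names)))
        uniq, counts = np.unique(codes, return_counts=True)
        pats = {
            frozenset(n for b, n in enumerate(names) if code >> b & 1): int(c)
            for code, c in zip(uniq, counts)
        }
        return cls(pats, names, total=stacked.shape[0])
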