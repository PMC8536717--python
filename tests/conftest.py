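import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from multifm.containers import GwasTable, ReferencePanel
from multifm.single import AbfContext

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20211022)


def hwe_genotypes(rng, n: int, freqs) -> np.ndarray:
    """Genotype columns with *exactly* Hardy-Weinberg counts (independently
    shuffled), so the sample variance of each column equals 2 f (1 - f) to
    machine precision and summary-statistic algebra is exact."""
    cols = []
    for f in freqs:
        n2 = round(n * f * f)
        n1 = round(n * 2 * f * (1 - f))
        col = np.array([2] * n2 + [1] * n1 + [0] * (n - n1 - n2), dtype=float)
        rng.shuffle(col)
        cols.append(col)
    return np.column_stack(cols)


def sample_context(X: np.ndarray, y: np.ndarray, snp_ids=None) -> AbfContext:
    """AbfContext with in-sample moments: marginal scores are the sample
    correlations and R the sample genotype correlation."""
    n, P = X.shape
    snp_ids = snp_ids or [f"s{i}" for i in range(P)]
    r = np.array([np.corrcoef(X[:, j], y)[0, 1] for j in range(P)])
    return AbfContext(N=n, var_y=float(np.var(y)), r_scores=r,
                      R=np.corrcoef(X, rowvar=False), snp_ids=snp_ids)


def panel_from_R(R, raf=None, snp_ids=None) -> ReferencePanel:
    R = np.asarray(R, dtype=float)
    P = R.shape[0]
    snp_ids = snp_ids or [f"s{i}" for i in range(P)]
    raf = np.full(P, 0.3) if raf is None else np.asarray(raf)
    return ReferencePanel(snp_ids, R, raf)


def gwas_from_sample(X, y, snp_ids=None, trait_name="trait", ddof=0) -> GwasTable:
    """Simple-regression GWAS table from an individual-level sample."""
    n, P = X.shape
    snp_ids = snp_ids or [f"s{i}" for i in range(P)]
    xm = X.mean(axis=0)
    sxx = ((X - xm) ** 2).sum(axis=0)
    sxy = (X - xm).T @ (y - y.mean())
    beta = sxy / sxx
    rss = ((y - y.mean()) ** 2).sum() - beta * sxy
    se = np.sqrt(rss / ((n - 2) * sxx))
    df = pd.DataFrame({
        "snp_id": snp_ids,
        "effect_allele": "A", "other_allele": "G",
        "eaf": xm / 2.0, "beta": beta, "se": se, "n": float(n)})
    return GwasTable(df, trait_name, trait_variance=float(np.var(y, ddof=ddof)),
                     n_trait=n)


@pytest.fixture(scope="session")
def study_pool():
    """One shared haplotype pool for the simulation-based tests."""
    from multifm.simulate import joint_tagging_region, simulate_haplotypes
    return simulate_haplotypes(joint_tagging_region(), 100_000, rng=20211022)
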