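"""Effective sample size from linear-mixed-model GWAS summary statistics.

With related individuals the nominal cohort size N overstates the
information in mixed-model summary statistics.  The simple-regression
identity se^2 = (var_y - beta^2 v_x) / ((N - 2) v_x), v_x = 2 f (1 - f),
inverts to a per-SNP effective size

    N_e = (var_y - beta^2 v_x) / (se^2 v_x) + 2,

and the trait-level effective size is the median over SNPs.  For unrelated
cohorts this recovers N; duplicated or related individuals shrink it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GwasRecord, GwasTable

logger = logging.getLogger("multifm")


def neff_per_snp(record: GwasRecord, var_y: float = 1.0) -> float:
    """Per-SNP effective sample size, floored at 1."""
    v_x = 2.0 * record.eaf * (1.0 - record.eaf)
    resid = var_y - record.beta ** 2 * v_x
    if resid <= 0:
        logger.warning("%s: beta^2 * 2f(1-f) exceeds trait variance; "
                       "flooring N_e at 1", record.snp_id)
        return 1.0
    return max(resid / (record.se ** 2 * v_x) + 2.0, 1.0)


@dataclass
class NeffResult:
    trait_name: str
    n_eff: float
    iqr: tuple[float, float]
    per_snp: pd.Series

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trait": [self.trait_name], "n_eff": [self.n_eff],
             "q1": [self.iqr[0]], "q3": [self.iqr[1]],
             "n_snps": [len(self.per_snp)]})


def neff_trait(gwas: GwasTable, min_snps: int = 30) -> NeffResult:
    """Median per-SNP effective sample size for one trait (with IQR)."""
    df = gwas.df
    if len(df) < min_snps:
        logger.warning("trait %s: only %d SNPs for N_e estimation (recommend >= %d)",
                       gwas.trait_name, len(df), min_snps)
    f = df["eaf"].to_numpy(dtype=float)
    v_x = 2.0 * f * (1.0 - f)
    resid = gwas.trait_variance - df["beta"].to_numpy(dtype=float) ** 2 * v_x
    bad = resid <= 0
    if bad.any():
        logger.warning("trait %s: %d SNPs with beta^2 variance exceeding var_y; "
                       "floored at N_e=1", gwas.trait_name, int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ne = resid / (df["se"].to_numpy(dtype=float) ** 2 * v_x) + 2.0
    ne = np.where(bad, 1.0, np.maximum(ne, 1.0))
    per_snp = pd.Series(ne, index=df["snp_id"])
    q1, med, q3 = np.percentile(ne, [25, 50, 75])
    return NeffResult(gwas.trait_name, float(med), (float(q1), float(q3)), per_snp)
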