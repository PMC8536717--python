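"""Groups of statistically near-equivalent SNPs.

Fine-mapping posteriors rarely resolve to single variants: SNPs in strong
LD substitute for one another across models.  Reporting therefore uses
disjoint SNP groups built from two signals: pairwise LD (r^2) and the
model-selection correlation r_model, the posterior-weighted correlation of
two SNPs' model-inclusion indicators.  Substitutes have high r^2 and
negative r_model (they rarely appear in a model together); distinct causal
variants co-appear and have positive r_model, which blocks merging even at
high LD.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ModelPosteriorTable, ReferencePanel

logger = logging.getLogger("multifm")

MPP_MIN = 0.001
R2_MIN = 0.5
BETWEEN_R2_MAX = 0.6


def _labels():
    letters = string.ascii_uppercase
    for size in range(1, 3):
        for combo in itertools.product(letters, repeat=size):
            yield "".join(combo)


def _inclusion_matrix(table: ModelPosteriorTable, snps: list[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(snps)}
    X = np.zeros((len(table), len(snps)))
    for row, model in enumerate(table.df["snps"]):
        for s in model:
            if s in pos:
                X[row, pos[s]] = 1.0
    return X


def _weighted_rmodel_matrix(table: ModelPosteriorTable, snps: list[str]) -> np.ndarray:
    """PP-weighted Pearson correlation of model-inclusion indicators.

    Zero-variance indicators (a SNP in every model, or none, under the
    posterior weights) get r_model = 0 with a logged flag.
    """
    X = _inclusion_matrix(table, snps)
    w = table.df["pp"].to_numpy(dtype=float)
    w = w / w.sum()
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    var = np.diag(cov).copy()
    flat = var <= 1e-14
    if flat.any():
        logger.debug("%d SNP inclusion indicators have zero posterior variance; "
                     "r_model set to 0", int(flat.sum()))
    sd = np.sqrt(np.where(flat, 1.0, var))
    r = cov / np.outer(sd, sd)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def model_selection_correlation(table: ModelPosteriorTable, snp_a: str,
                                snp_b: str) -> float:
    """r_model between two SNPs: negative when they substitute for each other."""
    return float(_weighted_rmodel_matrix(table, [snp_a, snp_b])[0, 1])


@dataclass
class SnpGroupSet:
    """Disjoint labelled groups of near-equivalent SNPs for one trait/method."""

    groups: dict[str, tuple[str, ...]]
    method: str
    mpp: pd.Series
    min_within_r2: dict[str, float] = field(default_factory=dict)
    between_r2: float = float("nan")
    r2_min_used: float = R2_MIN

    def group_mpp(self, label: str) -> float:
        return float(sum(self.mpp.get(s, 0.0) for s in self.groups[label]))

    def size(self, label: str) -> int:
        return len(self.groups[label])

    def label_of(self, snp_id: str) -> str | None:
        for label, members in self.groups.items():
            if snp_id in members:
                return label
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, members in self.groups.items():
            gm = self.group_mpp(label)
            for s in members:
                rows.append((label, s, self.mpp.get(s, 0.0), gm,
                             self.min_within_r2.get(label, 1.0)))
        return pd.DataFrame(rows, columns=["group", "snp_id", "mpp",
                                           "group_mpp", "min_within_r2"])

    def relabel(self, mapping: dict[str, str]) -> "SnpGroupSet":
        groups = {mapping.get(k, k): v for k, v in self.groups.items()}
        min_r2 = {mapping.get(k, k): v for k, v in self.min_within_r2.items()}
        return SnpGroupSet(groups, self.method, self.mpp, min_r2,
                           self.between_r2, self.r2_min_used)


def _build_once(snps: list[str], mpps: pd.Series, r2: np.ndarray,
                rmodel: np.ndarray, r2_min: float) -> list[list[int]]:
    groups: list[list[int]] = [[i] for i in range(len(snps))]
    while True:
        best_pair = None
        best_score = -1.0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia, ib = groups[a], groups[b]
                cross_r2 = r2[np.ix_(ia, ib)]
                if cross_r2.min() < r2_min:
                    continue
                if rmodel[np.ix_(ia, ib)].max() > 0:
                    continue
                score = cross_r2.mean()
                if score > best_score:
                    best_score = score
                    best_pair = (a, b)
        if best_pair is None:
            return groups
        a, b = best_pair
        groups[a] = groups[a] + groups[b]
        del groups[b]


def _mean_between_r2(groups: list[list[int]], r2: np.ndarray) -> float:
    vals = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            vals.append(r2[np.ix_(groups[a], groups[b])].mean())
    return float(np.mean(vals)) if vals else 0.0


def build_groups(table: ModelPosteriorTable, panel: ReferencePanel,
                 mpp_min: float = MPP_MIN, r2_min: float = R2_MIN,
                 method: str = "single-trait",
                 max_escalations: int = 8) -> SnpGroupSet:
    """Agglomerative SNP grouping from model posteriors and LD.

    Starting from singletons over SNPs with MPP > ``mpp_min``, repeatedly
    merge the admissible pair of groups with the highest mean cross-group
    r^2; a merge is admissible when every cross pair has r^2 >= ``r2_min``
    and model-selection correlation <= 0.  If the mean between-group r^2 of
    the result reaches 0.6, ``r2_min`` is raised by 0.05 and the build is
    repeated (at most ``max_escalations`` times).  Groups are labelled
    A, B, C, ... in decreasing group-MPP order.
    """
    mpps = table.mpp()
    snps = [s for s in panel.snp_ids if mpps.get(s, 0.0) > mpp_min]
    if not snps:
        return SnpGroupSet({}, method, mpps, {}, 0.0, r2_min)
    idx = panel.index(snps)
    r2 = panel.r2()[np.ix_(idx, idx)]
    rmodel = _weighted_rmodel_matrix(table, snps)
    current = r2_min
    for _attempt in range(max_escalations + 1):
        groups = _build_once(snps, mpps, r2, rmodel, current)
        between = _mean_between_r2(groups, r2)
        if between < BETWEEN_R2_MAX or len(groups) <= 1:
            break
        current = min(current + 0.05, 0.999)
    else:
        logger.warning("between-group mean r^2 %.3f still >= %.1f after %d "
                       "escalations", between, BETWEEN_R2_MAX, max_escalations)
    order = sorted(range(len(groups)),
                   key=lambda g: -sum(mpps.get(snps[i], 0.0) for i in groups[g]))
    labels = _labels()
    out: dict[str, tuple[str, ...]] = {}
    min_r2: dict[str, float] = {}
    for g in order:
        label = next(labels)
        members = tuple(snps[i] for i in groups[g])
        out[label] = members
        sub = r2[np.ix_(groups[g], groups[g])]
        min_r2[label] = float(sub.min())
    return SnpGroupSet(out, method, mpps, min_r2, between, current)


def map_labels(stfm: SnpGroupSet, ffm: SnpGroupSet,
               panel: ReferencePanel) -> SnpGroupSet:
    """Relabel joint-fine-mapping groups by their single-trait counterparts.

    A joint group overlapping exactly one single-trait (STFM) group inherits
    its label; when an STFM group A intersects several joint groups they
    become A.1, A.2, ... in decreasing group-MPP order; a joint group
    overlapping several STFM groups is assigned to the one with the larger
    member overlap (ties broken by higher mean cross-group r^2); joint
    groups overlapping nothing get fresh labels.
    """
    assignment: dict[str, str] = {}
    for flabel, fmembers in ffm.groups.items():
        overlaps = []
        for slabel, smembers in stfm.groups.items():
            n = len(set(fmembers) & set(smembers))
            if n:
                fi, si = panel.index(fmembers), panel.index(smembers)
                mean_r2 = float(panel.r2()[np.ix_(fi, si)].mean())
                overlaps.append((n, mean_r2, slabel))
        if overlaps:
            overlaps.sort(key=lambda t: (-t[0], -t[1], t[2]))
            assignment[flabel] = overlaps[0][2]
    mapping: dict[str, str] = {}
    used = set(stfm.groups)
    by_target: dict[str, list[str]] = {}
    for flabel, target in assignment.items():
        by_target.setdefault(target, []).append(flabel)
    for target, flabels in by_target.items():
        if len(flabels) == 1:
            mapping[flabels[0]] = target
        else:
            flabels.sort(key=lambda fl: -ffm.group_mpp(fl))
            for i, fl in enumerate(flabels, start=1):
                mapping[fl] = f"{target}.{i}"
    fresh = (lab for lab in _labels() if lab not in used)
    for flabel in ffm.groups:
        if flabel not in mapping:
            mapping[flabel] = next(fresh)
    return ffm.relabel(mapping)


def label_by_causal(groups: SnpGroupSet, causal_snps: dict[str, str],
                    panel: ReferencePanel, r2_proxy: float = 0.7) -> dict[str, str | None]:
    """Map causal-variant names to group labels for simulation evaluation.

    A group containing the causal variant gets its name; failing that, a
    group holding a SNP with r^2 > ``r2_proxy`` to the causal variant gets
    the name (the group with the strongest such proxy wins); otherwise None.
    """
    r2 = panel.r2()
    out: dict[str, str | None] = {}
    for name, snp in causal_snps.items():
        direct = groups.label_of(snp)
        if direct is not None:
            out[name] = direct
            continue
        best = (r2_proxy, None)
        if snp in set(panel.snp_ids):
            si = panel.index([snp])[0]
            for label, members in groups.groups.items():
                mi = panel.index(members)
                top = float(r2[si, mi].max())
                if top > best[0]:
                    best = (top, label)
        out[name] = best[1]
    return out
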