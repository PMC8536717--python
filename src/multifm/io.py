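"""Readers and writers for GWAS tables, reference panels, model posteriors.

All files are plain delimited text (tab by default, comma accepted).  The
model-posterior dialect is the whitespace-delimited ``rank config prob``
layout written by FINEMAP's ``.config`` files, with ``config`` a
comma-joined list of SNP ids; single-trait output is written in the same
dialect so it is self-importable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (GWAS_COLUMNS, GwasTable, ModelPosteriorTable,
                         ReferencePanel)

logger = logging.getLogger("multifm")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _read_delimited(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


def read_gwas(path, column_map: dict[str, str] | None = None,
              trait_name: str | None = None,
              trait_variance: float | None = None,
              n_trait: float | None = None) -> GwasTable:
    """Read a per-trait GWAS summary table from delimited text.

    ``column_map`` maps the canonical names (``snp_id, effect_allele,
    other_allele, eaf, beta, se, n``) to the file's header names.  Rows with
    eaf outside (0,1), non-positive/unparsable se, or any unparsable numeric
    field are dropped with a logged count.
    """
    df = _read_delimited(path)
    column_map = column_map or {}
    rename = {column_map.get(c, c): c for c in GWAS_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.rename(columns=rename)[list(GWAS_COLUMNS)]
    for col in ("eaf", "beta", "se", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n_raw = len(df)
    ok = (df["eaf"].between(0, 1, inclusive="neither") & (df["se"] > 0)
          & df[["eaf", "beta", "se", "n"]].notna().all(axis=1))
    dropped = n_raw - int(ok.sum())
    if dropped:
        logger.warning("%s: dropped %d/%d rows failing QC (eaf in (0,1), se>0, "
                       "numeric fields)", path, dropped, n_raw)
    df = df[ok]
    if df.empty:
        raise ValueError(f"{path}: no usable rows after filtering")
    name = trait_name or Path(str(path)).name.split(".")[0]
    return GwasTable(df.reset_index(drop=True), name, trait_variance, n_trait)


def read_reference(path, raf=None, kind: str = "auto",
                   alleles_path=None) -> ReferencePanel:
    """Read a reference panel from either a dosage matrix or a correlation matrix.

    A dosage file is individuals x SNPs with a header of SNP ids.  A
    correlation file is square with SNP ids as header (and is paired with a
    ``raf`` vector: either an array aligned to the header order or a two-column
    ``snp_id raf`` file path).  ``kind`` may be ``dosage``, ``correlation`` or
    ``auto`` (correlation iff ``raf`` was supplied).
    """
    df = _read_delimited(path)
    snp_ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    if kind == "auto":
        kind = "dosage" if raf is None else "correlation"
    alleles = None
    if alleles_path is not None:
        alleles = _read_delimited(alleles_path)
    if kind == "dosage":
        return ReferencePanel.from_dosage(mat, snp_ids, alleles=alleles)
    if kind != "correlation":
        raise ValueError(f"unknown panel kind {kind!r}")
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: correlation matrix is not square "
                         f"({mat.shape[0]}x{mat.shape[1]})")
    if isinstance(raf, (str, Path)):
        raf_df = _read_delimited(raf)
        raf = raf_df.set_index(raf_df.columns[0]).iloc[:, 0].loc[snp_ids].to_numpy()
    raf = np.asarray(raf, dtype=float)
    if raf.shape != (len(snp_ids),):
        raise ValueError("raf length does not match the correlation matrix")
    return ReferencePanel(snp_ids, mat, raf, alleles=alleles)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonise(gwas: GwasTable, panel: ReferencePanel,
              ambiguity_maf: float = 0.42) -> tuple[GwasTable, ReferencePanel]:
    """Restrict a GWAS table and panel to their shared SNPs, aligned alleles.

    Both outputs follow the panel's SNP order; effect alleles are flipped to
    the panel's reference allele (negating beta, complementing eaf) where
    needed.  Strand-ambiguous A/T and C/G SNPs with min(eaf, 1-eaf) >
    ``ambiguity_maf`` are dropped, as orientation cannot be resolved.  When
    the panel carries no allele table, alignment falls back to frequency
    proximity with a warning.
    """
    shared = [s for s in panel.snp_ids if s in set(gwas.snp_ids)]
    if not shared:
        raise ValueError("GWAS and reference panel share no SNPs")
    g = gwas.df.set_index("snp_id")
    keep_ids: list[str] = []
    rows = []
    have_alleles = panel.alleles is not None
    if not have_alleles:
        logger.warning("panel has no allele table; aligning alleles by "
                       "frequency proximity to the panel RAF")
    for snp in shared:
        rec = g.loc[snp]
        ea, oa = rec["effect_allele"], rec["other_allele"]
        eaf, beta = float(rec["eaf"]), float(rec["beta"])
        if _is_ambiguous(ea, oa) and min(eaf, 1 - eaf) > ambiguity_maf:
            logger.warning("dropping strand-ambiguous SNP %s (eaf=%.3f)", snp, eaf)
            continue
        raf = float(panel.raf[panel.index([snp])[0]])
        if have_alleles:
            pa = panel.alleles.loc[snp]
            ref, alt = str(pa["effect_allele"]), str(pa["other_allele"])
            if (ea, oa) == (ref, alt):
                flip = False
            elif (ea, oa) == (alt, ref):
                flip = True
            elif (_COMPLEMENT.get(ea), _COMPLEMENT.get(oa)) == (ref, alt):
                flip = False
                ea, oa = ref, alt
            elif (_COMPLEMENT.get(ea), _COMPLEMENT.get(oa)) == (alt, ref):
                flip = True
                ea, oa = alt, ref
            else:
                logger.warning("dropping SNP %s: alleles %s/%s do not match "
                               "panel %s/%s in either orientation", snp, ea, oa, ref, alt)
                continue
        else:
            flip = abs(eaf - raf) > abs((1 - eaf) - raf)
            ref, alt = (oa, ea) if flip else (ea, oa)
        if flip:
            eaf, beta = 1 - eaf, -beta
            ea, oa = oa, ea
        keep_ids.append(snp)
        rows.append((snp, ea, oa, eaf, beta, float(rec["se"]), float(rec["n"])))
    if not keep_ids:
        raise ValueError("no SNPs survived allele harmonisation")
    out_df = pd.DataFrame(rows, columns=list(GWAS_COLUMNS))
    out_gwas = GwasTable(out_df, gwas.trait_name, gwas.trait_variance, gwas.n_trait)
    return out_gwas, panel.subset(keep_ids)


def import_finemap_config(path, trait_name: str | None = None,
                          cpp_threshold: float = 0.99) -> ModelPosteriorTable:
    """Parse a FINEMAP ``.config``-style table into a ModelPosteriorTable.

    Expects whitespace-delimited text with a header containing ``rank``,
    ``config`` (comma-joined SNP ids; ``NULL`` or empty for the null model)
    and ``prob`` columns.  Duplicate configurations are merged by summing
    their probabilities; probabilities are renormalised to sum to one.
    """
    df = pd.read_csv(path, sep=r"\s+")
    low = {c.lower(): c for c in df.columns}
    for col in ("rank", "config", "prob"):
        if col not in low:
            raise ValueError(f"{path}: missing column {col!r}")
    models: dict[tuple, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = getattr(row, low["config"])
        prob = getattr(row, low["prob"])
        try:
            prob = float(prob)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {i}: unparsable probability {prob!r}")
        if pd.isna(raw) or str(raw).strip().upper() in ("", "NULL", "NONE"):
            snps: tuple[str, ...] = ()
        else:
            snps = tuple(sorted(s.strip() for s in str(raw).split(",") if s.strip()))
            if not snps:
                raise ValueError(f"{path}: line {i}: unparsable SNP list {raw!r}")
        if snps in models:
            logger.warning("%s: duplicate configuration %s; summing probabilities",
                           path, ",".join(snps) or "NULL")
        models[snps] = models.get(snps, 0.0) + prob
    out = pd.DataFrame({"snps": list(models), "pp": list(models.values())})
    name = trait_name or Path(str(path)).stem
    return ModelPosteriorTable(out, name, cpp_threshold=cpp_threshold)


def write_model_table(table: ModelPosteriorTable, path):
    """Write a model table in the self-importable ``rank config prob`` dialect."""
    with open(path, "w") as fh:
        fh.write("rank config prob\n")
        for rank, row in enumerate(table.df.itertuples(index=False), start=1):
            config = ",".join(row.snps) if row.snps else "NULL"
            fh.write(f"{rank} {config} {row.pp:.15g}\n")


def write_results(result, out_dir, force: bool = False):
    """Write per-trait model-PP, per-SNP MPP and SNP-group tables.

    ``result`` must expose ``model_tables`` (mapping trait -> ModelPosteriorTable)
    and may expose ``group_sets`` (mapping trait -> SnpGroupSet).  Files
    round-trip through :func:`import_finemap_config` / pandas readers.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is non-empty; use force=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    for trait, table in result.model_tables.items():
        write_model_table(table, out_dir / f"{trait}.models.txt")
        mpp = table.mpp()
        mpp.rename("mpp").rename_axis("snp_id").reset_index().to_csv(
            out_dir / f"{trait}.mpp.txt", sep="\t", index=False, float_format="%.15g")
    for trait, gset in getattr(result, "group_sets", {}).items():
        gset.to_frame().to_csv(out_dir / f"{trait}.groups.txt", sep="\t",
                               index=False, float_format="%.15g")
    logger.info("wrote results for %d trait(s) to %s", len(result.model_tables), out_dir)
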