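"""Phenome-wide harvest of per-SNP associations with QC and standardization.

Per (SNP, trait) cell the scan records a z-score (beta / SE) and standardized
effect sizes as a function of MAF and sample size n:

    SE* = 1 / sqrt(2 * MAF * (1 - MAF) * (n + z^2)),    beta* = z * SE*

so that effects harvested from studies with heterogeneous units are comparable
on a per-s.d. scale.  Missing SNPs fall back to the best LD proxy (r^2 >= 0.5
within 500 kb), with the proxy's effect re-aligned to the index SNP via the
sign of their dosage correlation in the reference panel.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import DegenerateInputError, ReferencePanel, dosage_correlation_sign, find_proxy

logger = logging.getLogger(__name__)


def zscore(beta: float, se: float) -> float:
    """z = beta / se; requires se > 0."""
    if se <= 0:
        raise DegenerateInputError("standard error must be positive")
    return beta / se


def standardize_effect(z: float, maf: float, n: float) -> tuple[float, float]:
    """Standardized (SE*, beta*) from a z-score, MAF and sample size."""
    if not 0 < maf < 1:
        raise ValueError("maf must lie in (0, 1)")
    if n <= 0:
        raise ValueError("n must be positive")
    se_std = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * (n + z * z))
    return float(se_std), float(z * se_std)


@dataclass(frozen=True)
class QCDecision:
    keep: bool
    reason: Optional[str] = None


def qc_filter(
    n: float,
    binary: bool = False,
    maf: Optional[float] = None,
    n_smallest_group: Optional[float] = None,
    min_n: float = 500,
    min_minor_alleles: float = 25,
) -> QCDecision:
    """Study-level QC: more than ``min_n`` individuals; binary traits need at
    least ``min_minor_alleles`` minor alleles in the smallest group."""
    if n <= min_n:
        return QCDecision(False, "small_n")
    if binary:
        if maf is None or n_smallest_group is None:
            return QCDecision(False, "missing_group_info")
        if 2.0 * maf * n_smallest_group < min_minor_alleles:
            return QCDecision(False, "few_minor_alleles")
    return QCDecision(True)


def default_trait_exclusion(trait_id: str) -> bool:
    """T2D-family traits are excluded from the scan to avoid circularity."""
    return bool(re.search(r"(t2d|type[ _]?2[ _]?diab|diabetes)", trait_id, re.I))


def _align_trait_record(row, effect_allele: str, other_allele: str) -> Optional[float]:
    """Beta of a trait record on ``effect_allele``; None if alleles don't match."""
    if row["ea"] == effect_allele and row["oa"] == other_allele:
        return float(row["beta"])
    if row["ea"] == other_allele and row["oa"] == effect_allele:
        return -float(row["beta"])
    return None


def harvest(
    profile_snps: pd.DataFrame,
    trait_tables: Mapping[str, pd.DataFrame],
    panel: Optional[ReferencePanel] = None,
    trait_meta: Optional[pd.DataFrame] = None,
    proxy_r2: float = 0.5,
    window_bp: int = 500_000,
    min_n: float = 500,
    min_minor_alleles: float = 25,
    exclude_pattern=default_trait_exclusion,
) -> pd.DataFrame:
    """Long-format SNP x trait association table aligned to the BMI-increasing allele.

    ``trait_meta`` (optional) carries trait_id, binary, n_smallest_group for
    QC.  Cells are left missing when neither a direct record nor a qualifying
    proxy exists.  Each cell satisfies beta_std = z * se_std exactly.
    """
    meta = {}
    if trait_meta is not None:
        meta = {r["trait_id"]: r for _, r in trait_meta.iterrows()}
    rows = []
    for trait_id, table in trait_tables.items():
        if exclude_pattern is not None and exclude_pattern(trait_id):
            logger.info("harvest: trait %s excluded by pattern", trait_id)
            continue
        tm = meta.get(trait_id, {})
        binary = bool(tm.get("binary", False))
        by_snp = table.set_index("snp_id")
        for snp in profile_snps.itertuples():
            rec, is_proxy, flip = None, False, 1.0
            if snp.snp_id in by_snp.index:
                rec = by_snp.loc[snp.snp_id]
            elif panel is not None and snp.snp_id in panel:
                proxy = find_proxy(
                    panel,
                    snp.snp_id,
                    [s for s in by_snp.index if s in panel],
                    r2_min=proxy_r2,
                    window_bp=window_bp,
                )
                if proxy is not None:
                    rec = by_snp.loc[proxy]
                    is_proxy = True
                    flip = float(dosage_correlation_sign(panel, snp.snp_id, proxy))
            if rec is None:
                continue
            n = float(rec["n"])
            maf = min(float(rec["eaf"]), 1.0 - float(rec["eaf"]))
            dec = qc_filter(
                n,
                binary=binary,
                maf=maf,
                n_smallest_group=tm.get("n_smallest_group"),
                min_n=min_n,
                min_minor_alleles=min_minor_alleles,
            )
            if not dec.keep:
                continue
            if is_proxy:
                beta = float(rec["beta"]) * flip
            else:
                beta = _align_trait_record(rec, snp.bmi_allele, snp.other_allele)
                if beta is None:
                    continue
            z = zscore(beta, float(rec["se"]))
            se_std, beta_std = standardize_effect(z, maf, n)
            rows.append(
                {
                    "trait_id": trait_id,
                    "snp_id": snp.snp_id,
                    "label": snp.label,
                    "is_proxy": is_proxy,
                    "z": z,
                    "se_std": se_std,
                    "beta_std": beta_std,
                    "maf": maf,
                    "n": n,
                    "binary": binary,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trait_id", "snp_id", "label", "is_proxy",
            "z", "se_std", "beta_std", "maf", "n", "binary",
        ],
    )


def z_matrix(scan: pd.DataFrame) -> pd.DataFrame:
    """Wide SNP x trait z-score matrix (index snp_id, one column per trait)."""
    return scan.pivot_table(index="snp_id", columns="trait_id", values="z")
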