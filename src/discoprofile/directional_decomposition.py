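"""Directional decomposition of trait instruments against T2D risk.

For a candidate mediating trait, instruments are SNPs genome-wide significant
for both the trait and BMI, clumped to independence and aligned to the
BMI-increasing allele; they are then split by the sign of their trait effect,
and each group's per-allele effect on T2D is pooled from summary statistics by
fixed-effect inverse-variance weighting.  Proteins use a single cis
instrument, where the pooled estimate reduces to the Wald estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import instrument_selection
from .sumstats_io import EmptyInputError, ReferencePanel

logger = logging.getLogger(__name__)

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class DirectionalGroup:
    """Per-allele pooled T2D effect of one sign group of trait instruments."""

    trait: str
    direction: str  # trait_up | trait_down
    snp_ids: tuple[str, ...]
    log_or: float
    se: float
    p: float
    or_: float
    ci_lo: float
    ci_hi: float


def select_trait_instruments(
    trait_ss: pd.DataFrame,
    bmi_ss: pd.DataFrame,
    panel: ReferencePanel,
    p_gw: float = 5e-8,
    r2_max: float = 0.01,
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Clumped dual-significant (trait and BMI) instruments, BMI-aligned.

    Output columns follow instrument_selection.assign_profiles, with
    ``beta_t2d``-named columns holding the trait effect.
    """
    cand = instrument_selection.cross_reference(bmi_ss, trait_ss, p_gw=p_gw)
    if cand.empty:
        logger.warning("select_trait_instruments: no qualifying SNPs")
        return cand
    clumped = instrument_selection.clump(
        cand, panel, r2_max=r2_max, window_bp=window_bp
    )
    aligned = instrument_selection.assign_profiles(clumped)
    return aligned.rename(
        columns={
            "beta_t2d": "beta_trait",
            "se_t2d": "se_trait",
            "p_t2d": "p_trait",
        }
    ).drop(columns=["label"])


def split_by_sign(instruments: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition BMI-aligned instruments by the sign of the trait effect."""
    up = instruments[instruments["beta_trait"] > 0].reset_index(drop=True)
    down = instruments[instruments["beta_trait"] < 0].reset_index(drop=True)
    return up, down


def ivw_pool(betas, ses) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance pooling: (beta, se, p)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise EmptyInputError("ivw_pool needs at least one estimate")
    w = 1.0 / (s * s)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def summary_grs_effect(
    group: pd.DataFrame,
    outcome_ss: pd.DataFrame,
    trait: str = "",
    direction: str = "",
) -> DirectionalGroup:
    """Pooled per-allele T2D log-OR of a sign group from summary statistics.

    Outcome records are re-expressed on each member's BMI-increasing allele
    before pooling; members missing from the outcome table are dropped with a
    log entry.
    """
    if group.empty:
        raise EmptyInputError("summary_grs_effect: empty instrument group")
    out = outcome_ss.set_index("snp_id")
    betas, ses, ids = [], [], []
    for r in group.itertuples():
        if r.snp_id not in out.index:
            logger.info("summary_grs_effect: %s missing from outcome stats", r.snp_id)
            continue
        rec = out.loc[r.snp_id]
        if rec["ea"] == r.bmi_allele and rec["oa"] == r.other_allele:
            beta = float(rec["beta"])
        elif rec["ea"] == r.other_allele and rec["oa"] == r.bmi_allele:
            beta = -float(rec["beta"])
        else:
            logger.info("summary_grs_effect: allele mismatch at %s", r.snp_id)
            continue
        betas.append(beta)
        ses.append(float(rec["se"]))
        ids.append(r.snp_id)
    beta, se, p = ivw_pool(betas, ses)
    return DirectionalGroup(
        trait=trait,
        direction=direction,
        snp_ids=tuple(ids),
        log_or=beta,
        se=se,
        p=p,
        or_=float(np.exp(beta)),
        ci_lo=float(np.exp(beta - _Z95 * se)),
        ci_hi=float(np.exp(beta + _Z95 * se)),
    )


def decompose_trait(
    trait_ss: pd.DataFrame,
    bmi_ss: pd.DataFrame,
    t2d_ss: pd.DataFrame,
    panel: ReferencePanel,
    trait: str = "",
    p_gw: float = 5e-8,
) -> list[DirectionalGroup]:
    """Full directional decomposition of one candidate mediating trait."""
    instruments = select_trait_instruments(trait_ss, bmi_ss, panel, p_gw=p_gw)
    if instruments.empty:
        return []
    groups = []
    for direction, sub in zip(("trait_up", "trait_down"), split_by_sign(instruments)):
        if sub.empty:
            continue
        groups.append(summary_grs_effect(sub, t2d_ss, trait=trait, direction=direction))
    return groups


def cis_instrument(
    protein_ss: pd.DataFrame,
    bmi_ss: pd.DataFrame,
    region_chrom: str,
    region_start: int,
    region_end: int,
    p_gw: float = 5e-8,
) -> Optional[pd.Series]:
    """Strongest dual-significant SNP in a gene's cis region, or None.

    Selection by smaller protein p, ties by position then id.
    """
    bmi_p = bmi_ss.set_index("snp_id")["p"]
    sub = protein_ss[
        (protein_ss["chrom"].astype(str) == str(region_chrom))
        & protein_ss["pos"].between(region_start, region_end)
        & (protein_ss["p"] < p_gw)
        & protein_ss["snp_id"].map(bmi_p).lt(p_gw)
    ]
    if sub.empty:
        return None
    return sub.sort_values(["p", "pos", "snp_id"], kind="mergesort").iloc[0]
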