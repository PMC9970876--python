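"""Selection and labelling of concordant / discordant instruments.

Cross-references the BMI and T2D GWAS, filters to common biallelic SNPs
genome-wide significant in both, clumps to near-independence against a
reference panel, aligns everything to the BMI-increasing allele and labels
each SNP ``concordant`` (T2D effect same-signed as BMI) or ``discordant``
(opposite-signed).  A replication GWAS provides an independent sign check.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from . import sumstats_io
from .sumstats_io import ReferencePanel, records_from_frame

logger = logging.getLogger(__name__)

RANK_STATS = ("sum_log_p", "min_p", "bmi_p")


def cross_reference(
    bmi_ss: pd.DataFrame,
    t2d_ss: pd.DataFrame,
    maf_min: float = 0.01,
    p_gw: float = 5e-8,
    palindrome_maf_cut: float = 0.30,
) -> pd.DataFrame:
    """Harmonized SNPs present in both GWAS, common and dual genome-wide significant.

    Returns a frame with columns snp_id, chrom, pos, ea, oa, eaf,
    beta_bmi, se_bmi, p_bmi, beta_t2d, se_t2d, p_t2d (T2D aligned to the BMI
    effect allele).  Drop reasons are counted in ``attrs["drop_counts"]``.
    """
    b_recs = {r.snp_id: r for r in records_from_frame(bmi_ss)}
    t_recs = {r.snp_id: r for r in records_from_frame(t2d_ss)}
    pos = bmi_ss.set_index("snp_id")[["chrom", "pos"]]
    rows = []
    drops: dict[str, int] = {}
    for snp_id in bmi_ss["snp_id"]:
        if snp_id not in t_recs:
            continue
        a, b = b_recs[snp_id], t_recs[snp_id]
        pair = sumstats_io.harmonize(a, b, palindrome_maf_cut=palindrome_maf_cut)
        if pair.dropped:
            drops[pair.drop_reason] = drops.get(pair.drop_reason, 0) + 1
            continue
        maf = min(pair.eaf, 1.0 - pair.eaf)
        if maf <= maf_min:
            drops["rare"] = drops.get("rare", 0) + 1
            continue
        if not (pair.p_a < p_gw and pair.p_b < p_gw):
            drops["not_dual_significant"] = drops.get("not_dual_significant", 0) + 1
            continue
        rows.append(
            {
                "snp_id": snp_id,
                "chrom": str(pos.loc[snp_id, "chrom"]),
                "pos": int(pos.loc[snp_id, "pos"]),
                "ea": pair.aligned_effect_allele,
                "oa": pair.other_allele,
                "eaf": pair.eaf,
                "beta_bmi": pair.beta_a,
                "se_bmi": pair.se_a,
                "p_bmi": pair.p_a,
                "beta_t2d": pair.beta_b,
                "se_t2d": pair.se_b,
                "p_t2d": pair.p_b,
            }
        )
    if not rows:
        logger.warning("cross_reference: empty intersection after filters")
    out = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "ea", "oa", "eaf",
            "beta_bmi", "se_bmi", "p_bmi", "beta_t2d", "se_t2d", "p_t2d",
        ],
    )
    out.attrs["drop_counts"] = drops
    return out


def _rank_value(row, rank_stat: str) -> float:
    """Larger = stronger; deterministic given the statistic."""
    if rank_stat == "sum_log_p":
        return -np.log10(row.p_bmi) - np.log10(row.p_t2d)
    if rank_stat == "min_p":
        return -np.log10(min(row.p_bmi, row.p_t2d))
    if rank_stat == "bmi_p":
        return -np.log10(row.p_bmi)
    raise ValueError(f"unknown rank_stat {rank_stat!r}")


def clump(
    candidates: pd.DataFrame,
    panel: ReferencePanel,
    r2_max: float = 0.01,
    window_bp: int = 500_000,
    rank_stat: str = "sum_log_p",
) -> pd.DataFrame:
    """Greedy LD clumping: keep the top-ranked SNP, drop neighbours with
    r^2 >= ``r2_max`` within ``window_bp``, repeat.  Output order = selection
    order.  Candidates absent from the panel are dropped with a log entry."""
    present = candidates["snp_id"].isin(panel.meta["snp_id"]).to_numpy()
    n_absent = int((~present).sum())
    if n_absent:
        logger.info("clump: dropped %d candidates absent from panel", n_absent)
    cand = candidates.loc[present].copy()
    cand["_rank"] = [_rank_value(r, rank_stat) for r in cand.itertuples()]
    # stable, deterministic order: strongest first, ties by id
    cand = cand.sort_values(["_rank", "snp_id"], ascending=[False, True])
    kept_rows = []
    remaining = list(cand.itertuples())
    while remaining:
        top = remaining.pop(0)
        kept_rows.append(top)
        survivors = []
        for other in remaining:
            if other.chrom == top.chrom and abs(other.pos - top.pos) <= window_bp:
                if sumstats_io.ld_r2(panel, top.snp_id, other.snp_id) >= r2_max:
                    continue
            survivors.append(other)
        remaining = survivors
    out = pd.DataFrame(kept_rows).drop(columns=["Index", "_rank"], errors="ignore")
    return out.reset_index(drop=True)


def assign_profiles(clumped: pd.DataFrame) -> pd.DataFrame:
    """Align to the BMI-increasing allele and label by the sign of the T2D effect.

    If beta_bmi < 0 both effects are flipped and the allele pair swapped.
    SNPs with beta_t2d exactly 0 are excluded (the label is sign-defined).
    Output columns: snp_id, chrom, pos, bmi_allele, other_allele, eaf (of the
    BMI-increasing allele), beta_bmi, se_bmi, p_bmi, beta_t2d, se_t2d, p_t2d,
    label.
    """
    rows = []
    n_zero = 0
    for r in clumped.itertuples():
        beta_bmi, beta_t2d = r.beta_bmi, r.beta_t2d
        ea, oa, eaf = r.ea, r.oa, r.eaf
        if beta_bmi < 0:
            beta_bmi, beta_t2d = -beta_bmi, -beta_t2d
            ea, oa, eaf = oa, ea, 1.0 - eaf
        if beta_t2d == 0:
            n_zero += 1
            continue
        rows.append(
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "bmi_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta_bmi": beta_bmi,
                "se_bmi": r.se_bmi,
                "p_bmi": r.p_bmi,
                "beta_t2d": beta_t2d,
                "se_t2d": r.se_t2d,
                "p_t2d": r.p_t2d,
                "label": "concordant" if beta_t2d > 0 else "discordant",
            }
        )
    if n_zero:
        logger.info("assign_profiles: excluded %d SNPs with beta_t2d == 0", n_zero)
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chrom", "pos", "bmi_allele", "other_allele", "eaf",
            "beta_bmi", "se_bmi", "p_bmi", "beta_t2d", "se_t2d", "p_t2d", "label",
        ],
    )


def replicate_signs(
    profile: pd.DataFrame, replication_ss: pd.DataFrame
) -> pd.DataFrame:
    """Check T2D effect directions against an independent replication GWAS.

    ``replicated_sign`` is True when the replication effect, re-expressed on
    the BMI-increasing allele, has the same sign as ``beta_t2d``; SNPs absent
    from the replication set stay unset (NA).
    """
    rep = replication_ss.set_index("snp_id")
    out = profile.copy()
    flags: list[Optional[bool]] = []
    for r in profile.itertuples():
        if r.snp_id not in rep.index:
            flags.append(None)
            continue
        rr = rep.loc[r.snp_id]
        if rr["ea"] == r.bmi_allele and rr["oa"] == r.other_allele:
            beta_rep = rr["beta"]
        elif rr["ea"] == r.other_allele and rr["oa"] == r.bmi_allele:
            beta_rep = -rr["beta"]
        else:
            flags.append(None)
            continue
        flags.append(bool(np.sign(beta_rep) == np.sign(r.beta_t2d)))
    out["replicated_sign"] = pd.array(flags, dtype="boolean")
    return out


def select_instruments(
    bmi_ss: pd.DataFrame,
    t2d_ss: pd.DataFrame,
    panel: ReferencePanel,
    replication_ss: Optional[pd.DataFrame] = None,
    maf_min: float = 0.01,
    p_gw: float = 5e-8,
    r2_max: float = 0.01,
    window_bp: int = 500_000,
    rank_stat: str = "sum_log_p",
) -> pd.DataFrame:
    """Full pipeline: cross-reference -> clump -> assign profiles -> sign check."""
    cand = cross_reference(bmi_ss, t2d_ss, maf_min=maf_min, p_gw=p_gw)
    if cand.empty:
        logger.warning("select_instruments: no candidates survive filtering")
        return assign_profiles(cand)
    clumped = clump(cand, panel, r2_max=r2_max, window_bp=window_bp, rank_stat=rank_stat)
    profile = assign_profiles(clumped)
    if replication_ss is not None and not profile.empty:
        profile = replicate_signs(profile, replication_ss)
    return profile
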