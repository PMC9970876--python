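"""Summary-based Mendelian randomization (SMR) and the HEIDI linkage test.

SMR uses the strongest cis-eQTL as an instrument for a gene's expression and
tests its pleiotropic effect on an outcome with the Wald ratio
b_SMR = β_outcome / β_eQTL and the combined statistic

    T_SMR = z_out² · z_eQTL² / (z_out² + z_eQTL²)  ~  χ²₁.

HEIDI distinguishes a single shared causal variant (pleiotropy) from distinct
variants in LD (linkage) by testing heterogeneity of the per-SNP Wald ratios
of secondary SNPs in LD with the lead: under pleiotropy every SNP in the
region estimates the same ratio.  The statistic is a correlated sum of
squared standardized differences, referred to an eigenvalue-weighted χ²
mixture (Imhof numeric inversion, Monte-Carlo fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .profile_comparison import bh_fdr
from .sumstats_io import DegenerateInputError

logger = logging.getLogger(__name__)

#: secondary SNPs must reach chi2_1 > 10 for expression (convention of the
#: originating method; this screen's own choice where the source is silent)
HEIDI_EQTL_P_FLOOR = float(stats.chi2.sf(10.0, 1))


@dataclass(frozen=True)
class SmrResult:
    gene: str
    tissue: str
    outcome: str
    lead_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: Optional[float]
    n_heidi_snps: int
    q_smr: Optional[float] = None
    passes: Optional[bool] = None


def top_cis_eqtl(
    eqtls: pd.DataFrame,
    gene: str,
    tss: int,
    bmi_ss: pd.DataFrame,
    window_bp: int = 500_000,
    p_gw: float = 5e-8,
) -> Optional[pd.Series]:
    """Lead cis-eQTL: minimum eQTL p within the window, requiring genome-wide
    significance for both expression and BMI.  Ties by position then id."""
    sub = eqtls[(eqtls["gene"] == gene) & (np.abs(eqtls["pos"] - tss) <= window_bp)]
    sub = sub[sub["p"] < p_gw]
    if sub.empty:
        return None
    bmi_p = bmi_ss.set_index("snp_id")["p"]
    sub = sub[sub["snp_id"].map(bmi_p).lt(p_gw)]
    if sub.empty:
        return None
    sub = sub.sort_values(["p", "pos", "snp_id"], kind="mergesort")
    return sub.iloc[0]


def smr_test(
    beta_eqtl: float, se_eqtl: float, beta_out: float, se_out: float
) -> tuple[float, float, float]:
    """(b_SMR, se_SMR, p_SMR) from harmonized eQTL and outcome effects."""
    if beta_eqtl == 0:
        raise DegenerateInputError("smr_test: zero eQTL effect is not a valid instrument")
    z_e = beta_eqtl / se_eqtl
    z_o = beta_out / se_out
    b = beta_out / beta_eqtl
    t = (z_o**2 * z_e**2) / (z_o**2 + z_e**2) if (z_o != 0 or z_e != 0) else 0.0
    p = float(stats.chi2.sf(t, 1))
    se = abs(b) / np.sqrt(t) if t > 0 else np.inf
    return float(b), float(se), p


def imhof_pvalue(q: float, lam: np.ndarray, seed: int = 12345) -> float:
    """P(Σ λ_i χ²_1,i > q) by Imhof's integral.

    The integrand oscillates asymptotically with period 4π/q, so the tail is
    summed over half-period chunks with repeated averaging of partial sums
    (Euler acceleration of the alternating series).  Falls back to Monte Carlo
    (10⁶ draws, fixed seed) if the numeric inversion misbehaves.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * q * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return np.sin(theta) / (u * rho)

    try:
        L = 2.0 * np.pi / max(q, 1e-2)  # half oscillation period
        head, _ = integrate.quad(integrand, 0.0, L, limit=200)
        terms = []
        for i in range(1, 81):
            a, _ = integrate.quad(integrand, i * L, (i + 1) * L, limit=60)
            terms.append(a)
            if abs(a) < 1e-12 and i > 5:
                break
        s = np.cumsum(terms)
        while s.size > 1:
            s = 0.5 * (s[:-1] + s[1:])
        p = 0.5 + (head + float(s[0])) / np.pi
        if not np.isfinite(p) or p < -1e-6 or p > 1 + 1e-6:
            raise RuntimeError("imhof inversion out of range")
    except Exception:
        rng = np.random.default_rng(seed)
        draws = rng.chisquare(1, size=(10**6, lam.size)) @ lam
        p = float(np.mean(draws > q))
    return float(min(max(p, 1e-300), 1.0))


def heidi_test(
    region: pd.DataFrame,
    ld: np.ndarray,
    lead_snp: str,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
    eqtl_p_floor: float = HEIDI_EQTL_P_FLOOR,
) -> tuple[Optional[float], int]:
    """HEIDI heterogeneity test around the lead SNP.

    ``region`` needs one row per SNP with columns snp_id, beta_eqtl, se_eqtl,
    p_eqtl, beta_out, se_out; ``ld`` is the SNP x SNP correlation matrix in
    the same row order.  Secondary SNPs need r² to the lead inside
    ``r2_window`` and expression significance below ``eqtl_p_floor``; the
    strongest ``max_snps`` by eQTL p are used.  Returns (p_HEIDI, n_used);
    p is None when no secondary SNP qualifies.
    """
    snp_ids = region["snp_id"].tolist()
    try:
        i_lead = snp_ids.index(lead_snp)
    except ValueError:
        raise DegenerateInputError(f"lead SNP {lead_snp!r} not in region") from None
    r_lead = ld[i_lead]
    r2 = r_lead**2
    lo, hi = r2_window
    cand = [
        j
        for j in range(len(snp_ids))
        if j != i_lead
        and lo <= r2[j] <= hi
        and region["p_eqtl"].iloc[j] < eqtl_p_floor
    ]
    cand.sort(key=lambda j: (region["p_eqtl"].iloc[j], j))
    cand = cand[:max_snps]
    if not cand:
        return None, 0
    idx = [i_lead] + cand
    bx = region["beta_eqtl"].to_numpy(dtype=float)[idx]
    sx = region["se_eqtl"].to_numpy(dtype=float)[idx]
    by = region["beta_out"].to_numpy(dtype=float)[idx]
    sy = region["se_out"].to_numpy(dtype=float)[idx]
    R = ld[np.ix_(idx, idx)]
    b = by / bx
    # delta-method covariance of the Wald ratios (independent eQTL/outcome samples):
    # cov(b_i,b_j) = r_ij sy_i sy_j/(bx_i bx_j) + b_i b_j r_ij sx_i sx_j/(bx_i bx_j)
    denom = np.outer(bx, bx)
    cov_b = R * np.outer(sy, sy) / denom + np.outer(b, b) * R * np.outer(sx, sx) / denom
    m = len(cand)
    # d_i = b_i - b_lead, i = 1..m
    A = np.zeros((m, m + 1))
    A[:, 0] = -1.0
    A[:, 1:] = np.eye(m)
    V = A @ cov_b @ A.T
    sd = np.sqrt(np.diag(V))
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        return None, 0
    d = b[1:] - b[0]
    zd = d / sd
    T = float(np.sum(zd**2))
    C = V / np.outer(sd, sd)
    lam = np.linalg.eigvalsh((C + C.T) / 2.0)
    return imhof_pvalue(T, lam), m


def smr_with_heidi(
    region: pd.DataFrame,
    ld: np.ndarray,
    lead_snp: str,
    gene: str = "",
    tissue: str = "",
    outcome: str = "",
    **heidi_kwargs,
) -> SmrResult:
    """SMR at the lead SNP plus HEIDI over the region (shared input layout)."""
    row = region.set_index("snp_id").loc[lead_snp]
    b, se, p = smr_test(
        float(row["beta_eqtl"]), float(row["se_eqtl"]),
        float(row["beta_out"]), float(row["se_out"]),
    )
    p_heidi, n_used = heidi_test(region, ld, lead_snp, **heidi_kwargs)
    return SmrResult(gene, tissue, outcome, lead_snp, b, se, p, p_heidi, n_used)


def _region_table(
    eqtl: pd.DataFrame, outcome: pd.DataFrame
) -> pd.DataFrame:
    """Join eQTL and outcome stats by snp_id into the HEIDI region layout."""
    out = outcome.set_index("snp_id")
    df = pd.DataFrame(
        {
            "snp_id": eqtl["snp_id"].to_numpy(),
            "beta_eqtl": eqtl["beta"].to_numpy(dtype=float),
            "se_eqtl": eqtl["se"].to_numpy(dtype=float),
            "p_eqtl": eqtl["p"].to_numpy(dtype=float),
        }
    )
    df["beta_out"] = df["snp_id"].map(out["beta"]).to_numpy(dtype=float)
    df["se_out"] = df["snp_id"].map(out["se"]).to_numpy(dtype=float)
    return df.dropna(subset=["beta_out", "se_out"]).reset_index(drop=True)


def discordant_gene_screen(
    gene_regions: Sequence[dict],
    q_level: float = 0.05,
    heidi_cut: float = 0.01,
    window_bp: int = 500_000,
    p_gw: float = 5e-8,
) -> tuple[pd.DataFrame, list[str]]:
    """Screen genes for opposite-direction pleiotropic effects on BMI and T2D.

    Each element of ``gene_regions`` is a dict with keys gene, tissue, eqtl
    (cis-eQTL frame incl. tss), bmi, t2d (outcome frames), ld (correlation
    matrix aligned to the eqtl frame rows).  Per gene x tissue the lead eQTL
    is chosen, SMR run against both outcomes, BH-FDR applied per outcome
    across all tests, and a gene passes when both outcomes are FDR-significant
    with p_HEIDI > ``heidi_cut`` and the SMR effects have opposite signs.
    Returns (full result table, discordant gene list).
    """
    results: list[SmrResult] = []
    for reg in gene_regions:
        gene, tissue = reg["gene"], reg.get("tissue", "")
        eqtl = reg["eqtl"]
        tss = int(eqtl["tss"].iloc[0]) if "tss" in eqtl.columns else int(eqtl["pos"].iloc[0])
        lead = top_cis_eqtl(eqtl, gene, tss, reg["bmi"], window_bp=window_bp, p_gw=p_gw)
        if lead is None:
            continue
        for outcome_name in ("BMI", "T2D"):
            outcome_ss = reg["bmi"] if outcome_name == "BMI" else reg["t2d"]
            region = _region_table(eqtl, outcome_ss)
            ld_idx = [i for i, s in enumerate(eqtl["snp_id"]) if s in set(region["snp_id"])]
            ld = reg["ld"][np.ix_(ld_idx, ld_idx)]
            results.append(
                smr_with_heidi(
                    region, ld, lead["snp_id"],
                    gene=gene, tissue=tissue, outcome=outcome_name,
                )
            )
    if not results:
        return pd.DataFrame(), []
    df = pd.DataFrame([r.__dict__ for r in results])
    df["q_smr"] = np.nan
    for outcome_name, idx in df.groupby("outcome").groups.items():
        q, _ = bh_fdr(df.loc[idx, "p_smr"], q_level)
        df.loc[idx, "q_smr"] = q
    passes = []
    for (gene, tissue), sub in df.groupby(["gene", "tissue"]):
        if set(sub["outcome"]) != {"BMI", "T2D"}:
            continue
        ok = (
            (sub["q_smr"] <= q_level).all()
            and sub["p_heidi"].notna().all()
            and (sub["p_heidi"] > heidi_cut).all()
        )
        signs = np.sign(sub.set_index("outcome")["b_smr"])
        if ok and signs["BMI"] != signs["T2D"]:
            passes.append((gene, tissue))
    pass_set = set(passes)
    df["passes"] = [
        (g, t) in pass_set for g, t in zip(df["gene"], df["tissue"])
    ]
    discordant_genes = sorted({g for g, _ in passes})
    return df, discordant_genes
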