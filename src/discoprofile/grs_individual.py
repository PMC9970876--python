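"""Individual-level genetic risk scores and their association batteries.

The concordant and discordant GRSs are unweighted allele counts over the
respective SNP sets (PRS_Pi = Σ_{j∈P} G_ij).  Batteries: logistic phecode
PheWAS with case/control/exclusion logic and a minimum case count, linear
models for median lab values (optionally inverse-normalized), Cox
proportional-hazards mortality restricted to cause codes, and
Kruskal–Wallis subgroup tests for individuals in the top decile of either
profile score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .profile_comparison import DeltaResult, PooledEffect, delta_test
from .sumstats_io import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex") + tuple(f"PC{k}" for k in range(1, 11))


@dataclass(frozen=True)
class AssocEstimate:
    """Per-allele association of a GRS with one outcome."""

    outcome: str
    profile: str
    effect: float  # log-OR, per-s.d. beta, or log-HR per allele
    se: float
    p: float
    n: int
    n_cases: Optional[int] = None
    status: str = "ok"  # ok | separation | degenerate | skipped


def compute_grs(dosages: pd.DataFrame, snp_set: Sequence[str]) -> pd.Series:
    """Unweighted sum of risk-allele dosages over ``snp_set`` per individual.

    ``dosages`` must hold an ``iid`` column plus one column per SNP, already
    oriented to the risk (BMI-increasing) allele.  Missing dosages are
    mean-imputed with a log entry.
    """
    snp_set = list(snp_set)
    if not snp_set:
        raise ConfigurationError("compute_grs: empty SNP set")
    missing_cols = [s for s in snp_set if s not in dosages.columns]
    if missing_cols:
        raise ConfigurationError(f"SNPs absent from dosage table: {missing_cols[:5]}")
    G = dosages[snp_set].to_numpy(dtype=float)
    n_missing = int(np.isnan(G).sum())
    if n_missing:
        logger.info("compute_grs: mean-imputed %d missing dosages", n_missing)
        col_mean = np.nanmean(G, axis=0)
        G = np.where(np.isnan(G), col_mean, G)
    return pd.Series(G.sum(axis=1), index=dosages["iid"].to_numpy(), name="grs")


def orient_dosages(
    dosages: pd.DataFrame, profile_snps: pd.DataFrame, panel_meta: pd.DataFrame
) -> pd.DataFrame:
    """Re-orient raw alt-allele dosages so columns count BMI-increasing alleles."""
    alt = dict(zip(panel_meta["snp_id"], panel_meta["alt"]))
    out = dosages.copy()
    for r in profile_snps.itertuples():
        if r.snp_id in out.columns and alt.get(r.snp_id) != r.bmi_allele:
            out[r.snp_id] = 2.0 - out[r.snp_id]
    return out


def phecode_status(
    events: pd.DataFrame,
    exclusions: pd.DataFrame,
    iids: Sequence[str],
    phecode: str,
    two_visit_rule: bool = True,
) -> pd.Series:
    """Case/control/excluded status per individual for one phecode.

    A case needs codes on at least two different days when the two-visit rule
    is enabled (one otherwise); individuals on the exclusion list that are not
    cases are excluded.
    """
    ev = events[events["phecode"] == phecode]
    days_per_iid = ev.groupby("iid")["day"].nunique()
    need = 2 if two_visit_rule else 1
    cases = set(days_per_iid[days_per_iid >= need].index)
    excl = set(exclusions.loc[exclusions["phecode"] == phecode, "iid"])
    return pd.Series(
        [
            "case" if i in cases else ("excluded" if i in excl else "control")
            for i in iids
        ],
        index=list(iids),
    )


def _logit_fit(y: np.ndarray, X: pd.DataFrame) -> tuple[float, float, float, str]:
    """(effect, se, p, status) for the first non-constant column of X."""
    Xc = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            return float(res.params["grs"]), float(res.bse["grs"]), float(res.pvalues["grs"]), "separation"
        return float(res.params["grs"]), float(res.bse["grs"]), float(res.pvalues["grs"]), "ok"
    except Exception:
        return np.nan, np.nan, np.nan, "separation"


def phewas(
    grs: pd.Series,
    events: pd.DataFrame,
    exclusions: pd.DataFrame,
    covariates: pd.DataFrame,
    phecodes: Optional[Sequence[str]] = None,
    min_cases: int = 200,
    profile: str = "C",
    covariate_cols: Sequence[str] = DEFAULT_COVARIATES,
    two_visit_rule: bool = True,
) -> list[AssocEstimate]:
    """Logistic PheWAS of a GRS over phecodes with at least ``min_cases`` cases."""
    cov = covariates.set_index("iid").loc[grs.index, list(covariate_cols)]
    if phecodes is None:
        phecodes = sorted(events["phecode"].unique())
    out = []
    for code in phecodes:
        status = phecode_status(events, exclusions, grs.index, code, two_visit_rule)
        mask = status != "excluded"
        y = (status[mask] == "case").astype(int).to_numpy()
        n_cases = int(y.sum())
        if n_cases < min_cases:
            out.append(
                AssocEstimate(code, profile, np.nan, np.nan, np.nan,
                              int(mask.sum()), n_cases, status="skipped")
            )
            continue
        g = grs[mask]
        if np.std(g.to_numpy()) == 0:
            out.append(
                AssocEstimate(code, profile, np.nan, np.nan, np.nan,
                              int(mask.sum()), n_cases, status="degenerate")
            )
            continue
        X = cov[mask.to_numpy()].copy()
        X.insert(0, "grs", g.to_numpy())
        eff, se, p, st = _logit_fit(y, X)
        out.append(AssocEstimate(code, profile, eff, se, p, int(mask.sum()), n_cases, st))
    return out


def inverse_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offsets)."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.375) / (len(x) + 0.25))


def labwas(
    grs: pd.Series,
    labs: pd.DataFrame,
    covariates: pd.DataFrame,
    inverse_normalize: bool = True,
    profile: str = "C",
    covariate_cols: Sequence[str] = DEFAULT_COVARIATES,
) -> list[AssocEstimate]:
    """Linear models of per-individual median lab values on a GRS."""
    cov = covariates.set_index("iid")
    out = []
    for lab, sub in labs.groupby("lab", sort=True):
        med = sub.groupby("iid")["value"].median()
        iids = [i for i in grs.index if i in med.index]
        y = med.loc[iids].to_numpy(dtype=float)
        if inverse_normalize:
            y = inverse_normal(y)
        X = cov.loc[iids, list(covariate_cols)].copy()
        X.insert(0, "grs", grs.loc[iids].to_numpy())
        Xc = sm.add_constant(X, has_constant="add")
        res = sm.OLS(y, Xc).fit()
        out.append(
            AssocEstimate(
                lab, profile,
                float(res.params["grs"]), float(res.bse["grs"]),
                float(res.pvalues["grs"]), len(iids),
            )
        )
    return out


def cox_mortality(
    grs: pd.Series,
    survival: pd.DataFrame,
    covariates: pd.DataFrame,
    cause_codes: Sequence[str],
    profile: str = "C",
    covariate_cols: Sequence[str] = DEFAULT_COVARIATES,
) -> AssocEstimate:
    """Cox PH fit of cause-specific mortality on a GRS.

    Events are deaths whose primary cause is in ``cause_codes``; deaths from
    other causes are censored at the death time.
    """
    surv = survival.set_index("iid").loc[grs.index]
    event = (surv["event"].astype(bool) & surv["cause"].isin(set(cause_codes))).astype(int)
    if event.sum() == 0:
        raise DegenerateInputError("cox_mortality: zero qualifying events")
    cov = covariates.set_index("iid").loc[grs.index, list(covariate_cols)]
    df = cov.copy()
    df["grs"] = grs.to_numpy()
    df["time"] = surv["time"].to_numpy()
    df["event"] = event.to_numpy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return AssocEstimate(
        "cv_mortality", profile,
        float(cph.params_["grs"]),
        float(cph.standard_errors_["grs"]),
        float(cph.summary.loc["grs", "p"]),
        len(df), int(event.sum()),
    )


def compare_estimates(est_c: AssocEstimate, est_d: AssocEstimate) -> DeltaResult:
    """δ-test on two per-allele estimates (log scale for OR/HR outcomes)."""
    pc = PooledEffect(est_c.outcome, "C", est_c.effect, est_c.se, 0.0, 1)
    pdl = PooledEffect(est_d.outcome, "D", est_d.effect, est_d.se, 0.0, 1)
    return delta_test(pc, pdl)


def estimate_from_ci(
    outcome: str, profile: str, point: float, lo: float, hi: float,
    ratio_scale: bool = False, n: int = 0,
) -> AssocEstimate:
    """Build an estimate from a reported point value and 95% CI.

    Ratio-scale reports (OR/HR) are converted through log before
    SE = CI width / (2 × 1.96).
    """
    if ratio_scale:
        point, lo, hi = np.log(point), np.log(lo), np.log(hi)
    se = (hi - lo) / (2.0 * 1.959963984540054)
    return AssocEstimate(outcome, profile, float(point), float(se), np.nan, n)


def top_decile_mask(score: pd.Series) -> pd.Series:
    """True for scores at or above the type-7 empirical 90th percentile."""
    thr = np.quantile(score.to_numpy(dtype=float), 0.9, method="linear")
    return score >= thr


def extreme_decile_analysis(
    grs_c: pd.Series,
    grs_d: pd.Series,
    obesity_mask: pd.Series,
    traits: pd.DataFrame,
    sex: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, float]:
    """Subgroup tests of extreme-GRS individuals among those with obesity.

    Within individuals with obesity, extreme-C/extreme-D = top decile of the
    respective score.  Per trait (columns of ``traits``, indexed by iid) a
    Kruskal–Wallis test compares each extreme group against all other
    individuals with obesity; with ``sex`` given, also stratified per sex.
    Returns (per-trait statistics, union-membership fraction).
    """
    ob = obesity_mask[obesity_mask].index
    ec = top_decile_mask(grs_c.loc[ob])
    ed = top_decile_mask(grs_d.loc[ob])
    union_fraction = float((ec | ed).mean())
    rows = []
    strata = [("all", pd.Series(True, index=ob))]
    if sex is not None:
        strata += [(f"sex_{v}", sex.loc[ob] == v) for v in sorted(sex.loc[ob].unique())]
    for trait in traits.columns:
        x = traits.loc[ob, trait]
        for grp_name, grp in (("extreme_C", ec), ("extreme_D", ed)):
            for stratum, smask in strata:
                a = x[(grp & smask).to_numpy()].dropna()
                b = x[((~grp) & smask).to_numpy()].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                stat, p = stats.kruskal(a, b)
                rows.append(
                    {
                        "trait": trait,
                        "group": grp_name,
                        "stratum": stratum,
                        "n_extreme": len(a),
                        "n_rest": len(b),
                        "kw_stat": float(stat),
                        "p": float(p),
                        "median_extreme": float(a.median()),
                        "median_rest": float(b.median()),
                    }
                )
    return pd.DataFrame(rows), union_fraction
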