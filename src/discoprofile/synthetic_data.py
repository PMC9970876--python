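"""Synthetic worlds with recorded ground truth for every pipeline input.

Emulates, at desk scale, the data the analysis consumes: an LD-block-structured
genotype reference panel, paired BMI/T2D GWAS summary statistics with planted
concordant and discordant causal SNPs, a panel of secondary-trait associations,
an individual-level cohort (phenotypes, phecode events, labs, censored survival),
cis-eQTL regions under pleiotropy / linkage / null scenarios, and a tissue
expression atlas with promoter/enhancer marks.

Design notes
------------
* Genotypes come from a Gaussian copula: latent AR(1) haplotypes thresholded to
  alleles.  Because two binary variables with unequal frequencies cannot be
  highly correlated, MAF is drawn once per LD block and the latent correlation
  is calibrated (tetrachoric inversion) so the realized dosage correlation of
  adjacent SNPs matches ``within_block_ld``.
* GWAS summary statistics are generated analytically: marginal effects are
  propagated through the empirical block LD of the panel and observed effects
  add correlated noise at the standard error implied by MAF and sample size
  (continuous traits: SE = 1/sqrt(2*MAF*(1-MAF)*n)).  Binary traits use the same
  form with an effective sample size, on the log-OR scale.
* A single global seed fans out to per-stage seeds via a fixed CRC32 hash of
  stage names, so each stage is independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .sumstats_io import ReferencePanel

# non-palindromic allele pairs used for synthetic SNPs
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"), ("A", "C"), ("G", "T")]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class TraitSpec:
    """One secondary trait of the phenome-scan panel.

    ``mu_c`` / ``mu_d`` are the mean per-allele effects of concordant and
    discordant SNPs on the trait (s.d. units, or log-OR if binary); ``tau`` is
    the between-SNP effect s.d.  The trait separates the profiles iff
    ``mu_c != mu_d``.
    """

    name: str
    binary: bool = False
    mu_c: float = 0.0
    mu_d: float = 0.0
    tau: float = 0.0
    n: int = 100_000
    n_smallest_group: Optional[int] = None


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth parameters of a synthetic world."""

    seed: int = 0
    n_blocks: int = 40
    snps_per_block: int = 10
    within_block_ld: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_concordant: int = 12
    n_discordant: int = 5
    effect_size_bmi: float = 0.025
    effect_size_t2d: float = 0.05
    n_gwas_bmi: int = 500_000
    n_gwas_t2d: int = 150_000
    trait_panel: tuple[TraitSpec, ...] = ()
    cohort_n: int = 5_000
    # cohort generation
    phecode_log_or: float = 0.03
    n_phecodes: int = 12
    n_linked_phecodes: int = 3
    lab_effect: float = 0.05
    n_labs: int = 4
    mortality_hr: float = 1.05
    cvd_cause_code: str = "I21"
    # eQTL scenarios
    eqtl_region_m: int = 20
    eqtl_rho: float = 0.9
    n_eqtl: int = 30_000
    n_gwas_outcome: int = 300_000
    b_exp: float = 0.15
    b_gene: float = 0.12
    # expression atlas
    n_tissues: int = 20

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.within_block_ld < 1):
            raise ValueError("within_block_ld must be in [0, 1)")
        for name in ("n_blocks", "snps_per_block", "cohort_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_concordant + self.n_discordant > self.n_blocks:
            raise ValueError("more planted causal SNPs than LD blocks")
        for t in self.trait_panel:
            if t.tau < 0:
                raise ValueError("trait tau must be >= 0")


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def _tetrachoric_rho(p: float, target_r: float) -> float:
    """Latent normal correlation giving indicator correlation ``target_r`` when
    both indicators have frequency ``p``."""
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(p)

    def f(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [t, t], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        return (p11 - p * p) / (p * (1 - p)) - target_r

    return brentq(f, 1e-9, 1 - 1e-9, xtol=1e-8)


def _block_params(cfg: TruthConfig) -> list[tuple[float, float]]:
    """Per-block (allele frequency, latent AR(1) correlation); deterministic in cfg."""
    rng = np.random.default_rng(stage_seed(cfg.seed, "block_params"))
    lo, hi = cfg.maf_range
    params = []
    for _ in range(cfg.n_blocks):
        maf = float(rng.uniform(lo, hi))
        rho = _tetrachoric_rho(maf, cfg.within_block_ld)
        params.append((maf, rho))
    return params


def _simulate_dosages(
    params: Sequence[tuple[float, float]],
    snps_per_block: int,
    n_individuals: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Block-diagonal-LD dosages via two latent AR(1) haplotypes per individual."""
    blocks = []
    for maf, rho in params:
        t = stats.norm.ppf(maf)
        hap = np.empty((2 * n_individuals, snps_per_block))
        hap[:, 0] = rng.standard_normal(2 * n_individuals)
        scale = np.sqrt(1.0 - rho * rho)
        for k in range(1, snps_per_block):
            hap[:, k] = rho * hap[:, k - 1] + scale * rng.standard_normal(
                2 * n_individuals
            )
        alleles = (hap < t).astype(np.int8)
        blocks.append(alleles[:n_individuals] + alleles[n_individuals:])
    return np.concatenate(blocks, axis=1).astype(float)


def _panel_meta(cfg: TruthConfig) -> pd.DataFrame:
    rows = []
    for b in range(cfg.n_blocks):
        for k in range(cfg.snps_per_block):
            idx = b * cfg.snps_per_block + k
            ref, alt = _ALLELE_PAIRS[idx % len(_ALLELE_PAIRS)]
            rows.append(
                {
                    "snp_id": f"rs{idx + 1:05d}",
                    "chrom": str(b % 22 + 1),
                    # blocks are placed far apart so windows never span blocks
                    "pos": 1_000_000 * (b // 22 + 1) + 5_000 * k + 1,
                    "ref": ref,
                    "alt": alt,
                }
            )
    return pd.DataFrame(rows)


def simulate_reference_panel(
    cfg: TruthConfig, n_individuals: int = 2_000
) -> ReferencePanel:
    """Reference panel with block-diagonal LD and per-block MAF in ``maf_range``."""
    rng = np.random.default_rng(stage_seed(cfg.seed, "reference_panel"))
    dos = _simulate_dosages(_block_params(cfg), cfg.snps_per_block, n_individuals, rng)
    return ReferencePanel(meta=_panel_meta(cfg), dosages=dos)


# ---------------------------------------------------------------------------
# paired GWAS
# ---------------------------------------------------------------------------

def _causal_plan(cfg: TruthConfig) -> pd.DataFrame:
    """Which SNP in which block is causal, with true per-allele effects and labels.

    ``effect_size_bmi`` / ``effect_size_t2d`` are specified per genotype s.d.
    and converted to per-allele effects at each SNP's frequency; this mirrors
    instruments ascertained at genome-wide significance, whose detectability
    does not collapse at low MAF.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "causal_plan"))
    params = _block_params(cfg)
    blocks = rng.choice(cfg.n_blocks, cfg.n_concordant + cfg.n_discordant, replace=False)
    rows = []
    for i, b in enumerate(blocks):
        label = "concordant" if i < cfg.n_concordant else "discordant"
        snp_idx = int(b) * cfg.snps_per_block + cfg.snps_per_block // 2
        maf = params[int(b)][0]
        geno_sd = np.sqrt(2.0 * maf * (1.0 - maf))
        s_bmi = rng.choice([-1.0, 1.0])
        s_t2d = s_bmi if label == "concordant" else -s_bmi
        rows.append(
            {
                "snp_index": snp_idx,
                "block": int(b),
                "label": label,
                "beta_bmi_true": s_bmi * cfg.effect_size_bmi / geno_sd,
                "beta_t2d_true": s_t2d * cfg.effect_size_t2d / geno_sd,
            }
        )
    return pd.DataFrame(rows)


def _gwas_from_truth(
    panel: ReferencePanel,
    beta_true: np.ndarray,
    n: int,
    snps_per_block: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Marginal summary stats: LD-propagated effects plus correlated noise."""
    dos = panel.dosages
    m = dos.shape[1]
    eaf = dos.mean(axis=0) / 2.0
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)
    beta_hat = np.empty(m)
    for start in range(0, m, snps_per_block):
        sl = slice(start, start + snps_per_block)
        g = dos[:, sl]
        cov = np.cov(g, rowvar=False)
        var = np.diag(cov).copy()
        beta_marg = cov @ beta_true[sl] / var
        corr = cov / np.sqrt(np.outer(var, var))
        L = np.linalg.cholesky(corr + 1e-8 * np.eye(corr.shape[0]))
        beta_hat[sl] = beta_marg + se[sl] * (L @ rng.standard_normal(corr.shape[0]))
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = panel.meta.copy()
    out = out.rename(columns={"alt": "ea", "ref": "oa"})
    out["eaf"] = eaf
    out["beta"] = beta_hat
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["n"] = float(n)
    return out[["snp_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]]


def simulate_gwas_pair(
    cfg: TruthConfig, panel: ReferencePanel
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired BMI / T2D summary statistics plus the truth-label table.

    Planted concordant SNPs have same-signed BMI and T2D effects (after
    BMI-increasing alignment), discordant SNPs opposite; all other SNPs are
    null.  T2D effects are on the log-OR scale with ``n_gwas_t2d`` acting as
    the effective sample size.
    """
    plan = _causal_plan(cfg)
    m = panel.dosages.shape[1]
    b_bmi = np.zeros(m)
    b_t2d = np.zeros(m)
    b_bmi[plan["snp_index"].to_numpy()] = plan["beta_bmi_true"].to_numpy()
    b_t2d[plan["snp_index"].to_numpy()] = plan["beta_t2d_true"].to_numpy()
    rng_b = np.random.default_rng(stage_seed(cfg.seed, "gwas_bmi"))
    rng_t = np.random.default_rng(stage_seed(cfg.seed, "gwas_t2d"))
    bmi = _gwas_from_truth(panel, b_bmi, cfg.n_gwas_bmi, cfg.snps_per_block, rng_b)
    t2d = _gwas_from_truth(panel, b_t2d, cfg.n_gwas_t2d, cfg.snps_per_block, rng_t)
    truth = panel.meta[["snp_id"]].copy()
    truth["causal"] = False
    truth["label"] = pd.Series([None] * m, dtype=object)
    truth["beta_bmi_true"] = 0.0
    truth["beta_t2d_true"] = 0.0
    idx = plan["snp_index"].to_numpy()
    truth.loc[idx, "causal"] = True
    truth.loc[idx, "label"] = plan["label"].to_numpy()
    truth.loc[idx, "beta_bmi_true"] = plan["beta_bmi_true"].to_numpy()
    truth.loc[idx, "beta_t2d_true"] = plan["beta_t2d_true"].to_numpy()
    return bmi, t2d, truth


def simulate_replication_gwas(
    cfg: TruthConfig, panel: ReferencePanel, null: bool = False
) -> pd.DataFrame:
    """Independent T2D replication summary statistics (sign-check source)."""
    plan = _causal_plan(cfg)
    m = panel.dosages.shape[1]
    b_t2d = np.zeros(m)
    if not null:
        b_t2d[plan["snp_index"].to_numpy()] = plan["beta_t2d_true"].to_numpy()
    rng = np.random.default_rng(stage_seed(cfg.seed, "gwas_replication"))
    return _gwas_from_truth(panel, b_t2d, cfg.n_gwas_t2d, cfg.snps_per_block, rng)


# ---------------------------------------------------------------------------
# secondary trait panel
# ---------------------------------------------------------------------------

def simulate_trait_panel(
    cfg: TruthConfig, profile_snps: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-trait association tables for the profile SNPs, plus separation truth.

    ``profile_snps`` needs columns snp_id, label, bmi_allele, other_allele, eaf.
    Per-SNP true effects are drawn N(mu_C, tau^2) for concordant and
    N(mu_D, tau^2) for discordant SNPs; observed effects add noise at the SE
    implied by MAF and the trait's sample size.  Effects are already expressed
    on the BMI-increasing allele.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "trait_panel"))
    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    is_c = (profile_snps["label"] == "concordant").to_numpy()
    eaf = profile_snps["eaf"].to_numpy(dtype=float)
    for spec in cfg.trait_panel:
        mu = np.where(is_c, spec.mu_c, spec.mu_d)
        true_eff = mu + spec.tau * rng.standard_normal(len(profile_snps))
        se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * spec.n)
        beta = true_eff + se * rng.standard_normal(len(profile_snps))
        z = beta / se
        tbl = pd.DataFrame(
            {
                "snp_id": profile_snps["snp_id"].to_numpy(),
                "chrom": profile_snps.get("chrom", pd.Series(["1"] * len(profile_snps))).to_numpy(),
                "pos": profile_snps.get("pos", pd.Series(range(len(profile_snps)))).to_numpy(),
                "ea": profile_snps["bmi_allele"].to_numpy(),
                "oa": profile_snps["other_allele"].to_numpy(),
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "p": np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
                "n": float(spec.n),
            }
        )
        tables[spec.name] = tbl
        truth_rows.append(
            {
                "trait_id": spec.name,
                "binary": spec.binary,
                "separates": spec.mu_c != spec.mu_d,
                "mu_c": spec.mu_c,
                "mu_d": spec.mu_d,
                "tau": spec.tau,
            }
        )
    return tables, pd.DataFrame(truth_rows)


def default_trait_panel(
    n_null: int = 20,
    n_separating: int = 2,
    mu_sep: float = 0.01,
    tau: float = 0.003,
    n: int = 150_000,
) -> tuple[TraitSpec, ...]:
    """A realistic scan panel: a few separating traits among many nulls."""
    traits = [
        TraitSpec(f"null_trait_{i:02d}", mu_c=0.0, mu_d=0.0, tau=tau, n=n)
        for i in range(n_null)
    ]
    traits += [
        TraitSpec(f"sep_trait_{i:02d}", mu_c=mu_sep, mu_d=-mu_sep, tau=tau, n=n)
        for i in range(n_separating)
    ]
    return tuple(traits)


# ---------------------------------------------------------------------------
# individual-level cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Individual-level synthetic cohort.

    ``dosages``: individuals x SNPs (columns = snp_id); ``phenotypes``: bmi,
    t2d, obesity; ``covariates``: age, sex, PC1..PC10; ``phecode_events``: long
    (iid, phecode, day); ``phecode_exclusions``: (iid, phecode);
    ``labs``: long (iid, lab, value); ``survival``: (iid, time, event, cause).
    """

    dosages: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    phecode_events: pd.DataFrame
    phecode_exclusions: pd.DataFrame
    labs: pd.DataFrame
    survival: pd.DataFrame
    truth: dict


def simulate_cohort(
    cfg: TruthConfig, panel: ReferencePanel, profile_truth: pd.DataFrame
) -> CohortData:
    """Cohort with genotype-driven phenotypes, phecode events, labs and survival.

    BMI is the concordant+discordant genetic score plus noise; T2D liability
    takes positive contributions from concordant and negative from discordant
    alleles; linked phecodes follow logistic links to the concordant GRS;
    survival is exponential with log-hazard linear in the concordant GRS.
    """
    rng = np.random.default_rng(stage_seed(cfg.seed, "cohort"))
    n = cfg.cohort_n
    dos = _simulate_dosages(_block_params(cfg), cfg.snps_per_block, n, rng)
    snp_ids = panel.meta["snp_id"].tolist()
    dosages = pd.DataFrame(dos, columns=snp_ids)
    dosages.insert(0, "iid", [f"I{i:06d}" for i in range(n)])

    causal = profile_truth[profile_truth["causal"]]
    bmi_allele_sign = np.sign(causal["beta_bmi_true"].to_numpy())
    cols = [snp_ids.index(s) for s in causal["snp_id"]]
    # risk-allele dosage: count of the BMI-increasing allele
    g_aligned = np.where(bmi_allele_sign > 0, dos[:, cols], 2.0 - dos[:, cols])
    is_c = (causal["label"] == "concordant").to_numpy()
    grs_c = g_aligned[:, is_c].sum(axis=1)
    grs_d = g_aligned[:, ~is_c].sum(axis=1)

    bmi = dos[:, cols] @ causal["beta_bmi_true"].to_numpy()
    bmi = 27.0 + 4.0 * (bmi - bmi.mean()) / max(bmi.std(), 1e-12) + 2.0 * rng.standard_normal(n)
    liab = dos[:, cols] @ causal["beta_t2d_true"].to_numpy()
    p_t2d = 1.0 / (1.0 + np.exp(-(liab - liab.mean() + stats.norm.ppf(0.10) * 1.0)))
    t2d = (rng.uniform(size=n) < p_t2d).astype(int)
    phenotypes = pd.DataFrame(
        {
            "iid": dosages["iid"],
            "bmi": bmi,
            "t2d": t2d,
            "obesity": (bmi >= 30.0).astype(int),
        }
    )
    covariates = pd.DataFrame(
        {
            "iid": dosages["iid"],
            "age": rng.uniform(40, 70, n),
            "sex": rng.integers(0, 2, n),
            **{f"PC{k}": rng.standard_normal(n) for k in range(1, 11)},
        }
    )

    # phecodes: the first n_linked follow a logistic link to the concordant GRS
    ev_rows, ex_rows = [], []
    zc = grs_c - grs_c.mean()
    for j in range(cfg.n_phecodes):
        code = f"P{j + 1:03d}"
        eta = stats.norm.ppf(0.12)  # ~12% baseline prevalence on the logit scale
        lp = eta + (cfg.phecode_log_or * zc if j < cfg.n_linked_phecodes else 0.0)
        case = rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-lp))
        one_visit = (~case) & (rng.uniform(size=n) < 0.03)  # single-code encounters
        excluded = (~case) & (rng.uniform(size=n) < 0.02)
        for i in np.flatnonzero(case):
            days = rng.choice(3650, size=int(rng.integers(2, 5)), replace=False)
            ev_rows += [{"iid": f"I{i:06d}", "phecode": code, "day": int(d)} for d in days]
        for i in np.flatnonzero(one_visit):
            ev_rows.append({"iid": f"I{i:06d}", "phecode": code, "day": int(rng.integers(3650))})
        for i in np.flatnonzero(excluded):
            ex_rows.append({"iid": f"I{i:06d}", "phecode": code})
    phecode_events = pd.DataFrame(ev_rows, columns=["iid", "phecode", "day"])
    phecode_exclusions = pd.DataFrame(ex_rows, columns=["iid", "phecode"])

    # labs: repeated measurements; the first lab carries a planted per-allele effect
    lab_rows = []
    for j in range(cfg.n_labs):
        lab = f"lab_{j:02d}"
        mu = cfg.lab_effect * zc if j == 0 else np.zeros(n)
        n_meas = rng.integers(1, 4, n)
        for i in range(n):
            for _ in range(n_meas[i]):
                lab_rows.append(
                    {"iid": f"I{i:06d}", "lab": lab, "value": mu[i] + rng.standard_normal()}
                )
    labs = pd.DataFrame(lab_rows, columns=["iid", "lab", "value"])

    # survival: exponential with log-hazard linear in the concordant GRS
    log_hr = np.log(cfg.mortality_hr)
    rate = 0.03 * np.exp(log_hr * zc)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(1.0, 15.0, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    cause = np.where(
        event.astype(bool) & (rng.uniform(size=n) < 0.6), cfg.cvd_cause_code, "C34"
    )
    cause = np.where(event.astype(bool), cause, "")
    survival = pd.DataFrame(
        {"iid": dosages["iid"], "time": time, "event": event, "cause": cause}
    )

    truth = {
        "linked_phecodes": [f"P{j + 1:03d}" for j in range(cfg.n_linked_phecodes)],
        "phecode_log_or": cfg.phecode_log_or,
        "lab_effect": cfg.lab_effect,
        "linked_lab": "lab_00",
        "mortality_hr": cfg.mortality_hr,
        "grs_c_snps": causal.loc[is_c, "snp_id"].tolist(),
        "grs_d_snps": causal.loc[~is_c, "snp_id"].tolist(),
        # +1: the panel's alt allele is BMI-increasing; -1: the ref allele is
        "risk_allele_sign": dict(zip(causal["snp_id"], bmi_allele_sign)),
    }
    return CohortData(
        dosages=dosages,
        phenotypes=phenotypes,
        covariates=covariates,
        phecode_events=phecode_events,
        phecode_exclusions=phecode_exclusions,
        labs=labs,
        survival=survival,
        truth=truth,
    )


def risk_oriented_dosages(cohort: "CohortData") -> pd.DataFrame:
    """Cohort dosages re-expressed as counts of the BMI-increasing allele."""
    out = cohort.dosages.copy()
    for snp, sign in cohort.truth["risk_allele_sign"].items():
        if sign < 0:
            out[snp] = 2.0 - out[snp]
    return out


# ---------------------------------------------------------------------------
# cis-eQTL scenarios
# ---------------------------------------------------------------------------

def _region_stats(
    beta_true: np.ndarray, R: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed standardized effects in an LD region: R @ beta + MVN(0, R)*se."""
    se = np.full(len(beta_true), 1.0 / np.sqrt(n))
    L = np.linalg.cholesky(R + 1e-10 * np.eye(len(R)))
    beta_hat = R @ beta_true + se * (L @ rng.standard_normal(len(beta_true)))
    return beta_hat, se


def _region_frame(beta_hat, se, gene: Optional[str] = None, tissue: str = "blood") -> pd.DataFrame:
    m = len(beta_hat)
    z = beta_hat / se
    df = pd.DataFrame(
        {
            "snp_id": [f"rsE{k:04d}" for k in range(m)],
            "chrom": "1",
            "pos": 1_000_000 + 5_000 * np.arange(m),
            "ea": "A",
            "oa": "G",
            "eaf": 0.3,
            "beta": beta_hat,
            "se": se,
            "p": np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0),
            "n": float("nan"),
        }
    )
    if gene is not None:
        df.insert(0, "gene", gene)
        df.insert(1, "tissue", tissue)
        df.insert(2, "tss", 1_000_000 + 5_000 * (len(beta_hat) // 2))
    return df


def simulate_eqtl_scenario(
    kind: str,
    cfg: TruthConfig,
    seed: Optional[int] = None,
    gene: str = "GENE1",
    tissue: str = "blood",
    t2d_sign: float = -1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, np.ndarray, dict]:
    """One cis region under ``pleiotropy``, ``linkage`` or ``null``.

    pleiotropy: one causal SNP drives expression and (through it) both traits;
    linkage: distinct causal SNPs in LD (r^2 ~ 0.5) drive expression and traits;
    null: expression signal only.  Returns (eqtl, bmi, t2d, LD matrix, truth).
    Effects are standardized (per s.d.); ``t2d_sign`` sets the direction of the
    T2D effect relative to BMI (default discordant).
    """
    if kind not in {"pleiotropy", "linkage", "null"}:
        raise ValueError(f"unknown scenario kind {kind!r}")
    rng = np.random.default_rng(
        stage_seed(cfg.seed if seed is None else seed, f"eqtl_{kind}")
    )
    m = cfg.eqtl_region_m
    R = cfg.eqtl_rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    c_exp = m // 2
    b_e = np.zeros(m)
    b_e[c_exp] = cfg.b_exp
    b_bmi = np.zeros(m)
    b_t2d = np.zeros(m)
    if kind == "pleiotropy":
        b_bmi[c_exp] = cfg.b_gene * cfg.b_exp
        b_t2d[c_exp] = t2d_sign * cfg.b_gene * cfg.b_exp
    elif kind == "linkage":
        # offset chosen so r^2 between the two causal SNPs is closest to 0.5
        off = int(round(np.log(np.sqrt(0.5)) / np.log(cfg.eqtl_rho)))
        c_out = c_exp + max(off, 1)
        b_bmi[c_out] = cfg.b_gene
        b_t2d[c_out] = t2d_sign * cfg.b_gene
    eqtl_b, eqtl_se = _region_stats(b_e, R, cfg.n_eqtl, rng)
    bmi_b, bmi_se = _region_stats(b_bmi, R, cfg.n_gwas_outcome, rng)
    t2d_b, t2d_se = _region_stats(b_t2d, R, cfg.n_gwas_outcome, rng)
    truth = {
        "kind": kind,
        "causal_expression": c_exp,
        "b_exp": cfg.b_exp,
        "b_gene": cfg.b_gene if kind != "null" else 0.0,
        "t2d_sign": t2d_sign,
    }
    return (
        _region_frame(eqtl_b, eqtl_se, gene=gene, tissue=tissue),
        _region_frame(bmi_b, bmi_se),
        _region_frame(t2d_b, t2d_se),
        R,
        truth,
    )


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------

def simulate_expression_atlas(
    cfg: TruthConfig,
    genes: Sequence[str] = ("GENE1",),
    lead_snps: Optional[dict[str, str]] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Tissue x gene median-TPM table plus promoter/enhancer annotation.

    Each gene gets a designated true tissue with elevated expression and a
    promoter mark overlapping its lead SNP in a cell line mapped to that
    tissue.  Returns (tpm, annotation, cellline_map, truth).
    """
    rng = np.random.default_rng(
        stage_seed(cfg.seed if seed is None else seed, "expression_atlas")
    )
    tissues = [f"tissue_{k:02d}" for k in range(cfg.n_tissues)]
    lead_snps = lead_snps or {g: f"lead_{g}" for g in genes}
    tpm_rows, ann_rows, truth = [], [], {}
    for g in genes:
        true_t = tissues[int(rng.integers(cfg.n_tissues))]
        truth[g] = true_t
        base = rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n_tissues)
        base[tissues.index(true_t)] *= 5.0 * cfg.n_tissues
        for t, v in zip(tissues, base):
            tpm_rows.append({"tissue": t, "gene": g, "median_tpm": v})
        ann_rows.append(
            {"snp_id": lead_snps[g], "cell_line": f"CL_{true_t}", "mark": "promoter"}
        )
        # occasional stray enhancer marks in other tissues
        for t in tissues:
            if t != true_t and rng.uniform() < 0.05:
                ann_rows.append(
                    {"snp_id": lead_snps[g], "cell_line": f"CL_{t}", "mark": "enhancer"}
                )
    cellline_map = pd.DataFrame(
        {"cell_line": [f"CL_{t}" for t in tissues], "tissue": tissues}
    )
    return (
        pd.DataFrame(tpm_rows),
        pd.DataFrame(ann_rows, columns=["snp_id", "cell_line", "mark"]),
        cellline_map,
        truth,
    )
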