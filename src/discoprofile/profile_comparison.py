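"""Profile comparison: pooled effects, δ-test, FDR, Boruta and outlier detection.

Stage one pools the per-SNP effects of each profile per trait with a
Paule–Mandel random-effects meta-analysis, then tests the between-profile
difference δ = |β_C − β_D| with SE_δ² = SE_C² + SE_D² (two-sided z-test) and
corrects with Benjamini–Hochberg FDR.  Traits where a pooled estimate and δ
are both FDR-significant go to stage two, a Boruta relevance screen over the
SNP × trait z-matrix.  Single-linkage clustering over SNP rows flags the
variant most distal from the rest of its profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .sumstats_io import DegenerateInputError, EmptyInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects pooled estimate for one profile on one trait."""

    trait_id: str
    profile: str  # "C" or "D"
    beta_hat: float
    se: float
    tau2: float
    k: int


@dataclass(frozen=True)
class DeltaResult:
    """Between-profile difference test for one trait."""

    trait_id: str
    delta: float
    se_delta: float
    z: float
    p: float
    q: Optional[float] = None
    significant_any_profile: Optional[bool] = None


def pm_meta(
    betas: Sequence[float],
    ses: Sequence[float],
    trait_id: str = "",
    profile: str = "",
    tol: float = 1e-10,
) -> PooledEffect:
    """Paule–Mandel random-effects pooling.

    τ̂² solves the generalized Q equation Σ w_i(τ²)(β_i − β̂(τ²))² = k − 1 with
    w_i = 1/(se_i² + τ²); if Q at τ² = 0 is at most k − 1 then τ̂² = 0.  Q is
    monotone decreasing in τ², so the root is found by bisection to relative
    tolerance ``tol``.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise EmptyInputError("pm_meta needs at least one estimate")
    if np.any(s <= 0):
        raise DegenerateInputError("all standard errors must be positive")
    k = b.size

    def q_gen(tau2: float) -> float:
        w = 1.0 / (s * s + tau2)
        mu = np.sum(w * b) / np.sum(w)
        return float(np.sum(w * (b - mu) ** 2))

    if k == 1 or q_gen(0.0) <= k - 1:
        tau2 = 0.0
    else:
        hi = max(np.var(b), np.max(s) ** 2, 1e-12)
        while q_gen(hi) > k - 1:
            hi *= 2.0
        lo = 0.0
        while hi - lo > tol * max(hi, 1e-300):
            mid = 0.5 * (lo + hi)
            if q_gen(mid) > k - 1:
                lo = mid
            else:
                hi = mid
        tau2 = 0.5 * (lo + hi)
    w = 1.0 / (s * s + tau2)
    beta_hat = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return PooledEffect(trait_id, profile, beta_hat, se, tau2, k)


def delta_test(pooled_c: PooledEffect, pooled_d: PooledEffect) -> DeltaResult:
    """Two-sided z-test of δ = |β̂_C − β̂_D| with SE_δ² = SE_C² + SE_D²."""
    delta = abs(pooled_c.beta_hat - pooled_d.beta_hat)
    se_delta = float(np.sqrt(pooled_c.se**2 + pooled_d.se**2))
    z = delta / se_delta
    p = float(2.0 * stats.norm.sf(z))
    return DeltaResult(pooled_c.trait_id, delta, se_delta, z, min(p, 1.0))


def bh_fdr(p: Sequence[float], q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (q-values, significance flags at ``q_level``)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelevanceResult:
    trait_id: str
    decision: str  # confirmed | tentative | rejected
    mean_importance: float
    shadow_max_mean: float
    hits: int
    n_iter: int


def boruta_select(
    z_matrix: pd.DataFrame,
    labels: Sequence[str],
    n_iter: int = 1000,
    seed: int = 0,
    n_trees: int = 500,
    alpha: float = 0.01,
    n_shadow_copies: int = 5,
) -> list[RelevanceResult]:
    """Boruta relevance screen of traits for separating the two profiles.

    Each iteration appends column-wise permuted shadow copies of every trait
    (``n_shadow_copies`` independent permutations per trait; the reference
    algorithm likewise pads the shadow set when it is small, and a larger
    shadow pool stabilises the max-shadow reference at the few-dozen-SNP row
    counts typical here), fits a random-forest classifier of the profile
    labels, and scores a "hit" for each real trait whose importance exceeds
    the maximum shadow importance.
    After each iteration hit counts are referred to a two-sided binomial test
    against 0.5, Bonferroni-corrected over all traits (the originating
    algorithm's multiple-comparison adjustment at its default 0.01
    confidence); significantly-above features are confirmed,
    significantly-below rejected, the rest stay tentative.  Missing cells are
    imputed to 0 with a logged count.
    """
    X = z_matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("boruta_select: imputed %d missing cells to 0", n_missing)
        X = np.nan_to_num(X, nan=0.0)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateInputError("boruta_select needs two label classes")
    if min((y == c).sum() for c in classes) < 2:
        raise DegenerateInputError("each class needs at least 2 SNPs")
    n_feat = X.shape[1]
    rng = np.random.default_rng(seed)
    hits = np.zeros(n_feat, dtype=int)
    active = np.ones(n_feat, dtype=bool)  # undecided features
    decision = np.array(["tentative"] * n_feat, dtype=object)
    imp_sum = np.zeros(n_feat)
    shadow_sum = 0.0
    done_iter = np.full(n_feat, 0, dtype=int)
    it = 0
    while it < n_iter and active.any():
        it += 1
        shadow_blocks = []
        for _ in range(max(n_shadow_copies, 1)):
            block = X.copy()
            for j in range(n_feat):
                block[:, j] = rng.permutation(block[:, j])
            shadow_blocks.append(block)
        Xa = np.hstack([X] + shadow_blocks)
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xa, y)
        imp = rf.feature_importances_
        real, shadow = imp[:n_feat], imp[n_feat:]
        shadow_max = shadow.max()
        hits[active] += (real[active] > shadow_max).astype(int)
        imp_sum += real
        shadow_sum += shadow_max
        # binomial decisions, Bonferroni-adjusted over all traits
        for j in np.flatnonzero(active):
            p_hi = stats.binom.sf(hits[j] - 1, it, 0.5)
            p_lo = stats.binom.cdf(hits[j], it, 0.5)
            if p_hi < alpha / n_feat:
                decision[j] = "confirmed"
                active[j] = False
                done_iter[j] = it
            elif p_lo < alpha / n_feat:
                decision[j] = "rejected"
                active[j] = False
                done_iter[j] = it
    done_iter[active] = it
    total_it = max(it, 1)
    return [
        RelevanceResult(
            trait_id=str(z_matrix.columns[j]),
            decision=str(decision[j]),
            mean_importance=float(imp_sum[j] / total_it),
            shadow_max_mean=float(shadow_sum / total_it),
            hits=int(hits[j]),
            n_iter=int(done_iter[j]),
        )
        for j in range(n_feat)
    ]


# ---------------------------------------------------------------------------
# single-linkage outliers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterTree:
    """Single-linkage merge sequence over SNP rows of the z-matrix."""

    merges: pd.DataFrame  # columns: left, right, height, size
    leaves: tuple[str, ...]
    last_joined_leaf: str
    last_joined_height: float


def single_linkage_outliers(
    z_rows: pd.DataFrame, metric: str = "euclidean"
) -> ClusterTree:
    """Agglomerative single linkage over SNP rows; reports the full merge
    sequence and the leaf whose first merge happens at the greatest height
    (the most distal SNP of the set).  ``metric`` is ``euclidean`` or
    ``correlation``."""
    X = z_rows.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise DegenerateInputError("need at least two rows to cluster")
    Z = linkage(pdist(X, metric=metric), method="single")
    leaves = tuple(str(i) for i in z_rows.index)
    n = X.shape[0]
    join_height = np.full(n, np.nan)
    rows = []
    for a, b, h, size in Z:
        a, b = int(a), int(b)
        for side in (a, b):
            if side < n:
                join_height[side] = h
        rows.append({"left": a, "right": b, "height": float(h), "size": int(size)})
    last = int(np.nanargmax(join_height))
    return ClusterTree(
        merges=pd.DataFrame(rows),
        leaves=leaves,
        last_joined_leaf=leaves[last],
        last_joined_height=float(join_height[last]),
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compare_profiles(
    scan: pd.DataFrame,
    q_level: float = 0.05,
    domains: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Stage-one comparison over a long-format scan table.

    ``scan`` needs columns trait_id, snp_id, label, beta_std, se_std.  Pools
    each profile per trait (Paule–Mandel over the SNPs with data), runs the
    δ-test, and corrects two FDR families — per-profile p-values and δ
    p-values — within each phenotypic domain (``domains``: trait_id -> domain;
    a single domain by default).  Returns (pooled table, delta table,
    stage-two trait list).
    """
    if scan.empty:
        empty_p = pd.DataFrame(
            columns=["trait_id", "profile", "beta_hat", "se", "tau2", "k", "p", "q"]
        )
        empty_d = pd.DataFrame(
            columns=["trait_id", "delta", "se_delta", "z", "p", "q",
                     "significant_any_profile", "selected"]
        )
        return empty_p, empty_d, []
    domain_of = {}
    if domains is not None:
        domain_of = dict(zip(domains["trait_id"], domains["domain"]))
    pooled_rows, delta_rows = [], []
    for trait_id, sub in scan.groupby("trait_id", sort=True):
        pools = {}
        for prof_name, prof_label in (("C", "concordant"), ("D", "discordant")):
            ss = sub[sub["label"] == prof_label].dropna(subset=["beta_std", "se_std"])
            if ss.empty:
                continue
            pe = pm_meta(ss["beta_std"], ss["se_std"], trait_id=trait_id, profile=prof_name)
            pools[prof_name] = pe
            p_prof = float(2 * stats.norm.sf(abs(pe.beta_hat / pe.se)))
            pooled_rows.append(
                {
                    "trait_id": trait_id,
                    "domain": domain_of.get(trait_id, "all"),
                    "profile": prof_name,
                    "beta_hat": pe.beta_hat,
                    "se": pe.se,
                    "tau2": pe.tau2,
                    "k": pe.k,
                    "p": min(p_prof, 1.0),
                }
            )
        if "C" in pools and "D" in pools:
            dr = delta_test(pools["C"], pools["D"])
            delta_rows.append(
                {
                    "trait_id": trait_id,
                    "domain": domain_of.get(trait_id, "all"),
                    "delta": dr.delta,
                    "se_delta": dr.se_delta,
                    "z": dr.z,
                    "p": dr.p,
                }
            )
    pooled = pd.DataFrame(pooled_rows)
    delta = pd.DataFrame(delta_rows)
    if pooled.empty or delta.empty:
        return pooled, delta, []
    pooled["q"] = np.nan
    for _, idx in pooled.groupby("domain").groups.items():
        q, _ = bh_fdr(pooled.loc[idx, "p"], q_level)
        pooled.loc[idx, "q"] = q
    delta["q"] = np.nan
    for _, idx in delta.groupby("domain").groups.items():
        q, _ = bh_fdr(delta.loc[idx, "p"], q_level)
        delta.loc[idx, "q"] = q
    any_prof = (
        pooled.assign(sig=pooled["q"] <= q_level)
        .groupby("trait_id")["sig"]
        .any()
    )
    delta["significant_any_profile"] = delta["trait_id"].map(any_prof).fillna(False)
    delta["selected"] = delta["significant_any_profile"] & (delta["q"] <= q_level)
    selected = sorted(delta.loc[delta["selected"], "trait_id"].tolist())
    return pooled, delta, selected
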