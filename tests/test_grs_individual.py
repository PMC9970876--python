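"""Unweighted GRS construction and the individual-level association batteries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from discoprofile import grs_individual, synthetic_data
from discoprofile.grs_individual import (
    AssocEstimate,
    compare_estimates,
    compute_grs,
    cox_mortality,
    estimate_from_ci,
    extreme_decile_analysis,
    inverse_normal,
    labwas,
    phewas,
    top_decile_mask,
)
from discoprofile.profile_comparison import PooledEffect, delta_test
from discoprofile.sumstats_io import ConfigurationError, DegenerateInputError
from discoprofile.synthetic_data import TruthConfig


@pytest.fixture(scope="module")
def cohort():
    cfg = TruthConfig(seed=41, cohort_n=4_000)
    panel = synthetic_data.simulate_reference_panel(cfg, 800)
    _, _, truth = synthetic_data.simulate_gwas_pair(cfg, panel)
    c = synthetic_data.simulate_cohort(cfg, panel, truth)
    # express dosages as counts of the BMI-increasing allele, as the GRS requires
    c.dosages = synthetic_data.risk_oriented_dosages(c)
    return cfg, c


class TestComputeGrs:
    def dosages(self):
        return pd.DataFrame(
            {"iid": ["i1", "i2"], "s1": [0.0, 1.0], "s2": [1.0, 2.0], "s3": [2.0, 0.0]}
        )

    def test_exact_sum(self):
        grs = compute_grs(self.dosages(), ["s1", "s2", "s3"])
        assert grs["i1"] == 3.0 and grs["i2"] == 3.0

    def test_all_zero(self):
        d = self.dosages().assign(s1=0.0, s2=0.0, s3=0.0)
        assert (compute_grs(d, ["s1", "s2", "s3"]) == 0).all()

    def test_additivity_over_disjoint_sets(self):
        d = self.dosages()
        total = compute_grs(d, ["s1", "s2", "s3"])
        parts = compute_grs(d, ["s1"]) + compute_grs(d, ["s2", "s3"])
        assert (total == parts).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_grs(self.dosages(), [])

    def test_missing_dosage_mean_imputed(self):
        d = self.dosages()
        d.loc[0, "s1"] = np.nan
        grs = compute_grs(d, ["s1", "s2"])
        assert grs["i1"] == pytest.approx(1.0 + 1.0)  # s1 imputed to its mean


class TestPhewas:
    def test_small_phecodes_skipped_and_linked_recovered(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        ests = phewas(
            grs, c.phecode_events, c.phecode_exclusions, c.covariates, min_cases=200
        )
        by_code = {e.outcome: e for e in ests}
        assert all(
            e.status == "skipped" for e in ests if (e.n_cases or 0) < 200
        )
        linked = by_code[c.truth["linked_phecodes"][0]]
        assert linked.status == "ok" and linked.se > 0

    def test_min_cases_rule(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        ests = phewas(
            grs, c.phecode_events, c.phecode_exclusions, c.covariates,
            min_cases=10**9,
        )
        assert all(e.status == "skipped" for e in ests)

    def test_constant_grs_flagged(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"]) * 0.0
        ests = phewas(
            grs, c.phecode_events, c.phecode_exclusions, c.covariates, min_cases=200
        )
        assert all(e.status in {"degenerate", "skipped"} for e in ests)


class TestLabwas:
    def test_single_measurement_median_identity(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        one = c.labs.groupby(["iid", "lab"], as_index=False).first()
        ests = labwas(grs, one, c.covariates, inverse_normalize=False)
        assert len(ests) == cfg.n_labs

    def test_inverse_normal_moments(self):
        rng = np.random.default_rng(0)
        y = inverse_normal(rng.exponential(size=5_000))
        assert np.mean(y) == pytest.approx(0.0, abs=0.05)
        assert np.var(y) == pytest.approx(1.0, abs=0.05)

    def test_planted_lab_effect_within_ci(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        ests = {e.outcome: e for e in labwas(grs, c.labs, c.covariates, inverse_normalize=False)}
        e = ests[c.truth["linked_lab"]]
        # median-of-repeats attenuates noise, not the planted per-allele slope
        assert abs(e.effect - cfg.lab_effect) < 1.96 * e.se * 1.5


class TestCox:
    def test_time_scale_invariance(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        a = cox_mortality(grs, c.survival, c.covariates, [cfg.cvd_cause_code])
        doubled = c.survival.assign(time=c.survival["time"] * 2)
        b = cox_mortality(grs, doubled, c.covariates, [cfg.cvd_cause_code])
        assert a.effect == pytest.approx(b.effect, rel=1e-6)

    def test_non_matching_causes_censored(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        a = cox_mortality(grs, c.survival, c.covariates, [cfg.cvd_cause_code])
        assert a.n_cases < int(c.survival["event"].sum())

    def test_zero_events_raises(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        with pytest.raises(DegenerateInputError):
            cox_mortality(grs, c.survival, c.covariates, ["NOPE"])


class TestCompareEstimates:
    def test_equal_estimates_p_one(self):
        e = AssocEstimate("x", "C", 0.1, 0.02, 0.5, 100)
        assert compare_estimates(e, e).p == pytest.approx(1.0)

    def test_matches_delta_test_bitwise(self):
        ec = AssocEstimate("x", "C", 0.21, 0.02, 0.5, 100)
        ed = AssocEstimate("x", "D", -0.07, 0.04, 0.5, 100)
        d1 = compare_estimates(ec, ed)
        d2 = delta_test(
            PooledEffect("x", "C", 0.21, 0.02, 0.0, 1),
            PooledEffect("x", "D", -0.07, 0.04, 0.0, 1),
        )
        assert (d1.delta, d1.se_delta, d1.z, d1.p) == (d2.delta, d2.se_delta, d2.z, d2.p)

    def test_hypertension_worked_example(self):
        """Essential hypertension: OR_C 1.014 (1.009, 1.019) vs OR_D 0.99
        (0.98, 0.99) must separate at p < 1.2e-6 on the log-odds scale."""
        ec = estimate_from_ci("HT", "C", 1.014, 1.009, 1.019, ratio_scale=True)
        ed = estimate_from_ci("HT", "D", 0.99, 0.98, 0.99, ratio_scale=True)
        assert compare_estimates(ec, ed).p <= 1.2e-6

    def test_ckd_worked_example(self):
        """Chronic kidney disease: OR_C 1.02 (1.01, 1.02) vs OR_D 0.98
        (0.97, 0.99) must separate at p < 2.9e-6."""
        ec = estimate_from_ci("CKD", "C", 1.02, 1.01, 1.02, ratio_scale=True)
        ed = estimate_from_ci("CKD", "D", 0.98, 0.97, 0.99, ratio_scale=True)
        assert compare_estimates(ec, ed).p <= 2.9e-6


class TestExtremeDeciles:
    def test_union_fraction_analytic(self):
        rng = np.random.default_rng(3)
        n = 100_000
        iid = pd.Index([f"i{k}" for k in range(n)])
        gc = pd.Series(rng.standard_normal(n), index=iid)
        gd = pd.Series(rng.standard_normal(n), index=iid)
        ob = pd.Series(True, index=iid)
        traits = pd.DataFrame({"y": rng.standard_normal(n)}, index=iid)
        _, uf = extreme_decile_analysis(gc, gd, ob, traits)
        assert uf == pytest.approx(1 - 0.9**2, abs=0.005)

    def test_null_trait_p_uniform_vs_permutation(self):
        rng = np.random.default_rng(4)
        n = 200
        iid = pd.Index([f"i{k}" for k in range(n)])
        gc = pd.Series(rng.standard_normal(n), index=iid)
        gd = pd.Series(rng.standard_normal(n), index=iid)
        ob = pd.Series(True, index=iid)
        y = rng.standard_normal(n)
        stats_df, _ = extreme_decile_analysis(gc, gd, ob, pd.DataFrame({"y": y}, index=iid))
        kw_obs = stats_df.loc[stats_df["group"] == "extreme_C", "kw_stat"].iloc[0]
        mask = top_decile_mask(gc).to_numpy()
        perm_stats = []
        for s in range(500):
            pm = np.random.default_rng(s).permutation(mask)
            perm_stats.append(stats.kruskal(y[pm], y[~pm]).statistic)
        p_perm = np.mean(np.asarray(perm_stats) >= kw_obs)
        p_asym = stats_df.loc[stats_df["group"] == "extreme_C", "p"].iloc[0]
        assert abs(p_perm - p_asym) < 0.1

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        n = 5_000
        iid = pd.Index([f"i{k}" for k in range(n)])
        gc = pd.Series(rng.standard_normal(n), index=iid)
        gd = pd.Series(rng.standard_normal(n), index=iid)
        ob = pd.Series(True, index=iid)
        y = rng.standard_normal(n)
        y[top_decile_mask(gc).to_numpy()] += 1.0
        stats_df, _ = extreme_decile_analysis(gc, gd, ob, pd.DataFrame({"y": y}, index=iid))
        p = stats_df.loc[stats_df["group"] == "extreme_C", "p"].iloc[0]
        assert p < 1e-6

    def test_sex_stratification_rows_present(self):
        rng = np.random.default_rng(7)
        n = 400
        iid = pd.Index([f"i{k}" for k in range(n)])
        gc = pd.Series(rng.standard_normal(n), index=iid)
        gd = pd.Series(rng.standard_normal(n), index=iid)
        ob = pd.Series(True, index=iid)
        sex = pd.Series(rng.integers(0, 2, n), index=iid)
        traits = pd.DataFrame({"y": rng.standard_normal(n)}, index=iid)
        stats_df, _ = extreme_decile_analysis(gc, gd, ob, traits, sex=sex)
        assert {"all", "sex_0", "sex_1"} <= set(stats_df["stratum"])


class TestCovariateInvariance:
    def test_affine_covariate_rescaling_leaves_grs_effect(self, cohort):
        cfg, c = cohort
        grs = compute_grs(c.dosages, c.truth["grs_c_snps"])
        base = labwas(grs, c.labs, c.covariates, inverse_normalize=False)[0]
        cov2 = c.covariates.copy()
        cov2["age"] = cov2["age"] * 10 + 3
        rescaled = labwas(grs, c.labs, cov2, inverse_normalize=False)[0]
        assert base.effect == pytest.approx(rescaled.effect, rel=1e-8)
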