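"""Instrument filtering, clumping and concordant/discordant labelling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from discoprofile import instrument_selection, sumstats_io
from discoprofile.instrument_selection import (
    assign_profiles,
    clump,
    cross_reference,
    replicate_signs,
)

from conftest import make_sumstats
from test_sumstats_io import tiny_panel


def paired_tables():
    """6 SNPs: 3 pass all filters; the rest fail exactly one rule each."""
    base = dict(se=0.01, n=5e5)
    bmi = make_sumstats(
        [
            {"snp_id": "rs_ok1", "pos": 100, "ea": "A", "oa": "G", "beta": 0.05, "p": 1e-9, **base},
            {"snp_id": "rs_ok2", "pos": 200, "ea": "C", "oa": "T", "beta": -0.06, "p": 1e-10, **base},
            {"snp_id": "rs_ok3", "pos": 300, "ea": "A", "oa": "C", "beta": 0.04, "p": 1e-12, **base},
            {"snp_id": "rs_weak_t2d", "pos": 400, "ea": "A", "oa": "G", "beta": 0.05, "p": 1e-9, **base},
            {"snp_id": "rs_rare", "pos": 500, "ea": "A", "oa": "G", "beta": 0.05, "p": 1e-9, "eaf": 0.005, **base},
            {"snp_id": "rs_palin", "pos": 600, "ea": "A", "oa": "T", "beta": 0.05, "p": 1e-9, "eaf": 0.45, **base},
        ]
    )
    t2d = make_sumstats(
        [
            {"snp_id": "rs_ok1", "pos": 100, "ea": "A", "oa": "G", "beta": 0.08, "p": 1e-9, **base},
            {"snp_id": "rs_ok2", "pos": 200, "ea": "T", "oa": "C", "beta": 0.07, "p": 1e-11, **base},
            {"snp_id": "rs_ok3", "pos": 300, "ea": "A", "oa": "C", "beta": -0.05, "p": 1e-9, **base},
            {"snp_id": "rs_weak_t2d", "pos": 400, "ea": "A", "oa": "G", "beta": 0.02, "p": 1e-4, **base},
            {"snp_id": "rs_rare", "pos": 500, "ea": "A", "oa": "G", "beta": 0.08, "p": 1e-9, "eaf": 0.005, **base},
            {"snp_id": "rs_palin", "pos": 600, "ea": "A", "oa": "T", "beta": 0.08, "p": 1e-9, "eaf": 0.45, **base},
        ]
    )
    return bmi, t2d


class TestCrossReference:
    def test_fixture_enumeration(self):
        bmi, t2d = paired_tables()
        out = cross_reference(bmi, t2d)
        assert sorted(out["snp_id"]) == ["rs_ok1", "rs_ok2", "rs_ok3"]
        drops = out.attrs["drop_counts"]
        assert drops["not_dual_significant"] == 1
        assert drops["rare"] == 1
        assert drops["palindromic_ambiguous"] == 1

    def test_t2d_realigned_to_bmi_allele(self):
        bmi, t2d = paired_tables()
        out = cross_reference(bmi, t2d).set_index("snp_id")
        # rs_ok2 was reported on the opposite allele in the T2D table
        assert out.loc["rs_ok2", "beta_t2d"] == pytest.approx(-0.07)

    def test_empty_intersection_warns_not_raises(self):
        bmi, t2d = paired_tables()
        out = cross_reference(bmi, t2d.assign(snp_id=lambda d: d.snp_id + "_x"))
        assert out.empty


def brute_force_clump(cand: pd.DataFrame, panel, r2_max, window_bp, rank):
    """Independent oracle: explicit greedy selection using a full r2 matrix."""
    ids = list(cand["snp_id"])
    pos = dict(zip(cand["snp_id"], cand["pos"]))
    chrom = dict(zip(cand["snp_id"], cand["chrom"]))
    order = sorted(ids, key=lambda s: (-rank[s], s))
    kept = []
    for s in order:
        ok = True
        for k in kept:
            if chrom[k] == chrom[s] and abs(pos[k] - pos[s]) <= window_bp:
                if sumstats_io.ld_r2(panel, k, s) >= r2_max:
                    ok = False
                    break
        if ok:
            kept.append(s)
    return kept


class TestClump:
    def correlated_fixture(self, n_snps=10, seed=0):
        rng = np.random.default_rng(seed)
        cols, rows = {}, []
        for i in range(n_snps):
            if i % 2 == 0:
                x = rng.binomial(2, 0.4, 600).astype(float)
            else:  # noisy copy of the previous SNP -> high-LD pair
                x = cols[f"s{i - 1}"].copy()
                flip = rng.uniform(size=600) < 0.05
                x[flip] = rng.binomial(2, 0.4, int(flip.sum()))
            cols[f"s{i}"] = x
            rows.append(
                {"snp_id": f"s{i}", "pos": 1000 + 50_000 * i, "ea": "A", "oa": "G",
                 "beta": 0.05, "se": 0.01, "p": 10.0 ** -(9 + i)}
            )
        panel = tiny_panel(cols, positions={f"s{i}": 1000 + 50_000 * i for i in range(n_snps)})
        cand = make_sumstats(rows).rename(
            columns={"beta": "beta_bmi", "se": "se_bmi", "p": "p_bmi"}
        )
        cand["beta_t2d"] = 0.05
        cand["se_t2d"] = 0.01
        cand["p_t2d"] = cand["p_bmi"]
        return cand, panel

    def test_matches_brute_force_oracle(self):
        cand, panel = self.correlated_fixture()
        out = clump(cand, panel, r2_max=0.1, window_bp=500_000)
        rank = {
            r.snp_id: -np.log10(r.p_bmi) - np.log10(r.p_t2d) for r in cand.itertuples()
        }
        expected = brute_force_clump(cand, panel, 0.1, 500_000, rank)
        assert list(out["snp_id"]) == expected

    def test_high_ld_pair_within_window_pruned(self):
        x = np.array([0.0, 1, 2, 1, 0, 2, 1, 1] * 20)
        panel = tiny_panel({"a": x, "b": x.copy()}, positions={"a": 1000, "b": 101_000})
        cand = pd.DataFrame(
            {
                "snp_id": ["a", "b"], "chrom": "1", "pos": [1000, 101_000],
                "ea": "A", "oa": "G", "eaf": 0.3,
                "beta_bmi": [0.05, 0.04], "se_bmi": 0.01,
                "p_bmi": [1e-12, 1e-9], "beta_t2d": 0.05, "se_t2d": 0.01,
                "p_t2d": [1e-12, 1e-9],
            }
        )
        out = clump(cand, panel)
        assert list(out["snp_id"]) == ["a"]

    def test_high_ld_pair_beyond_window_both_kept(self):
        x = np.array([0.0, 1, 2, 1, 0, 2, 1, 1] * 20)
        panel = tiny_panel({"a": x, "b": x.copy()}, positions={"a": 1000, "b": 601_000})
        cand = pd.DataFrame(
            {
                "snp_id": ["a", "b"], "chrom": "1", "pos": [1000, 601_000],
                "ea": "A", "oa": "G", "eaf": 0.3,
                "beta_bmi": [0.05, 0.04], "se_bmi": 0.01,
                "p_bmi": [1e-12, 1e-9], "beta_t2d": 0.05, "se_t2d": 0.01,
                "p_t2d": [1e-12, 1e-9],
            }
        )
        out = clump(cand, panel)
        assert sorted(out["snp_id"]) == ["a", "b"]

    def test_output_pairwise_independent(self, profile, panel):
        for a, b in itertools.combinations(profile.itertuples(), 2):
            if a.chrom == b.chrom and abs(a.pos - b.pos) <= 500_000:
                assert sumstats_io.ld_r2(panel, a.snp_id, b.snp_id) < 0.01


class TestAssignProfiles:
    def base_row(self, **kw):
        row = dict(
            snp_id="rs1", chrom="1", pos=100, ea="A", oa="G", eaf=0.3,
            beta_bmi=0.01, se_bmi=0.002, p_bmi=1e-9,
            beta_t2d=0.03, se_t2d=0.01, p_t2d=1e-9,
        )
        row.update(kw)
        return pd.DataFrame([row])

    def test_negative_bmi_effect_flipped_and_labelled(self):
        out = assign_profiles(self.base_row(beta_bmi=-0.02, beta_t2d=0.05))
        r = out.iloc[0]
        assert r["beta_bmi"] == pytest.approx(0.02)
        assert r["beta_t2d"] == pytest.approx(-0.05)
        assert r["bmi_allele"] == "G" and r["other_allele"] == "A"
        assert r["eaf"] == pytest.approx(0.7)
        assert r["label"] == "discordant"

    def test_positive_both_is_concordant(self):
        out = assign_profiles(self.base_row(beta_bmi=0.01, beta_t2d=0.03))
        assert out.iloc[0]["label"] == "concordant"

    def test_zero_t2d_effect_excluded(self):
        out = assign_profiles(self.base_row(beta_t2d=0.0))
        assert out.empty

    def test_invariants_hold(self, profile):
        assert (profile["beta_bmi"] > 0).all()
        conc = profile["label"] == "concordant"
        assert (profile.loc[conc, "beta_t2d"] > 0).all()
        assert (profile.loc[~conc, "beta_t2d"] < 0).all()
        assert (profile["p_bmi"] < 5e-8).all() and (profile["p_t2d"] < 5e-8).all()

    def test_labels_recover_planted_truth(self, profile, gwas_pair):
        _, _, truth = gwas_pair
        m = profile.merge(truth[truth["causal"]], on="snp_id")
        assert len(m) > 0
        assert (m["label_x"] == m["label_y"]).mean() >= 0.95


class TestReplicateSigns:
    def test_same_and_opposite_allele_reports(self, profile):
        rep_rows = []
        for i, r in enumerate(profile.itertuples()):
            if i % 2 == 0:  # report on the BMI allele
                rep_rows.append(
                    {"snp_id": r.snp_id, "ea": r.bmi_allele, "oa": r.other_allele,
                     "beta": r.beta_t2d * 0.9, "se": 0.01, "p": 0.5,
                     "pos": r.pos, "eaf": r.eaf, "n": 1e5}
                )
            else:  # opposite allele, same underlying direction
                rep_rows.append(
                    {"snp_id": r.snp_id, "ea": r.other_allele, "oa": r.bmi_allele,
                     "beta": -r.beta_t2d * 0.9, "se": 0.01, "p": 0.5,
                     "pos": r.pos, "eaf": 1 - r.eaf, "n": 1e5}
                )
        rep = make_sumstats(rep_rows)
        out = replicate_signs(profile, rep)
        assert out["replicated_sign"].all()

    def test_missing_snps_left_unset(self, profile):
        rep = make_sumstats(
            [{"snp_id": "rs_other", "pos": 1, "ea": "A", "oa": "G",
              "beta": 0.1, "se": 0.01, "p": 0.5}]
        )
        out = replicate_signs(profile, rep)
        assert out["replicated_sign"].isna().all()

    def test_null_replication_agreement_near_half(self):
        rng = np.random.default_rng(4)
        n = 1_000
        prof = pd.DataFrame(
            {
                "snp_id": [f"r{i}" for i in range(n)],
                "chrom": "1", "pos": np.arange(n),
                "bmi_allele": "A", "other_allele": "G", "eaf": 0.3,
                "beta_bmi": 0.05, "se_bmi": 0.01, "p_bmi": 1e-9,
                "beta_t2d": rng.choice([-0.05, 0.05], n), "se_t2d": 0.01,
                "p_t2d": 1e-9, "label": "concordant",
            }
        )
        rep = make_sumstats(
            [
                {"snp_id": f"r{i}", "pos": i, "ea": "A", "oa": "G",
                 "beta": rng.standard_normal() * 0.01, "se": 0.01, "p": 0.5}
                for i in range(n)
            ]
        )
        agree = replicate_signs(prof, rep)["replicated_sign"].mean()
        assert agree == pytest.approx(0.5, abs=0.05)  # ~3 sigma of Binomial(1000, .5)


def test_pipeline_determinism(world_cfg, panel, gwas_pair, profile):
    bmi, t2d, _ = gwas_pair
    again = instrument_selection.select_instruments(bmi, t2d, panel)
    pd.testing.assert_frame_equal(profile, again)
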