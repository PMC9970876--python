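"""End-to-end orchestration over a synthetic world, with a run manifest.

``run_all`` executes simulate -> select-instruments -> scan -> compare ->
grs-assoc -> smr-screen -> tissue-score -> decompose on generated data,
writes every stage's tables as TSV under the output directory and records a
JSON manifest (config snapshot, seeds, output digests).  Stages lacking
inputs are skipped; all randomness flows from the explicit ``seed`` entry —
its absence is a configuration error, not a silent default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import (
    directional_decomposition,
    grs_individual,
    instrument_selection,
    phenome_scan,
    profile_comparison,
    smr_heidi,
    synthetic_data,
    tissue_scoring,
)
from .sumstats_io import ConfigurationError, write_sumstats
from .synthetic_data import TraitSpec, TruthConfig

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "select_instruments",
    "scan",
    "compare",
    "grs_assoc",
    "smr_screen",
    "tissue_score",
    "decompose",
)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def truth_config_from_dict(d: dict) -> TruthConfig:
    d = dict(d)
    panel = d.pop("trait_panel", None)
    if panel is None:
        traits = synthetic_data.default_trait_panel()
    else:
        traits = tuple(TraitSpec(**t) for t in panel)
    valid = {f.name for f in dataclasses.fields(TruthConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ConfigurationError(f"unknown world config keys: {sorted(unknown)}")
    return TruthConfig(trait_panel=traits, **d)


def run_all(config: dict, out_dir: Optional[str] = None) -> dict:
    """Run the requested stages and return the manifest (also written as JSON)."""
    if "seed" not in config:
        raise ConfigurationError("config must set an explicit 'seed'")
    seed = int(config["seed"])
    stages = tuple(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir or config.get("out_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)
    world = truth_config_from_dict({"seed": seed, **config.get("world", {})})
    panel_n = int(config.get("panel_n", 2_000))
    manifest: dict = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "stages": list(stages),
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"][name] = _digest(path)

    # --- simulate ----------------------------------------------------------
    panel = synthetic_data.simulate_reference_panel(world, n_individuals=panel_n)
    bmi_ss, t2d_ss, truth = synthetic_data.simulate_gwas_pair(world, panel)
    replication = synthetic_data.simulate_replication_gwas(world, panel)
    if "simulate" in stages:
        write_sumstats(bmi_ss, out / "bmi_sumstats.tsv")
        manifest["outputs"]["bmi_sumstats.tsv"] = _digest(out / "bmi_sumstats.tsv")
        write_sumstats(t2d_ss, out / "t2d_sumstats.tsv")
        manifest["outputs"]["t2d_sumstats.tsv"] = _digest(out / "t2d_sumstats.tsv")
        save(truth, "truth_labels.tsv")

    # --- instruments -------------------------------------------------------
    profile = instrument_selection.select_instruments(
        bmi_ss, t2d_ss, panel, replication_ss=replication
    )
    if "select_instruments" in stages:
        save(profile, "profile_snps.tsv")
    if profile.empty:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    # --- phenome scan ------------------------------------------------------
    scan = pd.DataFrame()
    if "scan" in stages or "compare" in stages:
        tables, trait_truth = synthetic_data.simulate_trait_panel(world, profile)
        scan = phenome_scan.harvest(profile, tables, panel=panel)
        save(scan, "scan_long.tsv")
        save(trait_truth, "trait_truth.tsv")

    # --- profile comparison ------------------------------------------------
    if "compare" in stages and not scan.empty:
        pooled, delta, selected = profile_comparison.compare_profiles(scan)
        save(pooled, "pooled_effects.tsv")
        save(delta, "delta_results.tsv")
        zmat = phenome_scan.z_matrix(scan)
        if selected:
            labels = profile.set_index("snp_id").loc[zmat.index, "label"]
            boruta = profile_comparison.boruta_select(
                zmat[selected],
                labels,
                n_iter=int(config.get("boruta_iters", 100)),
                n_trees=int(config.get("boruta_trees", 100)),
                seed=synthetic_data.stage_seed(seed, "boruta"),
            )
            save(pd.DataFrame([r.__dict__ for r in boruta]), "boruta_decisions.tsv")
        for prof_label in ("concordant", "discordant"):
            rows = zmat.loc[
                [s for s in zmat.index
                 if profile.set_index("snp_id").loc[s, "label"] == prof_label]
            ].fillna(0.0)
            if len(rows) >= 2:
                tree = profile_comparison.single_linkage_outliers(rows)
                save(tree.merges.assign(profile=prof_label), f"cluster_{prof_label}.tsv")

    # --- individual-level GRS ----------------------------------------------
    if "grs_assoc" in stages:
        cohort = synthetic_data.simulate_cohort(world, panel, truth)
        oriented = grs_individual.orient_dosages(cohort.dosages, profile, panel.meta)
        sets = {
            "C": profile.loc[profile["label"] == "concordant", "snp_id"].tolist(),
            "D": profile.loc[profile["label"] == "discordant", "snp_id"].tolist(),
        }
        est_rows = []
        for prof_name, snp_set in sets.items():
            if not snp_set:
                continue
            grs = grs_individual.compute_grs(oriented, snp_set)
            for est in grs_individual.phewas(
                grs, cohort.phecode_events, cohort.phecode_exclusions,
                cohort.covariates, min_cases=int(config.get("min_cases", 200)),
                profile=prof_name,
            ):
                est_rows.append(est.__dict__)
            for est in grs_individual.labwas(
                grs, cohort.labs, cohort.covariates, profile=prof_name
            ):
                est_rows.append(est.__dict__)
            try:
                est_rows.append(
                    grs_individual.cox_mortality(
                        grs, cohort.survival, cohort.covariates,
                        cause_codes=[world.cvd_cause_code], profile=prof_name,
                    ).__dict__
                )
            except Exception as exc:  # zero events at tiny cohort sizes
                logger.warning("cox stage skipped: %s", exc)
        save(pd.DataFrame(est_rows), "grs_associations.tsv")

    # --- SMR / HEIDI screen ------------------------------------------------
    lead_by_gene: dict[str, str] = {}
    screen = pd.DataFrame()
    if "smr_screen" in stages or "tissue_score" in stages:
        regions = []
        n_genes = int(config.get("n_screen_genes", 8))
        n_discordant_genes = int(config.get("n_discordant_genes", 3))
        for g in range(n_genes):
            kind = "pleiotropy" if g < n_discordant_genes else "null"
            eqtl, rb, rt, R, _ = synthetic_data.simulate_eqtl_scenario(
                kind, world, seed=synthetic_data.stage_seed(seed, f"gene{g}"),
                gene=f"GENE{g + 1}",
            )
            regions.append(
                {"gene": f"GENE{g + 1}", "tissue": "blood",
                 "eqtl": eqtl, "bmi": rb, "t2d": rt, "ld": R}
            )
        screen, discordant_genes = smr_heidi.discordant_gene_screen(regions)
        if "smr_screen" in stages and not screen.empty:
            save(screen, "smr_results.tsv")
            manifest["discordant_genes"] = discordant_genes
            lead_by_gene = dict(
                screen.drop_duplicates("gene")[["gene", "lead_snp"]].to_numpy()
            )

    # --- tissue scoring -----------------------------------------------------
    if "tissue_score" in stages and lead_by_gene:
        genes = sorted(lead_by_gene)
        tpm, ann, cmap, _ = synthetic_data.simulate_expression_atlas(
            world, genes=genes, lead_snps=lead_by_gene
        )
        frames = [
            tissue_scoring.score_gene(tpm, ann, cmap, g, lead_by_gene[g])
            for g in genes
        ]
        save(pd.concat(frames, ignore_index=True), "tissue_scores.tsv")

    # --- directional decomposition -----------------------------------------
    if "decompose" in stages:
        tables, trait_truth = synthetic_data.simulate_trait_panel(world, profile)
        rows = []
        for trait_id in trait_truth.loc[trait_truth["separates"], "trait_id"]:
            tbl = tables[trait_id].copy()
            tbl["n"] = tbl["n"].fillna(100_000)
            groups = directional_decomposition.decompose_trait(
                tbl, bmi_ss, t2d_ss, panel, trait=trait_id
            )
            for grp in groups:
                d = grp.__dict__.copy()
                d["snp_ids"] = ",".join(d["snp_ids"])
                rows.append(d)
        save(pd.DataFrame(rows), "directional_grs.tsv")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["outputs"]["manifest.json"] = "self"
    return manifest
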