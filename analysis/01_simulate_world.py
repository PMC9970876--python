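"""Generate the synthetic study world: reference panel, paired GWAS, truth tables.

Writes the inputs every later step consumes under results/world/ and reports
how many planted concordant/discordant SNPs reached dual genome-wide
significance.
"""

from pathlib import Path

from discoprofile import synthetic_data
from discoprofile.sumstats_io import write_sumstats
from discoprofile.synthetic_data import TruthConfig

SEED = 2026
OUT = Path("results/world")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = TruthConfig(seed=SEED, trait_panel=synthetic_data.default_trait_panel())
    panel = synthetic_data.simulate_reference_panel(cfg, n_individuals=2_000)
    bmi, t2d, truth = synthetic_data.simulate_gwas_pair(cfg, panel)
    replication = synthetic_data.simulate_replication_gwas(cfg, panel)

    panel.to_dosage_tsv(OUT / "panel.tsv")
    write_sumstats(bmi, OUT / "bmi_sumstats.tsv")
    write_sumstats(t2d, OUT / "t2d_sumstats.tsv")
    write_sumstats(replication, OUT / "replication_sumstats.tsv")
    truth.to_csv(OUT / "truth_labels.tsv", sep="\t", index=False)

    causal = truth[truth["causal"]]
    dual = (bmi["p"] < 5e-8) & (t2d["p"] < 5e-8)
    print(f"world seed {SEED}: {len(causal)} planted causal SNPs "
          f"({(causal['label'] == 'concordant').sum()} concordant, "
          f"{(causal['label'] == 'discordant').sum()} discordant)")
    print(f"{int(dual.sum())} SNPs reach p < 5e-8 in both GWAS "
          f"(planted SNPs among them: "
          f"{int(dual[truth['causal']].sum())}/{len(causal)})")


if __name__ == "__main__":
    main()
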