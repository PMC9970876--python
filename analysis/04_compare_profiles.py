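"""Profile comparison: Paule–Mandel pooling, δ-tests, FDR, Boruta, outliers.

Stage one pools concordant and discordant effects per trait and tests their
difference; stage two runs the Boruta relevance screen on the selected
traits; single-linkage clustering flags the most distal SNP of each profile.
"""

from pathlib import Path

import pandas as pd

from discoprofile import phenome_scan, profile_comparison

OUT = Path("results")
SEED = 2026


def main() -> None:
    scan = pd.read_csv(OUT / "scan_long.tsv", sep="\t")
    profile = pd.read_csv(OUT / "profile_snps.tsv", sep="\t")

    pooled, delta, selected = profile_comparison.compare_profiles(scan)
    pooled.to_csv(OUT / "pooled_effects.tsv", sep="\t", index=False)
    delta.to_csv(OUT / "delta_results.tsv", sep="\t", index=False)
    print(f"stage one: {len(delta)} traits tested, "
          f"{int(delta['selected'].sum())} pass both FDR families: {selected}")

    truth = pd.read_csv(OUT / "trait_truth.tsv", sep="\t")
    sep_traits = set(truth.loc[truth["separates"], "trait_id"])
    print(f"planted separating traits recovered: "
          f"{len(sep_traits & set(selected))}/{len(sep_traits)}")

    zmat = phenome_scan.z_matrix(scan)
    labels = profile.set_index("snp_id").loc[zmat.index, "label"]
    if selected:
        res = profile_comparison.boruta_select(
            zmat[selected].copy(), labels, n_iter=100, n_trees=200, seed=SEED
        )
        decisions = pd.DataFrame([r.__dict__ for r in res])
        decisions.to_csv(OUT / "boruta_decisions.tsv", sep="\t", index=False)
        confirmed = decisions.loc[decisions["decision"] == "confirmed", "trait_id"]
        print(f"stage two (Boruta): confirmed {list(confirmed)}")

    for prof in ("concordant", "discordant"):
        rows = zmat.loc[labels[labels == prof].index].fillna(0.0)
        if len(rows) < 2:
            continue
        tree = profile_comparison.single_linkage_outliers(rows)
        tree.merges.to_csv(OUT / f"cluster_{prof}.tsv", sep="\t", index=False)
        print(f"{prof} profile: most distal SNP = {tree.last_joined_leaf} "
              f"(joined at height {tree.last_joined_height:.2f})")


if __name__ == "__main__":
    main()
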