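#!/usr/bin/env python
"""Summarize precursor/flank polymorphism and the conserved-vs-novel
comparison.

Reads results/02_pipeline/ and writes summary tables to
results/05_polymorphism/.
"""

from pathlib import Path

import pandas as pd

RUN = Path("results/02_pipeline")
OUT = Path("results/05_polymorphism")
REGIONS = ["up_1000", "up_500", "up_1", "hairpin", "dn_1", "dn_500", "dn_1000"]


def main() -> None:
    poly = pd.read_csv(RUN / "polymorphism.tsv", sep="\t")
    rates = pd.read_csv(RUN / "rates_by_window.tsv", sep="\t")
    comparison = pd.read_csv(RUN / "group_comparison.tsv", sep="\t")
    summary_table = pd.read_csv(RUN / "summary_table.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)

    mean_rates = (
        rates.groupby("group")[REGIONS].mean().reset_index()
    )
    mean_rates.to_csv(OUT / "mean_rates_by_region.tsv", sep="\t", index=False)

    contexts = pd.DataFrame(
        [
            {
                "n_hairpin_snps": int(poly["n_snps_hairpin"].sum()),
                "n_bulge": int(poly["n_bulge_snps"].sum()),
                "n_near_bulge_1_2nt": int(poly["n_near_bulge_snps"].sum()),
                "n_stem": int(poly["n_stem_snps"].sum()),
                "n_loop": int(poly["n_loop_snps"].sum()),
                "n_star_disrupting": int(poly["n_star_disrupting"].sum()),
            }
        ]
    )
    contexts.to_csv(OUT / "structural_contexts.tsv", sep="\t", index=False)

    summary_table.to_csv(OUT / "summary_table.tsv", sep="\t", index=False)
    comparison.to_csv(OUT / "group_comparison.tsv", sep="\t", index=False)

    print("--- mean SNP rates per 100 bp by region ---")
    print(mean_rates.to_string(index=False))
    print("--- structural contexts of hairpin SNPs ---")
    print(contexts.to_string(index=False))
    print("--- conserved vs novel permutation comparison ---")
    print(comparison.to_string(index=False))


if __name__ == "__main__":
    main()
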