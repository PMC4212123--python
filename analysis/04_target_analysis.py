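#!/usr/bin/env python
"""Summarize predicted target sites and their degradome support.

Reads results/02_pipeline/targets.tsv and writes summary tables to
results/04_targets/.
"""

from pathlib import Path

import pandas as pd

RUN = Path("results/02_pipeline")
OUT = Path("results/04_targets")


def main() -> None:
    targets = pd.read_csv(RUN / "targets.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)

    overview = pd.DataFrame(
        [
            {
                "n_sites": len(targets),
                "n_mirnas_with_sites": targets["mirna"].nunique(),
                "n_transcripts_targeted": targets["transcript_id"].nunique(),
                "n_validated": int(targets["validated"].sum()),
                "frac_validated": float(targets["validated"].mean()),
                "median_alignment_score": float(
                    targets["alignment_score"].median()
                ),
                "median_penalty": float(targets["penalty_score"].median()),
                "median_duplex_energy": float(targets["duplex_energy"].median()),
            }
        ]
    )
    overview.to_csv(OUT / "target_overview.tsv", sep="\t", index=False)

    categories = (
        targets["degradome_category"].value_counts().sort_index()
        .rename_axis("degradome_category").rename("n_sites").reset_index()
    )
    categories.to_csv(OUT / "degradome_categories.tsv", sep="\t", index=False)

    per_mirna = (
        targets.groupby("mirna")
        .agg(
            n_sites=("transcript_id", "size"),
            n_validated=("validated", "sum"),
            best_score=("alignment_score", "max"),
            min_penalty=("penalty_score", "min"),
        )
        .reset_index()
    )
    per_mirna.to_csv(OUT / "sites_per_mirna.tsv", sep="\t", index=False)

    print(overview.to_string(index=False))
    print(categories.to_string(index=False))


if __name__ == "__main__":
    main()
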