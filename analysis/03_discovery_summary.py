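#!/usr/bin/env python
"""Summarize the discovery run: status counts, class distribution,
mature properties, genomic contexts, families and conservation.

Reads results/02_pipeline/ (run analysis/02_run_pipeline.py first) and
writes summary tables to results/03_discovery/.
"""

from pathlib import Path

import pandas as pd

RUN = Path("results/02_pipeline")
OUT = Path("results/03_discovery")


def main() -> None:
    matures = pd.read_csv(RUN / "matures.tsv", sep="\t")
    precursors = pd.read_csv(RUN / "precursors.tsv", sep="\t")
    conservation = pd.read_csv(RUN / "conservation.tsv", sep="\t")
    families = pd.read_csv(RUN / "families.tsv", sep="\t")
    OUT.mkdir(parents=True, exist_ok=True)

    status = (
        matures["status"].value_counts().rename_axis("status")
        .rename("n_matures").reset_index()
    )
    status.to_csv(OUT / "status_counts.tsv", sep="\t", index=False)

    classes = (
        precursors["global_class"].value_counts().sort_index()
        .rename_axis("global_class").rename("n_precursors").reset_index()
    )
    classes.to_csv(OUT / "class_distribution.tsv", sep="\t", index=False)

    accepted = matures[matures["status"] != "rejected"]
    mature_props = pd.DataFrame(
        [
            {
                "n_accepted_matures": len(accepted),
                "frac_length_21": float((accepted["length"] == 21).mean()),
                "frac_5prime_u": float(
                    accepted["mature"].str.startswith("T").mean()
                ),
                "median_total_count": float(accepted["total_count"].median()),
            }
        ]
    )
    mature_props.to_csv(OUT / "mature_properties.tsv", sep="\t", index=False)

    retained = precursors[precursors["status"] != "rejected"]
    contexts = (
        retained["context"].value_counts().rename_axis("context")
        .rename("n_precursors").reset_index()
    )
    contexts.to_csv(OUT / "genomic_contexts.tsv", sep="\t", index=False)

    precursor_props = pd.DataFrame(
        [
            {
                "n_retained_precursors": len(retained),
                "median_length": float(retained["length"].median()),
                "frac_100_300nt": float(
                    retained["length"].between(100, 300).mean()
                ),
                "median_mfe": float(retained["mfe"].median()),
                "median_mfe_density": float(retained["mfe_density"].median()),
            }
        ]
    )
    precursor_props.to_csv(OUT / "precursor_properties.tsv", sep="\t", index=False)

    fam_sizes = (
        families["n_members"].value_counts().sort_index()
        .rename_axis("family_size").rename("n_families").reset_index()
    )
    fam_sizes.to_csv(OUT / "family_sizes.tsv", sep="\t", index=False)

    cons = (
        conservation["category"].value_counts().rename_axis("category")
        .rename("n_matures").reset_index()
    )
    cons.to_csv(OUT / "conservation_categories.tsv", sep="\t", index=False)

    for name, df in (
        ("status counts", status),
        ("class distribution", classes),
        ("mature properties", mature_props),
        ("genomic contexts", contexts),
        ("precursor properties", precursor_props),
        ("conservation", cons),
    ):
        print(f"--- {name} ---")
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
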