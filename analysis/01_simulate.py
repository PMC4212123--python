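#!/usr/bin/env python
"""Generate the synthetic study dataset and tabulate its ground truth.

Writes small truth/composition tables under results/01_dataset/ and the
bulky dataset flat files (genome, libraries, annotation, variants) under
scratch/01_dataset/, which is scratch space and not tracked.
"""

from pathlib import Path

import pandas as pd

from mirnaome.synthetic import SimulationConfig, simulate_all, write_dataset

SEED = 0
OUT = Path("results/01_dataset")
SCRATCH = Path("scratch/01_dataset")


def main() -> None:
    config = SimulationConfig(seed=SEED)
    data = simulate_all(config)
    write_dataset(data, SCRATCH)

    rows = []
    for locus in data.truth.loci:
        rows.append(
            {
                "locus_id": locus.locus_id,
                "kind": locus.kind,
                "chrom": locus.precursor_locus.seq_id,
                "start": locus.precursor_locus.start,
                "end": locus.precursor_locus.end,
                "strand": locus.precursor_locus.strand,
                "expected_class": locus.expected_class,
                "context": locus.context,
                "known_status": locus.known_status,
                "mature_length": len(locus.mature_seq) if locus.mature_seq else 0,
                "precursor_length": (
                    len(locus.precursor_seq) if locus.precursor_seq else 0
                ),
                "n_copies": len(locus.copy_loci) or 1,
            }
        )
    truth = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    truth.to_csv(OUT / "truth_loci.tsv", sep="\t", index=False)

    composition = (
        truth.groupby(["kind", "expected_class"], dropna=False)
        .size()
        .rename("n_loci")
        .reset_index()
    )
    composition.to_csv(OUT / "truth_composition.tsv", sep="\t", index=False)

    lib_sizes = pd.DataFrame(
        [{"library": k, "n_raw_reads": len(v)} for k, v in data.libraries.items()]
    )
    lib_sizes.to_csv(OUT / "library_sizes.tsv", sep="\t", index=False)

    print(composition.to_string(index=False))
    print(lib_sizes.to_string(index=False))
    print(f"truth tables in {OUT}; dataset flat files in {SCRATCH}")


if __name__ == "__main__":
    main()
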