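#!/usr/bin/env python
"""Run the complete discovery pipeline on the default synthetic dataset.

Writes all stage tables, the funnel and the manifest to
results/02_pipeline/.
"""

from pathlib import Path

from mirnaome.pipeline import PipelineConfig, run_all

SEED = 0
OUT = Path("results/02_pipeline")


def main() -> None:
    result = run_all(PipelineConfig(seed=SEED), OUT)
    print(result["funnel"].to_string(index=False))
    print(f"outputs in {OUT.resolve()}")


if __name__ == "__main__":
    main()
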