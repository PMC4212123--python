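"""Shared fixtures: one small synthetic dataset and one small end-to-end
run, both session-scoped so the folding cost is paid once."""

from __future__ import annotations

import dataclasses

import pytest

from mirnaome.pipeline import PipelineConfig, run_all
from mirnaome.synthetic import SimulationConfig, simulate_all

SMALL_SIM_KWARGS = dict(
    seed=3,
    genome_length=1_200_000,
    n_chromosomes=1,
    n_true_mirna_loci=6,
    class_mix={1: 3, 2: 1, 3: 1, 4: 1},
    n_sirna_repeat_loci=2,
    n_rrna_trna_loci=2,
    background_reads_per_length={
        18: 20, 19: 20, 20: 20, 21: 300, 22: 20, 23: 20, 24: 120, 25: 20
    },
    n_transcripts=8,
    n_planted_target_sites=4,
    n_decoy_target_sites=2,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(**SMALL_SIM_KWARGS)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def small_pipeline_config(small_config) -> PipelineConfig:
    return PipelineConfig(seed=3, simulation=small_config, n_permutations=500)


@pytest.fixture(scope="session")
def small_run(small_pipeline_config, small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_run")
    return run_all(small_pipeline_config, out, data=small_dataset)


@pytest.fixture(scope="session")
def small_run_rerun(small_pipeline_config, tmp_path_factory):
    """Completely independent rerun (fresh simulation) for determinism."""
    out = tmp_path_factory.mktemp("small_rerun")
    return run_all(dataclasses.replace(small_pipeline_config), out)
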