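"""Shared fixtures: synthetic datasets are generated once per session."""

from __future__ import annotations

import pytest

from profileclust.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from profileclust.synthetic_data import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def dataset17(tmp_path_factory):
    """Full-size reference dataset at the default study conditions, seed 17."""
    outdir = tmp_path_factory.mktemp("dataset17")
    return simulate_dataset(outdir, seed=17)


@pytest.fixture(scope="session")
def pipeline17(dataset17, tmp_path_factory):
    """End-to-end pipeline result on the reference dataset."""
    outdir = tmp_path_factory.mktemp("run17")
    inputs = PipelineInputs.from_simulation(dataset17.outdir)
    return run_pipeline(inputs, PipelineConfig(seed=17), outdir)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Compact dataset for cheap structural tests (single 3.5-Mb chromosome)."""
    outdir = tmp_path_factory.mktemp("small_ds")
    params = SimulationParams(n_genes=120, n_chroms=1, chrom_length=3_500_000,
                              n_repressed_targets=4)
    return simulate_dataset(outdir, seed=7, params=params)
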