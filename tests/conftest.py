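"""Shared fixtures: a reference synthetic study and the pipeline run on it.

Both are session-scoped — generation plus a full (GSEA-free) pipeline run
takes a few seconds and nearly every module's end-to-end test consumes them.
"""

import pandas as pd
import pytest

from mirnet import PipelineConfig, SimulationConfig, generate_study, run_pipeline
from mirnet.containers import SampleDesign

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def bundle(sim_config, tmp_path_factory):
    return generate_study(sim_config, tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    config = PipelineConfig(seed=FIXTURE_SEED, run_gsea=False)
    return run_pipeline(bundle.outdir, tmp_path_factory.mktemp("results"), config)


@pytest.fixture()
def tiny_design() -> SampleDesign:
    """2 conditions x 1 stage x 2 replicates."""
    return SampleDesign(
        pd.DataFrame(
            {
                "sample_id": ["sham_1", "sham_2", "mi_1", "mi_2"],
                "condition": ["sham", "sham", "MI", "MI"],
                "stage": ["1D"] * 4,
                "replicate": [1, 2, 1, 2],
            }
        )
    )
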