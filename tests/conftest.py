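import warnings

import pytest

from spongebiomass.io import PipelineConfig
from spongebiomass.pipeline import run_pipeline
from spongebiomass.synthetic_data import SimulationConfig, simulate_bundle

BUNDLE_SEED = 1


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Synthetic input bundle at the default study design (seed fixed)."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = simulate_bundle(SimulationConfig(seed=BUNDLE_SEED), outdir)
    return paths


@pytest.fixture(scope="session")
def pipeline_results(bundle, tmp_path_factory):
    """Full pipeline run on the session bundle."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        inputs={
            k: str(v)
            for k, v in bundle.items()
            if k not in ("ground_truth", "true_measurements")
        },
        outdir=str(outdir),
        seed=BUNDLE_SEED,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run_pipeline(config)
    results["_outdir"] = outdir
    results["_config"] = config
    return results
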