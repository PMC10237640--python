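import numpy as np
import pytest

from nearshore_overlap.config import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A 3-beach, 8-day campaign small enough for per-frame simulation."""
    return GeneratorConfig(seed=42, n_beaches=3, n_days=8, aggregation_beaches=(0, 1))


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run shared by the pipeline/report tests."""
    from nearshore_overlap.pipeline import run_pipeline, write_report

    outdir = tmp_path_factory.mktemp("demo_run")
    cfg = GeneratorConfig(seed=7, n_beaches=3, n_days=10, aggregation_beaches=(0, 1))
    manifest = run_pipeline(cfg, outdir)
    write_report(outdir)
    return cfg, outdir, manifest
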