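import pytest

from vdrdomains.master_classifier import Thresholds
from vdrdomains.pipeline import run_pipeline
from vdrdomains.synthetic_data import SynthConfig, generate


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def bundle(default_config):
    """One full default bundle shared by read-only tests."""
    return generate(default_config, seed=7)


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    return run_pipeline(
        bundle.peaks,
        bundle.interactions,
        bundle.chrom_sizes,
        bundle.genome,
        bundle.signals,
        bundle.genes,
        thresholds=Thresholds(),
    )
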