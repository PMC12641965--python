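import numpy as np
import pytest

from flowintern import SynthConfig, generate_gallery
from flowintern.gating import run_pipeline


@pytest.fixture(scope="session")
def default_cfg():
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def gallery_500(default_cfg):
    """The default study gallery: 500 events, internalized_fraction 0.7."""
    records, truth = generate_gallery(default_cfg, 500)
    return records, truth


@pytest.fixture(scope="session")
def pipeline_500(gallery_500):
    records, truth = gallery_500
    features, tree, summary = run_pipeline(records, sample_name="demo_1")
    return features, tree, summary, truth


@pytest.fixture(scope="session")
def clean_cfg():
    """No dead cells, doublets or defocus: isolates geometry and signal placement."""
    return SynthConfig(seed=7, dead_fraction=0.0, doublet_fraction=0.0, defocus_fraction=0.0)


@pytest.fixture(scope="session")
def clean_gallery(clean_cfg):
    return generate_gallery(clean_cfg, 40)
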