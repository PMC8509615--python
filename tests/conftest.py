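import numpy as np
import pytest

from snapqsar import fixtures as fx


@pytest.fixture(scope="session")
def toy_assay():
    return fx.generate_toy_assay(n=24, prevalence=0.33, seed=7)


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """8-molecule, single-viewpoint image dataset for fast harness tests."""
    assay = fx.generate_toy_assay(n=8, prevalence=0.5, seed=3)
    out = tmp_path_factory.mktemp("tinyimg")
    return fx.generate_image_fixture(assay, theta=(360, 360, 360), seed=3,
                                     out_dir=out, image_size=64)


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """18 molecules x 8 viewpoints; enough signal for short training runs."""
    assay = fx.generate_toy_assay(n=18, prevalence=0.45, seed=5)
    out = tmp_path_factory.mktemp("smallimg")
    return fx.generate_image_fixture(assay, theta=(195, 195, 195), seed=5,
                                     out_dir=out, image_size=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
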