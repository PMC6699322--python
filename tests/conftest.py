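import numpy as np
import pytest

from ivimhsi.phantom import (
    DEFAULT_BVALUES,
    Ellipse,
    Lesion,
    PhantomSpec,
    generate_phantom,
    reference_phantom_spec,
)
from ivimhsi.pipeline import PipelineConfig, run_pipeline

#: sigma giving SNR 50 relative to the normal-parenchyma baseline (S0 = 100)
SNR50_SIGMA = 2.0


@pytest.fixture
def bvals():
    return np.asarray(DEFAULT_BVALUES, dtype=float)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_phantom_spec():
    """A fast 24x24x1 phantom with one tumor and one cyst lesion."""
    lesions = (
        Lesion(Ellipse((9.0, 9.0), (3.0, 3.0)), tissue="tumor_central", name="core"),
        Lesion(Ellipse((15.0, 15.0), (2.5, 2.5)), tissue="cyst", name="cyst"),
    )
    return PhantomSpec(
        shape=(24, 24, 1),
        body=Ellipse((12.0, 12.0), (10.0, 10.0)),
        lesions=lesions,
    )


@pytest.fixture(scope="session")
def ref_noiseless():
    return generate_phantom(reference_phantom_spec())


@pytest.fixture(scope="session")
def ref_snr50():
    return generate_phantom(reference_phantom_spec(noise_sigma=SNR50_SIGMA, seed=11))


@pytest.fixture(scope="session")
def pipeline_noiseless(ref_noiseless):
    cube, _, _ = ref_noiseless
    return run_pipeline(PipelineConfig(seed=0), cube)


@pytest.fixture(scope="session")
def pipeline_snr50(ref_snr50):
    cube, _, _ = ref_snr50
    return run_pipeline(PipelineConfig(seed=11), cube)
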