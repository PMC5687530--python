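import numpy as np
import pytest

from qctlung import (
    DeformationSpec,
    PhantomConfig,
    generate_phantom_pair,
)


@pytest.fixture(scope="session")
def still_phantom():
    """Noise-free, deformation-free phantom with 15% emphysema / 25% trapping
    prescribed in every lobe — the exact-recovery reference case."""
    cfg = PhantomConfig(
        target_emph_pct=15.0,
        target_fsad_pct=25.0,
        deformation_spec=DeformationSpec(),
        noise_sd_hu=0.0,
        seed=11,
    )
    return generate_phantom_pair(cfg)


@pytest.fixture(scope="session")
def deforming_phantom():
    """Noise-free phantom with the default affine expansion + sinusoid field."""
    cfg = PhantomConfig(noise_sd_hu=0.0, seed=12)
    return generate_phantom_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
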