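import numpy as np
import pytest

from vesselvote import (
    PhantomSpec,
    PipelineConfig,
    ScalarVolume,
    build_scale_space,
    generate,
    make_scale_ladder,
)
from vesselvote.phantom import ModalityParams, straight_tube


def gaussian_tube_volume(shape=(32, 32, 40), spacing=(1.0, 1.0, 1.0),
                         sd=2.0, axis_xy=(15.5, 15.5), amplitude=1.0):
    """Analytic noise-free tube along z with Gaussian cross-section of sd mm."""
    sp = np.asarray(spacing)
    x = np.arange(shape[0]) * sp[0]
    y = np.arange(shape[1]) * sp[1]
    d2 = (x[:, None] - axis_xy[0]) ** 2 + (y[None, :] - axis_xy[1]) ** 2
    img = amplitude * np.exp(-d2 / (2 * sd**2))
    data = np.repeat(img[:, :, None], shape[2], axis=2)
    return ScalarVolume(data=data, spacing=spacing)


@pytest.fixture(scope="session")
def ladder10():
    return make_scale_ladder(1.0, 4.5, 10)


@pytest.fixture(scope="session")
def tube_volume():
    return gaussian_tube_volume()


@pytest.fixture(scope="session")
def tube_scale_space(tube_volume, ladder10):
    return build_scale_space(tube_volume, ladder10)


@pytest.fixture(scope="session")
def straight_bundle():
    """Noisy two-modality straight-tube phantom (default study conditions)."""
    return generate(
        PhantomSpec(
            tubes=(straight_tube((23.5, 23.5, 2.0), (23.5, 23.5, 45.0), radius=2.0),),
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def quiet_bundle():
    """Near-noise-free single-modality straight tube for geometric checks."""
    return generate(
        PhantomSpec(
            tubes=(straight_tube((23.5, 23.5, 2.0), (23.5, 23.5, 45.0), radius=2.0),),
            modalities=(ModalityParams(noise_sd=1e-4, psf_sd=0.2),),
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()
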