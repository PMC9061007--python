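import numpy as np
import pytest

from osfpnet import BackboneConfig, CohortSpec, ModelConfig, PoolingSpec, generate_cohort


@pytest.fixture(scope="session")
def micro_model_cfg():
    """Smallest configuration that still exercises every architectural piece:
    two conv blocks (one pool), 2-level SPP/MSP, a single hidden FC layer."""
    return ModelConfig(
        backbone=BackboneConfig(
            n_blocks=2, convs_per_block=(1, 1), channels=(2, 3), in_channels=1
        ),
        pooling_T=PoolingSpec("SPP", ((1, 1), (2, 2))),
        pooling_L=PoolingSpec("MSP", ((1, 1), (2, 1)), "average"),
        fc_sizes=(8,),
        dropout_drop_p=0.5,
    )


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def small_cohort():
    """10 fast subjects with compact images."""
    spec = CohortSpec(
        n_subjects=10,
        transverse_size_range=(60, 72),
        longitudinal_height_range=(60, 68),
        longitudinal_aspect_range=(2.5, 3.0),
        effect_size=1.0,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_quadruple(rng, lo=48, hi=72):
    """A valid (LT, LL, RT, RL) quadruple of random sizes and intensities."""
    def trans():
        h = int(rng.integers(lo, hi))
        w = int(rng.integers(max(lo, int(0.8 * h)), min(hi, int(1.3 * h)) + 1))
        return rng.integers(0, 256, (h, w), dtype=np.uint8)

    def longi():
        h = int(rng.integers(lo, hi))
        return rng.integers(0, 256, (h, int(2.5 * h)), dtype=np.uint8)

    return (trans(), longi(), trans(), longi())
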