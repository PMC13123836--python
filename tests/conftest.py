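"""Shared fixtures: small schemes, micro generator configs, a mini model.

Everything here is generated at test time; the "micro" grid (64 x 32, short
acquisition) keeps the end-to-end network tests fast while exercising the
same code paths as the full 512 x 200 pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest

from singlepulse import (
    AcquisitionScheme,
    ArchConfig,
    CorrelationMapper,
    GeneratorConfig,
    SpinSystem,
    TrainConfig,
    train_curriculum,
)


@pytest.fixture(scope="session")
def small_scheme() -> AcquisitionScheme:
    """16.4 T scheme with few offsets — cheap but physically standard."""
    return AcquisitionScheme(
        n_zf=512,
        offsets_c=np.linspace(-2.0, 28.0, 21),
    )


@pytest.fixture(scope="session")
def one_spin() -> SpinSystem:
    return SpinSystem(wh=0.5, wc=13.0, j_hc=125.0, r2_h=25.0, r2_mq=25.0,
                      r2_aph=25.0, i0=1.0)


def micro_config(**overrides) -> GeneratorConfig:
    """A 64 x 32 grid with a short acquisition: same pipeline, tiny cost."""
    kw = dict(
        n_zf=64,
        n_offsets=32,
        t_max=0.016,  # <= 64 acquired points at the widest jittered sweep
        h_fwhm_min_hz=110.0,
        c_fwhm_hz=220.0,
        noise_max_range=(0.0, 0.02),
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


@pytest.fixture(scope="session")
def micro_gen_config() -> GeneratorConfig:
    return micro_config()


MICRO_ARCH = ArchConfig(widths=(6, 12, 24), kernels=(3, 3, 5, 5, 3, 3, 3, 3))


@pytest.fixture(scope="session")
def mini_model(micro_gen_config):
    """A small network trained on 1-2-peak micro examples.

    Good enough to localize isolated peaks, cheap enough for CI-style runs;
    shared across the network/reconstruction tests.
    """
    est = CorrelationMapper(arch=MICRO_ARCH, batch_size=8, random_state=0)
    tc = TrainConfig(curriculum=((1, 400), (2, 400)), seed=0, lr=2e-3,
                     lr_decay_per_round=0.5)
    train_curriculum(est, tc, micro_gen_config)
    return est
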