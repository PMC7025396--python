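import dataclasses

import numpy as np
import pytest

from cvipwi import load_config
from cvipwi.core import BinaryMask, Geometry, PerfusionSeries, ScalarMap
from cvipwi.phantom import PhantomSpec, build_phantom


@pytest.fixture
def simple_geometry():
    vs = (1.8, 1.8, 5.2)
    affine = np.diag(list(vs) + [1.0])
    return Geometry((8, 6, 4), vs, affine, left_right_axis=0)


def make_geometry(shape, voxel_size=(1.8, 1.8, 5.2)):
    affine = np.diag(list(voxel_size) + [1.0])
    return Geometry(shape, voxel_size, affine, left_right_axis=0)


@pytest.fixture
def cfg_left():
    return load_config(
        affected_side="left", motion_correction=False, assume_registered=True
    )


SMALL_SPEC = PhantomSpec(
    name="small", shape=(32, 32, 10), n_volumes=20, noise_sigma=0.0,
    bolus_t0=12.0, core_block=(5, 10, 3),
)


@pytest.fixture(scope="session")
def small_phantom():
    """Small noise-free phantom for fast unit tests."""
    return build_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def symmetric_phantom_noisefree():
    return build_phantom(PhantomSpec(name="symmetric-noisefree", noise_sigma=0.0))


@pytest.fixture(scope="session")
def symmetric_phantom():
    return build_phantom(PhantomSpec(name="symmetric", seed=11))


def run_cvi_case(ph, cfg):
    """Convenience: full in-memory pipeline on a phantom."""
    from cvipwi import run_case_objects

    return run_case_objects(
        ph.series, ph.adc, ph.brain, ph.ventricles, ph.atlas_density,
        ph.sinus, cortex=ph.cortex, cfg=cfg,
    )
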