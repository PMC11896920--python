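import dataclasses

import numpy as np
import pytest

from gutmotion.geometry import resample_centerline
from gutmotion.phantom import PhantomConfig, generate_phantom, preset_phantoms
from gutmotion.registration import OracleBackend, build_tube_roi


def straight_path(x0=12.0, x1=76.0, y=44.1, z=16.25, n=120):
    x = np.linspace(x0, x1, n)
    return np.column_stack([x, np.full_like(x, y), np.full_like(x, z)])


@pytest.fixture(scope="session")
def compact_forward():
    """Compact motile_forward phantom: frames, centerline, ground truth."""
    return generate_phantom(preset_phantoms("motile_forward", seed=11, compact=True))


@pytest.fixture(scope="session")
def compact_nonmotile():
    return generate_phantom(preset_phantoms("non_motile", seed=12, compact=True))


@pytest.fixture(scope="session")
def static_pair():
    """Two identical noiseless frames of a static tube (no motion at all)."""
    cfg = PhantomConfig(
        grid_shape=(64, 64, 14), n_frames=2, noise_sd=0.0, seed=3, tube_path=straight_path()
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def forward_oracle_model(compact_forward):
    """Oracle deformation model for the first frame pair of the forward phantom."""
    frames, cl, truth = compact_forward
    ref = resample_centerline(cl.points, 1.0)
    roi = build_tube_roi(ref, 40.0, volume=frames[0])
    return OracleBackend(truth).register(frames[0], frames[1], roi), ref


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
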