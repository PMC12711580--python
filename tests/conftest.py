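"""Shared fixtures: compact synthetic scenes reused across test modules."""

import numpy as np
import pytest

from samquant import RegionSpec, SceneSpec, make_scene, no_noise, render_scene


@pytest.fixture(scope="session")
def region_spec():
    return RegionSpec()


def small_spec(**overrides) -> SceneSpec:
    """A compact scene (160x160 px, 0.7 um/px) that keeps tests fast."""
    base = dict(
        image_shape=(160, 160),
        pixel_size_um=0.7,
        apex_rc=(20.0, 80.0),
        n_nuclei=60,
        seed=11,
    )
    base.update(overrides)
    return SceneSpec(**base)


@pytest.fixture(scope="session")
def clean_scene(region_spec):
    """Noise-free scene with an exact (unjittered) outline trace."""
    spec = small_spec(noise=no_noise(), outline_jitter_px=0.0)
    truth = make_scene(spec, region_spec)
    stack, mask = render_scene(truth)
    return truth, stack, mask


@pytest.fixture(scope="session")
def noisy_scene(region_spec):
    """Scene with the default noise model and jittered outline."""
    spec = small_spec(seed=12)
    truth = make_scene(spec, region_spec)
    stack, mask = render_scene(truth)
    return truth, stack, mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
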