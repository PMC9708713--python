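"""Shared fixtures: anatomies and phantoms are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from petdeblur.anatomy import AnatomyConfig, generate_anatomy
from petdeblur.phantom import render_ground_truth, sample_activity_assignment

#: A compact head that still realizes all nine labels, for fast unit tests.
SMALL_CONFIG = AnatomyConfig(
    grid_shape=(48, 48, 48),
    head_axes_mm=(19.0, 22.0, 20.0),
    cortical_thickness_mm=2.5,
    shell_thicknesses_mm=(2.5, 3.0, 2.5),
    cerebellum_fraction=0.45,
    bg_blob_spec=(2, 3.0),
    jitter_scale=0.0,
    seed=7,
)


@pytest.fixture(scope="session")
def small_anatomy():
    return generate_anatomy(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_anatomy():
    return generate_anatomy(AnatomyConfig(seed=7))


@pytest.fixture(scope="session")
def small_phantom(small_anatomy):
    a = sample_activity_assignment(
        gm_wm_ratio=3.6, rng=np.random.default_rng(11)
    )
    return render_ground_truth(small_anatomy, a)


@pytest.fixture(scope="session")
def default_phantom(default_anatomy):
    a = sample_activity_assignment(
        gm_wm_ratio=3.6, rng=np.random.default_rng(11)
    )
    return render_ground_truth(default_anatomy, a)
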