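"""Shared fixtures: small synthetic clips and preprocessed windows.

Session-scoped so the rendering/preprocessing cost is paid once; tests must
not mutate these objects.
"""

from __future__ import annotations

import numpy as np
import pytest

from hydramotion.config import PipelineConfig
from hydramotion.fixtures import SyntheticSpec, make_behavior_clip
from hydramotion.preprocess import iter_windows, process_clip, register_window

SMALL = dict(image_size=160, body_length_px=60)


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """Reduced-resolution pipeline settings used throughout the suite."""
    return PipelineConfig(canonical_size=160, canonical_body_px=55,
                          opening_radius_px=25, gmm_k=8)


@pytest.fixture(scope="session")
def bending_clip():
    return make_behavior_clip(SyntheticSpec("bending", seed=5, **SMALL))


@pytest.fixture(scope="session")
def silent_clip_noisefree():
    return make_behavior_clip(SyntheticSpec("silent", seed=3, noise_sd=0.0,
                                            **SMALL))


@pytest.fixture(scope="session")
def sway_window(small_config):
    """A registered tentacle-sway window plus its clip-level products."""
    clip, truth = make_behavior_clip(SyntheticSpec("tentacle_sway", seed=7,
                                                   **SMALL))
    geos = process_clip(clip, small_config)
    start, sub = next(iter_windows(clip, small_config))
    window = register_window(sub, geos[:small_config.window_frames],
                             small_config)
    return {"clip": clip, "truth": truth, "geometries": geos,
            "window": window}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
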