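"""Shared fixtures: small synthetic datasets and reduced-scale configs."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vam.encoder import EncoderConfig
from vam.stimuli import (
    GroundTruthConfig,
    RenderConfig,
    records_to_frame,
    render_batch,
    sample_trial_specs,
    simulate_participant,
)


@pytest.fixture(scope="session")
def desk_render_cfg():
    return RenderConfig(out_hw=(32, 32), canvas_scale=0.25)


@pytest.fixture(scope="session")
def tiny_encoder_cfg():
    """8x8 single-channel two-block encoder for gradient checks."""
    return EncoderConfig(input_hw=(8, 8), in_channels=1,
                         conv_channels=(4, 4), fc_width=8)


@pytest.fixture(scope="session")
def desk_encoder_cfg():
    return EncoderConfig(input_hw=(32, 32), conv_channels=(16, 16, 32),
                         fc_width=64)


@pytest.fixture(scope="session")
def synthetic_session(desk_render_cfg):
    """600 trials with images at desk scale (rendered once per session)."""
    specs = sample_trial_specs(600, 0.5, seed=123, cfg=desk_render_cfg)
    records = simulate_participant(specs, GroundTruthConfig(), seed=321)
    trials = records_to_frame(records)
    images = render_batch([r.spec for r in records], desk_render_cfg)
    return trials, images


@pytest.fixture(scope="session")
def behavior_frame():
    """Pure trial table (no images) with strong congruency structure."""
    specs = sample_trial_specs(4000, 0.5, seed=7)
    records = simulate_participant(specs, GroundTruthConfig(), seed=8)
    return records_to_frame(records)
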