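"""Shared fixtures.

The two trained-network fixtures run a desk-scale training (small widths,
small sample counts) once per session; the acceptance tests and the
end-to-end movie tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from holomass.optics import OpticalConfig
from holomass.runet import MapCodec, RUNetConfig, TrainConfig, build_runet, train_runet
from holomass.simulate import (
    SceneParams,
    SequenceParams,
    render_truth_maps,
    sample_runet_scene,
    sample_wacnet_sequence,
    simulate_hologram,
)
from holomass.wacnet import WacCodec, build_wacnet, train_wacnet, WACNetConfig

# ---- desk-scale study conditions -------------------------------------------
# 64-px training grids: the angular-spectrum kernel of a 64-px grid at
# 3.6 µm pitch aliases beyond ~1.7 mm, so the axial range is [500, 1500] µm;
# particle counts match the areal density of the full-scale 1-8 per 128².
SCALED_SCENE = SceneParams(
    image_shape=(64, 64), n_particles=(1, 3), z_range_um=(500.0, 1500.0)
)
SCALED_SEQUENCE = SequenceParams(z_range_um=(500.0, 1500.0))
SCALED_RUNET = RUNetConfig(
    down_filters=(8, 16, 32, 48),
    up_filters=(48, 32, 16, 8),
    seg_up_filters=(16, 12, 8, 6),  # segmentation needs less capacity
    convs_per_block=2,
    input_shape=(64, 64),
)
SCALED_RUNET_TRAIN = TrainConfig(
    learning_rate=3e-3,
    lr_schedule="cosine",
    batch_size=4,
    epochs=32,
    n_samples=500,
    prebuffer=250,
    loss_weights={"z": 3.0, "mass": 3.0},
    seed=7,
)
SCALED_MAP_CODEC_KW = {"mass_encoding": "log"}
SCALED_WACNET = WACNetConfig(
    conv_filters=(8, 16, 32, 48),
    latent_dense=(64, 64),
    weight_head=(64, 1),
    output_head=(32, 32, 2),
)
SCALED_WACNET_TRAIN = TrainConfig(
    learning_rate=1e-3,
    lr_schedule="cosine",
    batch_size=8,
    epochs=16,
    n_samples=500,
    prebuffer=250,
    seed=11,
)
SCALED_WAC_CODEC_KW = {"optical_volume_encoding": "log"}


@pytest.fixture(scope="session")
def optics() -> OpticalConfig:
    return OpticalConfig()


def runet_scene_stream(config: OpticalConfig, seed: int, params: SceneParams):
    rng = np.random.default_rng(seed)
    while True:
        scene = sample_runet_scene(rng, config, params)
        holo = simulate_hologram(scene, rng_seed=int(rng.integers(0, 2**31 - 1)))
        yield holo, render_truth_maps(scene)


def wacnet_sequence_stream(config: OpticalConfig, seed: int, params: SequenceParams):
    rng = np.random.default_rng(seed)
    while True:
        yield sample_wacnet_sequence(rng, config, params)


@pytest.fixture(scope="session")
def trained_runet(optics):
    """Detection network trained at desk scale (shared across tests)."""
    model = build_runet(SCALED_RUNET, seed=7)
    codec = MapCodec(**SCALED_MAP_CODEC_KW)
    history = train_runet(
        model, runet_scene_stream(optics, 1234, SCALED_SCENE), SCALED_RUNET_TRAIN, codec
    )
    return model, codec, history


@pytest.fixture(scope="session")
def trained_wacnet(optics):
    """Mass-refinement network trained at desk scale (shared across tests)."""
    model = build_wacnet(SCALED_WACNET, seed=11)
    codec = WacCodec(**SCALED_WAC_CODEC_KW)
    history = train_wacnet(
        model,
        wacnet_sequence_stream(optics, 4321, SCALED_SEQUENCE),
        SCALED_WACNET_TRAIN,
        codec,
    )
    return model, codec, history
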