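"""End-to-end orchestration: simulate/train as needed, then
detect -> track -> mass series -> events, with every artifact stamped by the
configuration hash and seed."""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np

from . import io as hio
from .detect import detections_from_maps
from .runet import MapCodec, build_runet, load_runet, predict_maps, save_runet, train_runet
from .simulate import (
    make_feeding_movie,
    render_truth_maps,
    sample_runet_scene,
    sample_wacnet_sequence,
    simulate_hologram,
)
from .tracking import (
    detect_division_events,
    detect_feeding_events,
    link_tracks,
    mass_time_series,
)
from .wacnet import WacCodec, build_wacnet, load_wacnet, save_wacnet, train_wacnet

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "scene_stream", "sequence_stream", "ensure_models"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, partial outputs persist."""


def scene_stream(config: "hio.PipelineConfig", seed: int):
    """Endless deterministic stream of (Hologram, TruthMaps) training pairs."""
    rng = np.random.default_rng(seed)
    while True:
        scene = sample_runet_scene(rng, config.optics, config.scene)
        holo = simulate_hologram(scene, rng_seed=int(rng.integers(0, 2**31 - 1)))
        yield holo, render_truth_maps(scene)


def sequence_stream(config: "hio.PipelineConfig", seed: int):
    """Endless deterministic stream of crop-sequence training samples."""
    rng = np.random.default_rng(seed)
    while True:
        yield sample_wacnet_sequence(rng, config.optics, config.sequence)


def ensure_models(
    config: "hio.PipelineConfig",
    out_dir: str,
    train_if_missing: bool = True,
):
    """Load checkpoints from ``out_dir`` or train them from the config.

    Returns ``(runet_model, map_codec, wacnet_model, wac_codec)``.
    """
    runet_path = os.path.join(out_dir, "runet.npz")
    wacnet_path = os.path.join(out_dir, "wacnet.npz")
    chash = hio.config_hash(config)

    if os.path.exists(runet_path):
        model, codec, _ = load_runet(runet_path)
    elif train_if_missing:
        logger.info("training detection network (seed %d)", config.seed)
        model = build_runet(config.runet, seed=config.seed)
        codec = config.map_codec
        train_runet(model, scene_stream(config, config.seed + 1), config.runet_train, codec)
        save_runet(
            runet_path,
            model,
            codec,
            {"seed": config.seed, "config_hash": chash, "train": "pipeline"},
        )
    else:
        raise PipelineError(
            f"stage=models: no checkpoint at {runet_path} and training is "
            "disabled; train one with `holomass train-runet` or enable training"
        )

    if os.path.exists(wacnet_path):
        wmodel, wcodec, _ = load_wacnet(wacnet_path)
    elif train_if_missing:
        logger.info("training mass-refinement network (seed %d)", config.seed)
        wmodel = build_wacnet(config.wacnet, seed=config.seed)
        wcodec = config.wac_codec
        train_wacnet(
            wmodel, sequence_stream(config, config.seed + 2), config.wacnet_train, wcodec
        )
        save_wacnet(
            wacnet_path,
            wmodel,
            wcodec,
            {"seed": config.seed, "config_hash": chash, "train": "pipeline"},
        )
    else:
        raise PipelineError(
            f"stage=models: no checkpoint at {wacnet_path} and training is "
            "disabled; train one with `holomass train-wacnet` or enable training"
        )
    return model, codec, wmodel, wcodec


def run_pipeline(
    config: "hio.PipelineConfig",
    frames: np.ndarray | None = None,
    train_if_missing: bool = True,
) -> dict:
    """Run the full chain on a frame stack (synthetic demo movie if None).

    Writes detections.csv, tracks.csv, feeding_events.json,
    division_events.json and run.json (stage log) into
    ``config.output_dir``; returns a summary dict.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    chash = hio.config_hash(config)
    stamp = {"config_hash": chash, "seed": config.seed}
    stages = []

    def stage(name):
        t0 = time.time()

        def done(**counts):
            stages.append({"stage": name, "seconds": round(time.time() - t0, 2), **counts})
            logger.info("stage %s done in %.1fs %s", name, time.time() - t0, counts)

        return done

    try:
        done = stage("models")
        runet_model, map_codec, wac_model, wac_codec = ensure_models(
            config, out, train_if_missing
        )
        done()
    except PipelineError:
        _persist_log(out, stages, stamp)
        raise

    if frames is None:
        done = stage("simulate")
        frames, truth = make_feeding_movie(
            config.optics, np.random.default_rng(config.seed + 3)
        )
        hio.save_frames(os.path.join(out, "frames.tiff"), frames)
        done(n_frames=len(frames))

    pitch = config.optics.pixel_pitch_um
    try:
        done = stage("detect")
        per_frame = []
        for i, frame in enumerate(frames):
            maps = predict_maps(runet_model, frame, map_codec)
            per_frame.append(detections_from_maps(maps, config.decoder, frame_index=i))
        all_dets = [d for dets in per_frame for d in dets]
        hio.detections_to_csv(all_dets, pitch, os.path.join(out, "detections.csv"))
        done(n_detections=len(all_dets))

        done = stage("track")
        tracks = link_tracks(per_frame, pitch, config.link)
        done(n_tracks=len(tracks))

        done = stage("mass_series")
        window = config.mass_window
        usable = []
        for t in tracks:
            if t.death - t.birth + 1 >= max(window, 15):
                mass_time_series(
                    t, wac_model, frames, window, pitch, wac_codec,
                    config.optics.dn_dc_ml_g,
                )
                usable.append(t)
        hio.tracks_to_csv(usable, pitch, os.path.join(out, "tracks.csv"))
        done(n_annotated=len(usable))

        done = stage("events")
        feeding = detect_feeding_events(usable, pitch, config.feeding)
        division = detect_division_events(usable, pitch, config.division)
        hio.events_to_json(feeding, os.path.join(out, "feeding_events.json"), stamp)
        hio.events_to_json(division, os.path.join(out, "division_events.json"), stamp)
        done(n_feeding=len(feeding), n_division=len(division))
    except Exception as e:
        _persist_log(out, stages, stamp)
        raise PipelineError(f"stage={stages[-1]['stage'] if stages else '?'}: {e}") from e

    _persist_log(out, stages, stamp)
    return {
        "config_hash": chash,
        "n_tracks": len(tracks),
        "n_feeding_events": len(feeding),
        "n_division_events": len(division),
        "stages": stages,
        "output_dir": out,
    }


def _persist_log(out, stages, stamp):
    with open(os.path.join(out, "run.json"), "w") as fh:
        json.dump({**stamp, "stages": stages}, fh, indent=2)
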