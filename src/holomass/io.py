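"""Frame loading, configuration serialization, and result tables."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .detect import DecoderParams, Detection
from .optics import OpticalConfig
from .runet import MapCodec, RUNetConfig, TrainConfig
from .simulate import SceneParams, SequenceParams
from .tracking import DivisionParams, FeedingParams, LinkParams, Track
from .wacnet import WacCodec, WACNetConfig

logger = logging.getLogger(__name__)

__all__ = [
    "load_frames",
    "save_frames",
    "PipelineConfig",
    "load_config",
    "save_config",
    "config_hash",
    "detections_to_csv",
    "detections_from_csv",
    "tracks_to_csv",
    "events_to_json",
]


def load_frames(path, normalize: bool = False) -> tuple[np.ndarray, dict]:
    """Load a frame stack from a multi-page TIFF or a directory of PNG/TIFF.

    Returns ``(stack (T, H, W) float64, metadata)``.  RGB input is averaged
    to one channel with a warning; mixed shapes raise.  With
    ``normalize=True`` each frame is divided by the temporal median image
    (the static background), which maps the unscattered background to 1.
    """
    import tifffile

    if os.path.isdir(path):
        names = sorted(
            f
            for f in os.listdir(path)
            if f.lower().endswith((".png", ".tif", ".tiff"))
        )
        if not names:
            raise ValueError(f"no PNG/TIFF frames in {path}")
        import imageio.v3 as iio

        frames = []
        for name in names:
            full = os.path.join(path, name)
            img = (
                tifffile.imread(full)
                if name.lower().endswith((".tif", ".tiff"))
                else iio.imread(full)
            )
            frames.append(np.asarray(img))
    else:
        stack = tifffile.imread(path)
        frames = [stack] if stack.ndim == 2 else list(stack)

    shapes = {f.shape[:2] for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"mixed frame shapes: {sorted(shapes)}")
    out = []
    for f in frames:
        if f.ndim == 3:
            logger.warning("RGB frame converted to single channel by averaging")
            f = f.mean(axis=-1)
        out.append(f.astype(np.float64))
    stack = np.stack(out)
    meta = {"n_frames": len(out), "shape": list(shapes.pop()), "normalized": normalize}
    if normalize:
        background = np.median(stack, axis=0)
        background = np.where(background == 0, 1.0, background)
        stack = stack / background
    return stack, meta


def save_frames(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) stack as a multi-page float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, serializable to one YAML document."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    scene: SceneParams = field(default_factory=SceneParams)
    sequence: SequenceParams = field(default_factory=SequenceParams)
    runet: RUNetConfig = field(default_factory=RUNetConfig)
    runet_train: TrainConfig = field(default_factory=TrainConfig)
    map_codec: MapCodec = field(default_factory=MapCodec)
    wacnet: WACNetConfig = field(default_factory=WACNetConfig)
    wacnet_train: TrainConfig = field(default_factory=TrainConfig)
    wac_codec: WacCodec = field(default_factory=WacCodec)
    decoder: DecoderParams = field(default_factory=DecoderParams)
    link: LinkParams = field(default_factory=LinkParams)
    feeding: FeedingParams = field(default_factory=FeedingParams)
    division: DivisionParams = field(default_factory=DivisionParams)
    seed: int = 0
    output_dir: str = "holomass_out"
    mass_window: int = 1


_TUPLE_FIELDS = {"sensor_size_mm", "sensor_pixels"}


def _build(cls, d: dict):
    """Instantiate a (nested) dataclass from a plain dict, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in d.items():
        ftype = fields[name].type
        nested = _NESTED.get((cls, name))
        if nested is not None:
            kwargs[name] = _build(nested, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        elif isinstance(value, dict):
            kwargs[name] = dict(value)
        else:
            kwargs[name] = value
        del ftype
    return cls(**kwargs)


_NESTED = {
    (PipelineConfig, "optics"): OpticalConfig,
    (PipelineConfig, "scene"): SceneParams,
    (PipelineConfig, "sequence"): SequenceParams,
    (PipelineConfig, "runet"): RUNetConfig,
    (PipelineConfig, "runet_train"): TrainConfig,
    (PipelineConfig, "map_codec"): MapCodec,
    (PipelineConfig, "wacnet"): WACNetConfig,
    (PipelineConfig, "wacnet_train"): TrainConfig,
    (PipelineConfig, "wac_codec"): WacCodec,
    (PipelineConfig, "decoder"): DecoderParams,
    (PipelineConfig, "link"): LinkParams,
    (PipelineConfig, "feeding"): FeedingParams,
    (PipelineConfig, "division"): DivisionParams,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return _build(PipelineConfig, raw)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash stamped on every artifact for traceability."""
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_DET_COLUMNS = [
    "frame",
    "x_px",
    "y_px",
    "x_um",
    "y_um",
    "z_um",
    "mass_pg",
    "support",
    "confidence",
]


def detections_to_csv(detections: list[Detection], pitch_um: float, path) -> None:
    import pandas as pd

    rows = [
        {
            "frame": d.frame_index,
            "x_px": d.x_px,
            "y_px": d.y_px,
            "x_um": d.x_px * pitch_um,
            "y_um": d.y_px * pitch_um,
            "z_um": d.z_um,
            "mass_pg": d.mass_pg,
            "support": d.support,
            "confidence": d.confidence,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=_DET_COLUMNS).to_csv(path, index=False)


def detections_from_csv(path) -> list[Detection]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        Detection(
            frame_index=int(r.frame),
            x_px=float(r.x_px),
            y_px=float(r.y_px),
            z_um=float(r.z_um),
            mass_pg=float(r.mass_pg),
            support=int(r.support),
            confidence=float(r.confidence),
        )
        for r in df.itertuples()
    ]


def tracks_to_csv(tracks: list[Track], pitch_um: float, path) -> None:
    import pandas as pd

    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append(
                {
                    "track_id": t.id,
                    "frame": d.frame_index,
                    "x_um": d.x_px * pitch_um,
                    "y_um": d.y_px * pitch_um,
                    "z_um": d.z_um,
                    "mass_pg": t.mass_at(d.frame_index) or d.mass_pg,
                    "window": t.window if t.window is not None else 0,
                }
            )
    pd.DataFrame(
        rows,
        columns=["track_id", "frame", "x_um", "y_um", "z_um", "mass_pg", "window"],
    ).to_csv(path, index=False)


def events_to_json(events, path, provenance: dict | None = None) -> None:
    """Serialize feeding/division event records with provenance."""
    payload = {
        "provenance": provenance or {},
        "events": [_to_plain(e) if dataclasses.is_dataclass(e) else e for e in events],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
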