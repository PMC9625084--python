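"""Regression U-Net: hologram -> five per-pixel heat maps.

A U-Net whose upsampling path splits into two parallel arms.  One arm ends
in a sigmoid and produces the segmentation channel; the other ends in a
ReLU and produces the four regression channels (axial position z, dry mass
m, and the signed in-plane offsets Δx, Δy to the nearest particle center,
used for subpixel localization).  Regression targets are trained in encoded
units (z and mass divided by fixed scales; offsets shifted and scaled to be
non-negative so a ReLU head can express them); :class:`MapCodec` owns those
constants and travels with every checkpoint.

The loss is binary cross-entropy on the segmentation channel plus a mean
absolute error on each regression channel restricted to the pixels where
that channel is defined (the particle's segmentation disk for z/mass, the
offset-definition neighbourhood for Δx/Δy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np

from .nn import Adam, Conv2D, Module, Tensor, bce, concat, conv2d, maxpool2, split_last, upsample2
from .nn.optim import release_heap
from .nn.checkpoint import load_checkpoint, save_checkpoint
from .simulate import Hologram, TruthMaps

logger = logging.getLogger(__name__)

__all__ = [
    "RUNetConfig",
    "TrainConfig",
    "MapCodec",
    "RUNet",
    "build_runet",
    "runet_loss",
    "train_runet",
    "predict_maps",
    "save_runet",
    "load_runet",
    "TrainingDivergedError",
]

CHANNEL_NAMES = ("seg", "z", "mass", "dx", "dy")


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the history so far."""

    def __init__(self, msg: str, history: dict):
        super().__init__(msg)
        self.history = history


@dataclass(frozen=True)
class RUNetConfig:
    """Architecture: six down blocks (filter counts below), the first four
    followed by 2x2 max-pooling, the last two at bottleneck resolution; two
    independent four-block upsampling arms with skip connections from every
    pooled stage."""

    down_filters: tuple[int, ...] = (8, 16, 32, 64, 32, 32)
    up_filters: tuple[int, ...] = (128, 64, 32, 16)
    seg_up_filters: tuple[int, ...] | None = None  # defaults to up_filters
    convs_per_block: int = 2
    input_shape: tuple[int, int] = (128, 128)
    in_channels: int = 1

    def __post_init__(self):
        div = 2 ** len(self.up_filters)
        if any(s % div for s in self.input_shape):
            raise ValueError(
                f"input_shape {self.input_shape} must be divisible by {div}"
            )
        if len(self.down_filters) < len(self.up_filters):
            raise ValueError("need at least as many down blocks as up blocks")
        if self.seg_up_filters is not None and len(self.seg_up_filters) != len(
            self.up_filters
        ):
            raise ValueError("both arms need the same number of upsampling blocks")


@dataclass(frozen=True)
class MapCodec:
    """Encode/decode constants between physical units and training units.

    Mass spans three decades (1-995 pg); with ``mass_encoding="log"`` the
    channel is trained as log10(1 + m/mass_scale·100), which balances the
    absolute-error loss across the range (an error of fixed size in the
    encoded unit is a fixed *relative* mass error).  ``"linear"`` trains
    plain m/mass_scale.
    """

    z_scale: float = 1000.0  # µm per training unit
    mass_scale: float = 100.0  # pg per training unit (linear encoding)
    mass_encoding: str = "linear"  # or "log"
    offset_range: float = 16.0  # px shift making offsets non-negative
    offset_scale: float = 16.0  # px per training unit after the shift
    input_offset: float = 1.0  # hologram background level subtracted on input

    def encode_input(self, pixels: np.ndarray) -> np.ndarray:
        return (pixels - self.input_offset).astype(np.float32)

    def _encode_mass(self, mass: np.ndarray) -> np.ndarray:
        if self.mass_encoding == "log":
            return np.log10(1.0 + np.maximum(mass, 0.0))
        return mass / self.mass_scale

    def _decode_mass(self, enc: np.ndarray) -> np.ndarray:
        if self.mass_encoding == "log":
            return 10.0**enc - 1.0
        return enc * self.mass_scale

    def encode_targets(self, truth: TruthMaps) -> tuple[np.ndarray, np.ndarray]:
        """Return (target, mask), both (H, W, 5) float32."""
        enc_dx = np.clip(truth.dx + self.offset_range, 0.0, 2 * self.offset_range)
        enc_dy = np.clip(truth.dy + self.offset_range, 0.0, 2 * self.offset_range)
        target = np.stack(
            [
                truth.seg,
                truth.z / self.z_scale,
                self._encode_mass(truth.mass),
                enc_dx / self.offset_scale,
                enc_dy / self.offset_scale,
            ],
            axis=-1,
        ).astype(np.float32)
        seg = truth.seg > 0
        mask = np.stack(
            [np.ones_like(seg), seg, seg, truth.offset_mask, truth.offset_mask],
            axis=-1,
        ).astype(np.float32)
        return target, mask

    def decode_stack(self, pred: np.ndarray) -> np.ndarray:
        """Training units -> physical units (seg prob, µm, pg, px, px)."""
        out = np.empty_like(pred, dtype=np.float64)
        out[..., 0] = pred[..., 0]
        out[..., 1] = pred[..., 1] * self.z_scale
        out[..., 2] = self._decode_mass(pred[..., 2])
        out[..., 3] = pred[..., 3] * self.offset_scale - self.offset_range
        out[..., 4] = pred[..., 4] * self.offset_scale - self.offset_range
        return out


class RUNet(Module):
    def __init__(self, config: RUNetConfig, rng: np.random.Generator):
        self.config = config
        n_up = len(config.up_filters)
        ch = config.in_channels
        self.down_convs: list[Conv2D] = []
        self._down_plan: list[tuple[int, bool]] = []  # (convs in block, pooled)
        skip_channels = []
        for i, f in enumerate(config.down_filters):
            for _ in range(config.convs_per_block):
                self.down_convs.append(Conv2D(ch, f, rng))
                ch = f
            pooled = i < n_up
            if pooled:
                skip_channels.append(f)
            self._down_plan.append((config.convs_per_block, pooled))
        bottleneck_ch = ch

        def make_arm(out_ch: int, filters):
            convs = []
            ch_a = bottleneck_ch
            for j, f in enumerate(filters):
                cin = ch_a + skip_channels[n_up - 1 - j]
                for k in range(config.convs_per_block):
                    convs.append(Conv2D(cin if k == 0 else f, f, rng))
                ch_a = f
            head = Conv2D(ch_a, out_ch, rng, k=1)
            return convs, head

        self.seg_convs, self.seg_head = make_arm(
            1, config.seg_up_filters or config.up_filters
        )
        self.reg_convs, self.reg_head = make_arm(4, config.up_filters)

    def forward(self, x: np.ndarray) -> Tensor:
        """(N, H, W, C) encoded input -> (N, H, W, 5) encoded prediction."""
        n_up = len(self.config.up_filters)
        h, w = x.shape[1:3]
        div = 2**n_up
        if h % div or w % div:
            raise ValueError(f"input spatial shape {(h, w)} not divisible by {div}")
        t = Tensor(np.ascontiguousarray(x, dtype=np.float32))
        skips = []
        ci = 0
        for i, (n_convs, pooled) in enumerate(self._down_plan):
            for _ in range(n_convs):
                t = self.down_convs[ci](t).relu()
                ci += 1
            if pooled:
                skips.append(t)
                t = maxpool2(t)

        def run_arm(convs, head, act):
            a = t
            ci = 0
            for j in range(n_up):
                a = concat([upsample2(a), skips[n_up - 1 - j]], axis=-1)
                for _ in range(self.config.convs_per_block):
                    a = convs[ci](a).relu()
                    ci += 1
            out = head(a)
            return out.sigmoid() if act == "sigmoid" else out.relu()

        seg = run_arm(self.seg_convs, self.seg_head, "sigmoid")
        reg = run_arm(self.reg_convs, self.reg_head, "relu")
        return concat([seg, reg], axis=-1)


def build_runet(config: RUNetConfig | None = None, seed: int = 0) -> RUNet:
    """Construct a randomly initialized RU-Net (He-normal, seeded)."""
    return RUNet(config or RUNetConfig(), np.random.default_rng(seed))


DEFAULT_LOSS_WEIGHTS = {
    "seg": 1.0,
    "z": 1.0,
    "mass": 1.0,
    "dx": 0.5,
    "dy": 0.5,
    # positive-class weight inside the segmentation BCE; foreground disks
    # cover ~1% of a training tile, so unweighted BCE collapses to background
    "seg_pos_weight": 10.0,
}


def runet_loss(
    pred: Tensor,
    target: np.ndarray,
    mask: np.ndarray,
    weights: dict[str, float] | None = None,
) -> Tensor:
    """BCE on segmentation + per-channel masked MAE on the regressions."""
    if pred.data.shape != target.shape or target.shape != mask.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.data.shape}, target {target.shape}, "
            f"mask {mask.shape}"
        )
    w = dict(DEFAULT_LOSS_WEIGHTS, **(weights or {}))
    chans = split_last(pred, [1, 1, 1, 1, 1])
    loss = w["seg"] * bce(chans[0], target[..., :1], pos_weight=w["seg_pos_weight"])
    for c, name in enumerate(CHANNEL_NAMES[1:], start=1):
        m = mask[..., c : c + 1]
        count = float(m.sum())
        if count == 0:
            continue
        diff = (chans[c] - target[..., c : c + 1]).abs() * m
        loss = loss + (w[name] / count) * diff.sum()
    return loss


@dataclass(frozen=True)
class TrainConfig:
    """Streamed-training schedule.

    ``prebuffer`` samples are generated before the first epoch; the pool
    then grows toward ``n_samples`` as training proceeds, so late epochs
    see fresh scenes (continuous-generation scheme).
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 300
    n_samples: int = 4000
    prebuffer: int = 2000
    loss_weights: dict = field(default_factory=dict)
    seed: int = 0
    lr_schedule: str = "constant"  # or "cosine" (decay to 0 over the epochs)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.prebuffer > self.n_samples:
            raise ValueError("prebuffer cannot exceed n_samples")


def train_runet(
    model: RUNet,
    scene_stream,
    cfg: TrainConfig,
    codec: MapCodec | None = None,
) -> dict:
    """Train on a stream of (Hologram, TruthMaps) pairs.

    Returns a history dict with per-epoch mean loss and a smoothed loss
    (5-epoch moving average).  Deterministic given the stream's seed and
    ``cfg.seed``.
    """
    codec = codec or MapCodec()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, amsgrad=True)

    xs: list[np.ndarray] = []
    ts: list[np.ndarray] = []
    ms: list[np.ndarray] = []

    def pull(n: int) -> None:
        for _ in range(n):
            try:
                holo, truth = next(scene_stream)
            except StopIteration:
                return
            xs.append(codec.encode_input(holo.pixels)[..., None])
            tgt, msk = codec.encode_targets(truth)
            ts.append(tgt)
            ms.append(msk)

    pull(cfg.prebuffer)
    growth = max(0, cfg.n_samples - cfg.prebuffer)
    per_epoch = int(np.ceil(growth / cfg.epochs)) if cfg.epochs else 0

    history = {"epoch_loss": [], "smoothed_loss": []}
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.epochs))
        if len(xs) < cfg.n_samples:
            pull(min(per_epoch, cfg.n_samples - len(xs)))
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = np.stack([xs[i] for i in idx])
            tb = np.stack([ts[i] for i in idx])
            mb = np.stack([ms[i] for i in idx])
            pred = model.forward(xb)
            loss = runet_loss(pred, tb, mb, cfg.loss_weights)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}",
                    history,
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lval)
            if (start // cfg.batch_size) % 50 == 49:
                release_heap()
        release_heap()
        history["epoch_loss"].append(float(np.mean(losses)))
        k = min(5, len(history["epoch_loss"]))
        history["smoothed_loss"].append(float(np.mean(history["epoch_loss"][-k:])))
        logger.info(
            "runet epoch %d/%d loss %.4f pool %d",
            epoch + 1,
            cfg.epochs,
            history["epoch_loss"][-1],
            len(xs),
        )
    return history


def predict_maps(
    model: RUNet,
    hologram: Hologram | np.ndarray,
    codec: MapCodec | None = None,
    tile: int = 128,
    overlap: int = 32,
) -> np.ndarray:
    """Predict the decoded five-channel stack (seg prob, z µm, mass pg, Δx px, Δy px).

    Frames no larger than ``tile`` run in one pass (padded to a multiple of
    16 if needed); larger frames are processed in overlapping tiles with
    center-cropped stitching.
    """
    codec = codec or MapCodec()
    pixels = hologram.pixels if isinstance(hologram, Hologram) else np.asarray(hologram)
    mean = float(pixels.mean())
    if abs(mean - 1.0) > 0.1:
        logger.warning(
            "hologram mean %.3f far from 1; input may not be background-normalized",
            mean,
        )
    H, W = pixels.shape
    div = 2 ** len(model.config.up_filters)

    def run(patch: np.ndarray) -> np.ndarray:
        x = codec.encode_input(patch)[None, ..., None]
        return model.forward(x).data[0].astype(np.float64)

    if H <= tile and W <= tile:
        ph = (div - H % div) % div
        pw = (div - W % div) % div
        padded = np.pad(pixels, ((0, ph), (0, pw)), mode="reflect") if ph or pw else pixels
        enc = run(padded)[:H, :W]
        return codec.decode_stack(enc)

    # overlapping tiles, keep the center of each
    step = tile - overlap
    out = np.zeros((H, W, 5))
    counted = np.zeros((H, W), dtype=bool)
    for y0 in range(0, max(H - overlap, 1), step):
        for x0 in range(0, max(W - overlap, 1), step):
            y1, x1 = min(y0 + tile, H), min(x0 + tile, W)
            y0a, x0a = max(0, y1 - tile), max(0, x1 - tile)
            enc = run(pixels[y0a:y1, x0a:x1])
            cy0 = y0a + (overlap // 2 if y0a > 0 else 0)
            cx0 = x0a + (overlap // 2 if x0a > 0 else 0)
            cy1 = y1 - (overlap // 2 if y1 < H else 0)
            cx1 = x1 - (overlap // 2 if x1 < W else 0)
            sel = ~counted[cy0:cy1, cx0:cx1]
            region = out[cy0:cy1, cx0:cx1]
            region[sel] = enc[cy0 - y0a : cy1 - y0a, cx0 - x0a : cx1 - x0a][sel]
            counted[cy0:cy1, cx0:cx1] = True
    return codec.decode_stack(out)


def save_runet(path, model: RUNet, codec: MapCodec, provenance: dict | None = None):
    meta = {
        "kind": "runet",
        "config": asdict(model.config),
        "codec": asdict(codec),
        "provenance": provenance or {},
    }
    save_checkpoint(path, model.state(), meta)


def load_runet(path) -> tuple[RUNet, MapCodec, dict]:
    state, meta = load_checkpoint(path)
    if meta.get("kind") != "runet":
        raise ValueError(f"{path} is not a RU-Net checkpoint")
    c = meta["config"]
    seg_up = c.get("seg_up_filters")
    config = RUNetConfig(
        down_filters=tuple(c["down_filters"]),
        up_filters=tuple(c["up_filters"]),
        seg_up_filters=tuple(seg_up) if seg_up else None,
        convs_per_block=c["convs_per_block"],
        input_shape=tuple(c["input_shape"]),
        in_channels=c["in_channels"],
    )
    model = build_runet(config, seed=0)
    model.load_state(state)
    codec = MapCodec(**meta["codec"])
    return model, codec, meta
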