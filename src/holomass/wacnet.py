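"""Weighted-average convolutional network: crop sequence -> (dry mass, radius).

Each 64x64 crop in a sequence passes through a shared convolutional trunk to
a latent vector; a small weight head scores every latent, a softmax over the
sequence axis turns the scores into convex combination weights, and the
weighted mean latent feeds a dense head producing two numbers.  Because the
weights are a softmax over however many frames are supplied, any sequence
length >= 1 works at inference; training uses 15-frame sequences.

The mass output is trained in optical-volume units (V·Δn, the quantity a
hologram actually encodes) and divided by the specific refractive-index
increment dn/dc only at decode time, so the same trained network converts
with any assumed solute composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Adam, Conv2D, Dense, Module, Tensor, maxpool2, softmax
from .nn.optim import release_heap
from .nn.checkpoint import load_checkpoint, save_checkpoint
from .optics import DEFAULT_DN_DC
from .runet import TrainConfig, TrainingDivergedError
from .simulate import SequenceSample

logger = logging.getLogger(__name__)

__all__ = [
    "WACNetConfig",
    "WacCodec",
    "WACNet",
    "build_wacnet",
    "wacnet_loss",
    "train_wacnet",
    "predict_mass_radius",
    "MassSeries",
    "save_wacnet",
    "load_wacnet",
]


@dataclass(frozen=True)
class WACNetConfig:
    """Shared-trunk architecture: four conv blocks (conv 3x3, ReLU, 2x2
    max-pool), two dense latent layers, a (dense, dense-1) weight head
    normalized with a softmax along the sequence, and a (32, 32, 2) output
    head."""

    conv_filters: tuple[int, ...] = (32, 64, 128, 256)
    latent_dense: tuple[int, ...] = (128, 128)
    weight_head: tuple[int, ...] = (128, 1)
    output_head: tuple[int, ...] = (32, 32, 2)
    crop_size: int = 64
    train_sequence_length: int = 15


@dataclass(frozen=True)
class WacCodec:
    """Target encodings: optical volume (V·Δn, pg·ml/g) and radius (µm).

    The network regresses optical volume — the quantity a hologram actually
    encodes — and the dn/dc division happens only at decode time, so masses
    from one trained network rescale exactly inversely with the assumed
    solute composition.  ``optical_volume_encoding="log"`` trains
    log10(1 + OV·100/scale), balancing the MAE loss across the three-decade
    mass range.
    """

    optical_volume_scale: float = 20.0
    optical_volume_encoding: str = "linear"  # or "log"
    radius_scale: float = 1.0
    input_offset: float = 1.0

    def encode_input(self, frames: np.ndarray) -> np.ndarray:
        return (frames - self.input_offset).astype(np.float32)

    def _encode_ov(self, ov: float | np.ndarray):
        if self.optical_volume_encoding == "log":
            return np.log10(1.0 + np.maximum(ov, 0.0) * 100.0 / self.optical_volume_scale)
        return ov / self.optical_volume_scale

    def _decode_ov(self, enc: np.ndarray) -> np.ndarray:
        if self.optical_volume_encoding == "log":
            return (10.0**enc - 1.0) * self.optical_volume_scale / 100.0
        return enc * self.optical_volume_scale

    def encode_targets(self, sample: SequenceSample) -> np.ndarray:
        return np.array(
            [
                self._encode_ov(sample.target_optical_volume),
                sample.target_radius / self.radius_scale,
            ],
            dtype=np.float32,
        )

    def decode_outputs(
        self, out: np.ndarray, dn_dc: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Network outputs -> (mass pg, radius µm) given the assumed dn/dc."""
        mass = self._decode_ov(out[..., 0]) / dn_dc
        radius = out[..., 1] * self.radius_scale
        return mass, radius


class WACNet(Module):
    def __init__(self, config: WACNetConfig, rng: np.random.Generator):
        self.config = config
        ch = 1
        self.convs = []
        for f in config.conv_filters:
            self.convs.append(Conv2D(ch, f, rng))
            ch = f
        side = config.crop_size // (2 ** len(config.conv_filters))
        d = side * side * ch
        self.latents = []
        for n in config.latent_dense:
            self.latents.append(Dense(d, n, rng))
            d = n
        self.weight_layers = []
        dw = d
        for n in config.weight_head:
            self.weight_layers.append(Dense(dw, n, rng))
            dw = n
        self.heads = []
        dh = d
        for n in config.output_head:
            self.heads.append(Dense(dh, n, rng))
            dh = n
        self._latent_dim = d

    def forward(self, frames: np.ndarray) -> Tensor:
        """(N, T, S, S) encoded crops -> (N, 2) encoded outputs.

        Also stores the last softmax frame weights in ``self.last_weights``
        (N, T) for inspection.
        """
        if frames.ndim != 4:
            raise ValueError("frames must be (batch, time, size, size)")
        N, T = frames.shape[:2]
        if T < 1:
            raise ValueError("sequence must contain at least one frame")
        S = self.config.crop_size
        if frames.shape[2:] != (S, S):
            raise ValueError(f"crops must be {S}x{S}")
        t = Tensor(
            np.ascontiguousarray(frames, dtype=np.float32).reshape(N * T, S, S, 1)
        )
        for conv in self.convs:
            t = maxpool2(conv(t).relu())
        t = t.reshape(N * T, -1)
        for dense in self.latents:
            t = dense(t).relu()
        latent = t  # (N*T, D)

        w = latent
        for i, dense in enumerate(self.weight_layers):
            w = dense(w)
            if i < len(self.weight_layers) - 1:
                w = w.relu()
        w = softmax(w.reshape(N, T, 1), axis=1)
        self.last_weights = w.data[..., 0].copy()

        pooled = (latent.reshape(N, T, self._latent_dim) * w).sum(axis=1)
        out = pooled
        for i, dense in enumerate(self.heads):
            out = dense(out)
            if i < len(self.heads) - 1:
                out = out.relu()
        return out


def build_wacnet(config: WACNetConfig | None = None, seed: int = 0) -> WACNet:
    return WACNet(config or WACNetConfig(), np.random.default_rng(seed))


def wacnet_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    """Joint mean absolute error over the two encoded outputs."""
    if pred.data.shape != targets.shape:
        raise ValueError(f"shape mismatch: {pred.data.shape} vs {targets.shape}")
    return (pred - targets).abs().mean()


def train_wacnet(model: WACNet, sequence_stream, cfg: TrainConfig, codec: WacCodec | None = None) -> dict:
    """Train on a stream of :class:`SequenceSample`, MAE loss, AMSGrad.

    Same continuous-generation pool scheme as the detection network.
    """
    codec = codec or WacCodec()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, amsgrad=True)

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []

    def pull(n: int) -> None:
        for _ in range(n):
            try:
                sample = next(sequence_stream)
            except StopIteration:
                return
            xs.append(codec.encode_input(sample.frames))
            ys.append(codec.encode_targets(sample))

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
            yb = np.stack([ys[i] for i in idx])
            loss = wacnet_loss(model.forward(xb), yb)
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
            "wacnet epoch %d/%d loss %.4f pool %d",
            epoch + 1,
            cfg.epochs,
            history["epoch_loss"][-1],
            len(xs),
        )
    return history


@dataclass
class MassSeries:
    """Sliding-window mass/radius estimates; index i covers frames
    [i, i + window)."""

    mass_pg: np.ndarray
    radius_um: np.ndarray
    window: int


def predict_mass_radius(
    model: WACNet,
    frames: np.ndarray,
    window: int = 1,
    codec: WacCodec | None = None,
    dn_dc: float = DEFAULT_DN_DC,
    batch_size: int = 32,
) -> MassSeries:
    """Sliding-window (stride 1) evaluation over a crop stack (M, S, S)."""
    codec = codec or WacCodec()
    frames = np.asarray(frames)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(frames) < window:
        raise ValueError(f"need at least {window} frames, got {len(frames)}")
    n_out = len(frames) - window + 1
    outs = []
    for start in range(0, n_out, batch_size):
        idx = np.arange(start, min(start + batch_size, n_out))
        batch = np.stack([frames[i : i + window] for i in idx])
        outs.append(model.forward(codec.encode_input(batch)).data)
    out = np.concatenate(outs, axis=0)
    mass, radius = codec.decode_outputs(out, dn_dc)
    return MassSeries(mass.astype(np.float64), radius.astype(np.float64), window)


def save_wacnet(path, model: WACNet, codec: WacCodec, provenance: dict | None = None):
    meta = {
        "kind": "wacnet",
        "config": asdict(model.config),
        "codec": asdict(codec),
        "provenance": provenance or {},
    }
    save_checkpoint(path, model.state(), meta)


def load_wacnet(path) -> tuple[WACNet, WacCodec, dict]:
    state, meta = load_checkpoint(path)
    if meta.get("kind") != "wacnet":
        raise ValueError(f"{path} is not a WAC-Net checkpoint")
    c = meta["config"]
    config = WACNetConfig(
        conv_filters=tuple(c["conv_filters"]),
        latent_dense=tuple(c["latent_dense"]),
        weight_head=tuple(c["weight_head"]),
        output_head=tuple(c["output_head"]),
        crop_size=c["crop_size"],
        train_sequence_length=c["train_sequence_length"],
    )
    model = build_wacnet(config, seed=0)
    model.load_state(state)
    codec = WacCodec(**meta["codec"])
    return model, codec, meta
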