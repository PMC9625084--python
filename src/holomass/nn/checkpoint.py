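"""Single-file checkpoints: weights + config + provenance in one .npz."""

from __future__ import annotations

import json

import numpy as np

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path, state: dict[str, np.ndarray], meta: dict) -> None:
    """Write a flat weight dict and a JSON-serializable metadata dict.

    ``meta`` must carry everything needed to rebuild the model: the network
    config, the encode/decode constants, and training provenance (seed,
    epochs, data parameters).
    """
    payload = {f"w:{k}": v for k, v in state.items()}
    payload["meta"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"].tobytes()).decode())
        state = {k[2:]: f[k] for k in f.files if k.startswith("w:")}
    return state, meta
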