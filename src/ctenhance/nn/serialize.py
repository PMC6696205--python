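"""Single-file checkpoints: model weights + JSON config in one .npz."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1


def save_checkpoint(path, module, config: dict, extra: dict | None = None) -> None:
    """Serialize module weights plus a JSON-encodable config dict."""
    meta = {
        "version": FORMAT_VERSION,
        "config": config,
        "extra": extra or {},
    }
    arrays = {f"state/{k}": v for k, v in module.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(str(path), **arrays)


def load_checkpoint(path):
    """Return (state_dict, config, extra). Raises FileNotFoundError if absent."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(str(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if meta.get("version") != FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        state = {
            k[len("state/"):]: npz[k] for k in npz.files if k.startswith("state/")
        }
    return state, meta["config"], meta["extra"]
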