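"""Checkpoints: network weights as .npz plus a JSON metadata sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def save_checkpoint(path, module, meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = module.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    (path.with_suffix(".json")).write_text(json.dumps(meta or {}, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path, module) -> dict:
    path = Path(path)
    npz = np.load(path.with_suffix(".npz"))
    module.load_state_dict({k: npz[k] for k in npz.files})
    meta_path = path.with_suffix(".json")
    return json.loads(meta_path.read_text()) if meta_path.exists() else {}


def read_checkpoint_meta(path) -> dict:
    return json.loads(Path(path).with_suffix(".json").read_text())
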