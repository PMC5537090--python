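"""Model checkpoint container: topology metadata + parameter tensors.

Checkpoints are ``.npz`` archives holding a JSON metadata record (topology
id, input size, training configuration) plus one array per parameter.  Both
network stages (detector and classifier) use the same container.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigError

_META_KEY = "__meta__"
_PARAM_PREFIX = "param::"


def save_checkpoint(path, meta: dict, state: dict[str, np.ndarray]) -> None:
    arrays = {_PARAM_PREFIX + k: v for k, v in state.items()}
    with open(Path(path), "wb") as fh:
        np.savez(fh, **{_META_KEY: np.array(json.dumps(meta))}, **arrays)


def load_checkpoint(path) -> tuple[dict, dict[str, np.ndarray]]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"model checkpoint not found: {path}")
    with np.load(path, allow_pickle=False) as npz:
        if _META_KEY not in npz:
            raise ConfigError(f"{path} is not an autobaa checkpoint")
        meta = json.loads(str(npz[_META_KEY]))
        state = {
            k[len(_PARAM_PREFIX):]: npz[k]
            for k in npz.files
            if k.startswith(_PARAM_PREFIX)
        }
    return meta, state
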