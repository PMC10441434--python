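"""File formats: TIFF stacks, delimited tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_tiles_tiff(path: str | Path, tiles: list[np.ndarray],
                     mode: str = "float32") -> None:
    """Write tiles as a multi-page TIFF (raw uint16 counts or float32)."""
    stack = np.asarray(tiles)
    if mode == "uint16":
        stack = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    elif mode == "float32":
        stack = stack.astype(np.float32)
    else:
        raise ValueError("mode must be 'uint16' or 'float32'")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_tiles_tiff(path: str | Path) -> list[np.ndarray]:
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        return [stack]
    return [stack[i] for i in range(stack.shape[0])]


def write_table(path: str | Path, df: pd.DataFrame, config_hash: str = "") -> None:
    """CSV with an optional config-hash provenance column."""
    out = df.copy()
    if config_hash:
        out["config_hash"] = config_hash
    out.to_csv(path, index=False)


def write_sidecar(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
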