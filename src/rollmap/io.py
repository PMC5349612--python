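"""File round-tripping: TIFF movies/tiles, CSV tables, YAML configs, JSON truth."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml


def write_movie(path: str | Path, movie: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def read_movie(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_tiles(path: str | Path, tiles: list[np.ndarray]) -> None:
    tifffile.imwrite(str(path), np.stack(tiles).astype(np.float32))


def read_tiles(path: str | Path) -> list[np.ndarray]:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return [a for a in arr]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping, embedded in every output."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def dump_json(path: str | Path, obj: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
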