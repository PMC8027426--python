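"""TIFF stack I/O, config loading, and provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "read_stack",
    "write_stack",
    "write_image",
    "read_config",
    "write_sidecar",
    "config_hash",
]


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF into an (n_frames, h, w) array, dtype preserved."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted format errors
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages forming a stack, got shape {arr.shape}")
    return arr


def _check_writable(data: np.ndarray, dtype: str) -> np.ndarray:
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values cannot be written")
    if dtype == "uint16":
        if np.any(data < 0):
            raise ValueError(
                "negative values cannot be written as uint16; use dtype='float32'"
            )
        return np.round(data).astype(np.uint16)
    if dtype == "float32":
        return data.astype(np.float32)
    raise ValueError(f"unsupported dtype {dtype!r}; use 'uint16' or 'float32'")


def write_stack(stack: np.ndarray, path, dtype: str = "float32", sidecar: dict | None = None) -> None:
    """Write an image stack as a multi-page TIFF with an optional JSON sidecar."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D")
    tifffile.imwrite(Path(path), _check_writable(stack, dtype), photometric="minisblack")
    if sidecar is not None:
        write_sidecar(path, sidecar)


def write_image(image: np.ndarray, path, dtype: str = "float32", sidecar: dict | None = None) -> None:
    """Write a single 2-D image as TIFF with an optional JSON sidecar."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    tifffile.imwrite(Path(path), _check_writable(image, dtype), photometric="minisblack")
    if sidecar is not None:
        write_sidecar(path, sidecar)


def write_sidecar(data_path, payload: dict) -> Path:
    """Write provenance JSON next to a data file (``<name>.json``)."""
    p = Path(data_path).with_suffix(Path(data_path).suffix + ".json")
    p.write_text(json.dumps(payload, indent=2, default=str))
    return p


def read_config(path) -> dict:
    """Load a JSON or YAML configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
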