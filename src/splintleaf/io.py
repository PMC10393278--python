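"""File I/O: images and masks (PNG), manifests and measurements (CSV),
reports (JSON), configuration (YAML), and model checkpoints (npz)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .nn.unet import SegModelConfig, UNet, build_model

CHECKPOINT_FORMAT_VERSION = 1


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(Path(path))


def read_image(path) -> np.ndarray:
    arr = np.asarray(Image.open(Path(path)).convert("RGB"))
    return arr


def write_mask(path, mask: np.ndarray) -> None:
    """Masks are stored as single-channel PNG, 255 = leaf, 0 = background."""
    m = (np.asarray(mask) != 0).astype(np.uint8) * 255
    Image.fromarray(m, mode="L").save(Path(path))


def read_mask(path) -> np.ndarray:
    m = np.asarray(Image.open(Path(path)).convert("L"))
    return (m >= 128).astype(np.uint8)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_checkpoint(path, model: UNet) -> None:
    """Checkpoints carry a format version and the full architecture config,
    so evaluation can never silently mismatch the network shape."""
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION,
            "config": model.config.to_dict()}
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(Path(path), meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> UNet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta.get('format_version')!r}")
        config = SegModelConfig.from_dict(meta["config"])
        model = build_model(config, seed=0)
        keys = sorted(k for k in z.files if k.startswith("param_"))
        model.load_state_arrays([z[k] for k in keys])
    return model
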