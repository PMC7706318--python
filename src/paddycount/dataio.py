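"""Readers and writers: annotations, images, map archives, run configuration."""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np

from .codec import DotAnnotation

__all__ = [
    "load_annotations",
    "save_annotations",
    "load_image",
    "save_map_archive",
    "load_map_archive",
    "load_config",
    "derive_seed",
    "DEFAULT_CONFIG",
]

# paper-default codec and model settings; a YAML config overrides these
DEFAULT_CONFIG = {
    "codec": {"sigma": 4.0, "s": 0.1, "q": -2.0, "block": 32, "stride": 8},
    "model": {"backbone": "tiny", "n_layers": 3},
    "train": {
        "downsample_ratio": 0.25,
        "crop": 384,
        "batch": 8,
        "lr0": 1e-2,
        "lr_decay_factor": 10,
        "lr_decay_every": 200,
        "epochs": 600,
        "momentum": 0.9,
        "weight_decay": 1e-4,
        "mode": "classification",
    },
    "eval": {"r2_definition": "pearson"},
    "seed": 0,
}


def load_annotations(path: str | Path) -> dict[str, DotAnnotation]:
    """Load dot annotations from the CSV (``image,x,y``) or JSON dialect.

    Duplicate rows are kept — a point annotated twice contributes
    multiplicity 2, matching the rasterizer's accumulation rule.
    """
    path = Path(path)
    out: dict[str, DotAnnotation] = {}
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        for image_id, pts in data.items():
            out[image_id] = DotAnnotation(image_id, [(float(x), float(y)) for x, y in pts])
        return out
    with open(path, newline="") as fh:
        header = fh.readline().strip().split(",")
        if [h.strip().lower() for h in header] != ["image", "x", "y"]:
            raise ValueError(f"unknown annotation header {header!r}; expected image,x,y")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            image_id, xs, ys = parts
            try:
                x, y = float(xs), float(ys)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from exc
            out.setdefault(image_id, DotAnnotation(image_id)).points.append((x, y))
    return out


def save_annotations(annotations: dict[str, DotAnnotation], path: str | Path):
    with open(path, "w") as fh:
        fh.write("image,x,y\n")
        for image_id, ann in annotations.items():
            for x, y in ann.points:
                fh.write(f"{image_id},{x!r},{y!r}\n")


def load_image(path: str | Path) -> np.ndarray:
    """PNG/JPEG -> HWC float32 in [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0


def save_map_archive(path: str | Path, metadata: dict, **arrays):
    """Compressed array archive with a JSON metadata block.

    Metadata carries the codec parameters (block, stride, s, q, c_max, sigma)
    so a saved map is interpretable on its own.
    """
    meta = np.frombuffer(json.dumps(metadata).encode(), dtype=np.uint8)
    np.savez_compressed(path, __metadata__=meta, **arrays)


def load_map_archive(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__metadata__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__metadata__"}
    return meta, arrays


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise KeyError(f"unknown config key '{path}{k}'")
        if isinstance(base[k], dict):
            if not isinstance(v, dict):
                raise ValueError(f"config key '{path}{k}' must be a mapping")
            out[k] = _merge(base[k], v, f"{path}{k}.")
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merged run configuration: defaults < YAML file < explicit overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        import yaml

        loaded = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, loaded)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def derive_seed(master: int, label: str) -> int:
    """Named substream seed (< 2^31) from a top-level seed.

    Each stochastic component (scene generation, weight init, cropping) gets
    its own labeled stream so components can be re-seeded independently.
    """
    ss = np.random.SeedSequence([int(master), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
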