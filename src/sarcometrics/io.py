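"""File-format plumbing: multi-channel TIFF bundles, CSV tables, JSON
sidecars with generation parameters."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import IntensityProfile

__all__ = [
    "write_image_bundle",
    "read_image_bundle",
    "write_profiles_csv",
    "read_profiles_csv",
    "params_to_jsonable",
    "config_hash",
]


def params_to_jsonable(obj):
    """Recursively convert dataclasses/arrays into JSON-serialisable data."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: params_to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): params_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [params_to_jsonable(v) for v in obj]
    return obj


def config_hash(params) -> str:
    """Stable sha256 of a JSON-serialisable parameter structure."""
    blob = json.dumps(params_to_jsonable(params), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_image_bundle(prefix: str | Path, image: np.ndarray,
                       channels: list[str], truth: pd.DataFrame | None,
                       params: dict) -> dict[str, Path]:
    """Write a simulated image as TIFF (one page per channel) plus the
    ground-truth CSV and a JSON sidecar echoing all generation parameters."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"tiff": prefix.with_suffix(".tif"),
             "sidecar": prefix.with_suffix(".json")}
    tifffile.imwrite(paths["tiff"], np.asarray(image, dtype=np.float32),
                     metadata={"axes": "CYX", "channels": channels})
    sidecar = {"channels": channels, "params": params_to_jsonable(params),
               "config_hash": config_hash(params)}
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    if truth is not None:
        paths["truth"] = prefix.parent / (prefix.name + "_truth.csv")
        truth.to_csv(paths["truth"], index=False)
    return paths


def read_image_bundle(prefix: str | Path) -> tuple[np.ndarray, list[str], dict]:
    prefix = Path(prefix)
    image = tifffile.imread(prefix.with_suffix(".tif"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return np.asarray(image), list(sidecar["channels"]), sidecar


def write_profiles_csv(path: str | Path,
                       profiles: dict[str, IntensityProfile]) -> Path:
    """Tidy long-format profile table: channel, position_um, intensity."""
    frames = []
    for channel, prof in profiles.items():
        frame = prof.to_frame()
        frame.insert(0, "channel", channel)
        frames.append(frame)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_profiles_csv(path: str | Path) -> dict[str, IntensityProfile]:
    table = pd.read_csv(path)
    return {str(ch): IntensityProfile.from_frame(sub, str(ch))
            for ch, sub in table.groupby("channel", sort=False)}
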