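"""File IO: multi-page TIFF scene stacks with JSON ground-truth sidecars.

Event tables, plates, and fiber tables are plain CSV handled directly with
pandas; this module covers the image-side formats: a rendered scene is
stored as a multi-page TIFF (one page per channel, in
:data:`repstress.simulate.CHANNELS` order) with an optional ``.truth.json``
sidecar holding the :class:`~repstress.simulate.SceneTruth`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulate import CHANNELS, SceneTruth

__all__ = ["write_scene", "read_scene", "read_channel_map"]


def write_scene(
    path: str | Path, stack: np.ndarray, truth: SceneTruth | None = None
) -> None:
    """Write a (channels, H, W) stack as multi-page TIFF, plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    if truth is not None:
        path.with_suffix(path.suffix + ".truth.json").write_text(truth.to_json())


def read_scene(path: str | Path) -> tuple[np.ndarray, SceneTruth | None]:
    """Read a scene stack and its ground-truth sidecar if present."""
    path = Path(path)
    stack = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    truth = SceneTruth.from_json(sidecar.read_text()) if sidecar.exists() else None
    return stack, truth


def read_channel_map(path: str | Path) -> tuple[str, ...]:
    """Read a YAML channel map (``channels: [dapi, edu, 53bp1, patm]``)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    channels = tuple(str(c) for c in cfg.get("channels", CHANNELS))
    missing = set(CHANNELS) - set(channels)
    if missing:
        raise ValueError(f"channel map lacks required channels: {sorted(missing)}")
    return channels
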