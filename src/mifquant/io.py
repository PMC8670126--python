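"""Reading and writing FOV images, masks and tabular artifacts.

FOVs are stored as multipage grayscale TIFFs (one page per channel) with a
JSON sidecar carrying channel names, per-channel exposure times, bit depth
and the staining-round grouping.  Masks are single-page 8-bit TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .masks import Mask
from .synthetic import FOVImage

__all__ = [
    "write_fov",
    "read_fov",
    "write_mask",
    "read_mask",
    "iter_fov_paths",
]


def write_fov(fov: FOVImage, directory: str | Path) -> Path:
    """Write one FOV as ``<fov_id>.tif`` plus ``<fov_id>.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{fov.fov_id}.tif"
    channels = list(fov.channels)
    stack = np.stack([fov.channels[c] for c in channels])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "section_id": fov.section_id,
        "fov_id": fov.fov_id,
        "channels": channels,
        "exposure_ms": fov.exposure_ms,
        "bit_depth": fov.bit_depth,
        "rounds": [list(r) for r in fov.rounds],
    }
    (directory / f"{fov.fov_id}.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_fov(tiff_path: str | Path) -> FOVImage:
    """Read a FOV written by :func:`write_fov` (TIFF + JSON sidecar)."""
    tiff_path = Path(tiff_path)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = dict(zip(sidecar["channels"], stack))
    return FOVImage(
        section_id=sidecar["section_id"],
        fov_id=sidecar["fov_id"],
        channels=channels,
        exposure_ms={k: float(v) for k, v in sidecar["exposure_ms"].items()},
        bit_depth=int(sidecar["bit_depth"]),
        rounds=tuple(tuple(r) for r in sidecar.get("rounds", [])),
    )


def write_mask(mask: Mask, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{mask.fov_id}_{mask.label}.tif"
    tifffile.imwrite(path, mask.pixels.astype(np.uint8) * 255)
    return path


def read_mask(path: str | Path, label: str = "", fov_id: str = "") -> Mask:
    arr = tifffile.imread(path)
    return Mask(arr > 0, label=label, fov_id=fov_id)


def iter_fov_paths(directory: str | Path):
    """Yield every FOV TIFF under ``directory`` (recursive, sorted)."""
    yield from sorted(Path(directory).rglob("*.tif"))
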