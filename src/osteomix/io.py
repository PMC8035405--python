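"""TIFF / CSV / YAML I/O with sidecar calibration.

Rasters travel as multi-page TIFF (page order: channel-major, then z or t);
physical calibration goes in a JSON sidecar next to the TIFF, since plain
TIFF has no reliable slot for anisotropic µm voxel sizes. Truth and result
tables are CSV; episode scripts are YAML or JSON lists of
``{blue_id, red_id, start, end}`` mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .containers import ConfigurationError, DataError, TimeLapse, TwoChannelImage, TwoChannelVolume
from .synthetic import ContactEpisode


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: TwoChannelImage, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.stack([image.cyan, image.red]).astype(np.float32))
    _sidecar(path).write_text(
        json.dumps({"kind": "image", "pixel_size_um": image.pixel_size_um})
    )


def read_image(path: str | Path) -> TwoChannelImage:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 3 or data.shape[0] != 2:
        raise DataError(f"{path}: expected 2 channel pages, got shape {data.shape}")
    meta = _read_meta(path, "image")
    return TwoChannelImage(data[0], data[1], pixel_size_um=meta.get("pixel_size_um", 1.0))


def write_volume(volume: TwoChannelVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.stack([volume.cyan, volume.red]).astype(np.float32))
    _sidecar(path).write_text(
        json.dumps({"kind": "volume", "voxel_size_um": list(volume.voxel_size_um)})
    )


def read_volume(path: str | Path) -> TwoChannelVolume:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 4 or data.shape[0] != 2:
        raise DataError(f"{path}: expected (2, z, y, x) pages, got shape {data.shape}")
    meta = _read_meta(path, "volume")
    return TwoChannelVolume(
        data[0], data[1], voxel_size_um=tuple(meta.get("voxel_size_um", (5.0, 1.0, 1.0)))
    )


def write_timelapse(timelapse: TimeLapse, path: str | Path) -> None:
    path = Path(path)
    stack = np.stack(
        [np.stack([f.cyan, f.red]) for f in timelapse.frames]
    )  # (t, 2, h, w)
    tifffile.imwrite(path, stack.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {
                "kind": "timelapse",
                "pixel_size_um": timelapse.pixel_size_um,
                "frame_interval_min": timelapse.frame_interval_min,
            }
        )
    )


def read_timelapse(path: str | Path) -> TimeLapse:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 4 or data.shape[1] != 2:
        raise DataError(f"{path}: expected (t, 2, h, w) pages, got shape {data.shape}")
    meta = _read_meta(path, "timelapse")
    px = meta.get("pixel_size_um", 1.0)
    frames = [TwoChannelImage(fr[0], fr[1], pixel_size_um=px) for fr in data]
    return TimeLapse(frames=frames, frame_interval_min=meta.get("frame_interval_min", 8.0))


def _read_meta(path: Path, kind: str) -> dict:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        return {}
    meta = json.loads(sidecar.read_text())
    if meta.get("kind") not in (None, kind):
        raise DataError(f"{sidecar}: calibration is for a {meta.get('kind')}, not a {kind}")
    return meta


def read_episode_script(path: str | Path) -> list[ContactEpisode]:
    """Episode script from YAML or JSON: a list of
    ``{blue_id, red_id, start, end}`` mappings."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, list):
        raise ConfigurationError(f"{path}: episode script must be a list")
    episodes = []
    for i, item in enumerate(raw):
        try:
            episodes.append(
                ContactEpisode(
                    blue_id=int(item["blue_id"]),
                    red_id=int(item["red_id"]),
                    start=int(item["start"]),
                    end=int(item["end"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(
                f"{path}: episode {i} must map blue_id/red_id/start/end"
            ) from exc
    return episodes
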