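"""Volume container I/O and image export.

Volumes travel as a zarr group (chunked-array store) holding named channels
on one grid, with a JSON metadata sidecar (``metadata.json`` inside the
store directory) recording spacings, noise variance, thresholds, software
version, phantom spec hash and seed.  Round trips are lossless: channels
are reproduced bit-exactly and metadata verbatim.

Image export writes per-B-scan 8/16-bit grayscale PNGs plus a sidecar
recording the value→gray mapping (vmin/vmax per channel), so the
quantized export can be mapped back to values within one quantization step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import zarr

__all__ = ["VolumeContainer", "write_volume", "read_volume", "export_images"]

_METADATA_FILE = "metadata.json"


@dataclass
class VolumeContainer:
    """Named channels on one grid plus a metadata record."""

    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        grids = {k: v.shape[-3:] for k, v in self.channels.items()}
        if len(set(grids.values())) > 1:
            raise ValueError(f"channel grids are not congruent: {grids}")

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(
                f"container is missing required channel(s): {missing}; "
                f"present: {sorted(self.channels)}"
            )

    @property
    def grid(self) -> tuple[int, int, int]:
        any_ch = next(iter(self.channels.values()))
        return any_ch.shape[-3:]


def write_volume(container: VolumeContainer, path) -> None:
    """Write a container to a zarr store with a JSON metadata sidecar."""
    path = Path(path)
    group = zarr.open_group(str(path), mode="w")
    for name, arr in container.channels.items():
        group.create_array(name, data=np.ascontiguousarray(arr))
    group.attrs["channel_names"] = sorted(container.channels)
    (path / _METADATA_FILE).write_text(
        json.dumps(container.metadata, indent=2, sort_keys=True, default=str)
    )


def read_volume(path) -> VolumeContainer:
    """Read a container back; rejects stores with missing metadata or channels."""
    path = Path(path)
    meta_path = path / _METADATA_FILE
    if not meta_path.exists():
        raise FileNotFoundError(
            f"{path}: metadata sidecar '{_METADATA_FILE}' is missing; "
            "supply spacings and acquisition metadata"
        )
    metadata = json.loads(meta_path.read_text())
    if "dx" not in metadata or "dy" not in metadata or "dz" not in metadata:
        raise ValueError(
            f"{path}: metadata lacks pixel spacings (dx, dy, dz in mm); "
            "supply spacings to interpret the volume"
        )
    group = zarr.open_group(str(path), mode="r")
    declared = group.attrs.get("channel_names")
    if declared is None:
        raise ValueError(f"{path}: store lacks the channel manifest")
    channels = {}
    for name in declared:
        if name not in group:
            raise ValueError(f"{path}: declared channel {name!r} is missing")
        channels[name] = group[name][:]
    return VolumeContainer(channels=channels, metadata=metadata)


def export_images(
    container: VolumeContainer,
    what: str,
    path,
    *,
    bit_depth: int = 16,
    vmin: float | None = None,
    vmax: float | None = None,
) -> list[Path]:
    """Export one channel as per-B-scan grayscale images plus a mapping sidecar.

    3-D channels produce one image per B-scan; 2-D channels (en face maps)
    a single image.  Values are linearly mapped from [vmin, vmax] (channel
    min/max by default) to the integer gray range.
    """
    if what not in container.channels:
        raise KeyError(
            f"unknown channel {what!r}; present: {sorted(container.channels)}"
        )
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    arr = np.asarray(container.channels[what], dtype=np.float64)
    arr = np.nan_to_num(arr, nan=0.0, posinf=0.0, neginf=0.0)
    lo = float(arr.min()) if vmin is None else vmin
    hi = float(arr.max()) if vmax is None else vmax
    if hi <= lo:
        hi = lo + 1.0
    gmax = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    scaled = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    gray = np.round(scaled * gmax).astype(dtype)

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if gray.ndim == 2:
        f = outdir / f"{what}.png"
        iio.imwrite(f, gray)
        written.append(f)
    else:
        for b in range(gray.shape[0]):
            f = outdir / f"{what}_b{b:04d}.png"
            iio.imwrite(f, gray[b])
            written.append(f)
    sidecar = outdir / f"{what}_mapping.json"
    sidecar.write_text(
        json.dumps(
            {"channel": what, "vmin": lo, "vmax": hi, "gray_max": gmax, "bit_depth": bit_depth},
            indent=2,
        )
    )
    written.append(sidecar)
    return written
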