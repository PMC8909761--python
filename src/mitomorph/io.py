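"""Reading and writing the standard on-disk formats.

2D scenes go to plain TIFF (intensity + nucleus/cell masks), 4D series to
OME-TIFF with PhysicalSizeX/Y/Z voxel metadata, tables to CSV and
configuration/provenance to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .scene import CellScene2D, VolumeSeries


def write_scene_2d(scene: CellScene2D, path: str | Path) -> None:
    """Write intensity + masks as <stem>.tif / <stem>_nucleus.tif / <stem>_cell.tif."""
    path = Path(path)
    tifffile.imwrite(path, scene.intensity.astype(np.float32))
    tifffile.imwrite(
        path.with_name(path.stem + "_nucleus.tif"),
        scene.nucleus_mask.astype(np.uint8),
    )
    tifffile.imwrite(
        path.with_name(path.stem + "_cell.tif"), scene.cell_mask.astype(np.uint8)
    )


def read_scene_2d(path: str | Path, pixel_size: float = 1.0) -> CellScene2D:
    path = Path(path)
    intensity = tifffile.imread(path)
    nucleus = tifffile.imread(path.with_name(path.stem + "_nucleus.tif")) > 0
    cell = tifffile.imread(path.with_name(path.stem + "_cell.tif")) > 0
    return CellScene2D(
        intensity=intensity, nucleus_mask=nucleus, cell_mask=cell, pixel_size=pixel_size
    )


def write_volume_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a (t, c, z, y, x) OME-TIFF with physical voxel sizes in µm."""
    names = list(series.channels)
    stack = np.stack([series.channels[n] for n in names], axis=1)  # t,c,z,y,x
    vz, vy, vx = series.voxel_size
    tifffile.imwrite(
        Path(path),
        stack.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TCZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "TimeIncrement": series.frame_interval,
            "TimeIncrementUnit": "s",
            "Channel": {"Name": names},
        },
    )


def read_volume_series(path: str | Path,
                       channel_names: list[str] | None = None) -> VolumeSeries:
    """Read an OME-TIFF written by :func:`write_volume_series`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tf.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        vz = float(px.get("PhysicalSizeZ", 1.0))
        vy = float(px.get("PhysicalSizeY", 1.0))
        vx = float(px.get("PhysicalSizeX", 1.0))
        dt = float(px.get("TimeIncrement", 1.0))
        names = [
            ch.get("Name") or f"ch{i}"
            for i, ch in enumerate(root.findall(".//ome:Channel", ns))
        ]
    if arr.ndim == 4:  # single channel squeezed
        arr = arr[:, None]
    if channel_names is not None:
        names = channel_names
    if len(names) != arr.shape[1]:
        names = [f"ch{i}" for i in range(arr.shape[1])]
    channels = {n: arr[:, i].astype(float) for i, n in enumerate(names)}
    return VolumeSeries(channels=channels, voxel_size=(vz, vy, vx), frame_interval=dt)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def write_csv(df, path: str | Path, float_format: str = "%.6g") -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    df.to_csv(Path(path), index=False, float_format=float_format)
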