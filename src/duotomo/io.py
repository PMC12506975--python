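"""File interfaces: HDF5 channel data, TIFF images with JSON sidecars,
JSON geometry tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import build_grid
from .pact_recon import ReconImage
from .phantom_forward import ChannelData

__all__ = [
    "save_channel_data", "load_channel_data",
    "save_recon_image", "load_recon_image",
    "save_geometry_json",
]


def save_channel_data(path: str | Path, cd: ChannelData) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("samples", data=cd.samples)
        ds.attrs["fs_MHz"] = cd.fs_MHz
        ds.attrs["c_mm_per_us"] = cd.c_mm_per_us
        ds.attrs["t0_us"] = cd.t0_us
        ds.attrs["modality"] = cd.modality
        ds.attrs["emitter_index"] = -1 if cd.emitter_index is None else cd.emitter_index
        ds.attrs["geometry_id"] = cd.geometry_id


def load_channel_data(path: str | Path) -> ChannelData:
    with h5py.File(path, "r") as f:
        ds = f["samples"]
        emitter = int(ds.attrs["emitter_index"])
        return ChannelData(
            samples=ds[...],
            fs_MHz=float(ds.attrs["fs_MHz"]),
            c_mm_per_us=float(ds.attrs["c_mm_per_us"]),
            t0_us=float(ds.attrs["t0_us"]),
            modality=str(ds.attrs["modality"]),
            emitter_index=None if emitter < 0 else emitter,
            geometry_id=str(ds.attrs["geometry_id"]),
        )


def save_recon_image(path: str | Path, img: ReconImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    sidecar = {
        "variant": img.variant,
        "provenance": img.provenance,
        "grid": {
            "width_mm": img.grid.width_mm, "depth_mm": img.grid.depth_mm,
            "pitch_mm": img.grid.pitch_mm, "center_xy": list(img.grid.center_xy),
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_recon_image(path: str | Path) -> ReconImage:
    path = Path(path)
    pixels = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    g = meta["grid"]
    grid = build_grid(g["width_mm"], g["depth_mm"], g["pitch_mm"],
                      tuple(g["center_xy"]))
    return ReconImage(pixels=pixels, grid=grid, variant=meta["variant"],
                      provenance=meta.get("provenance", {}))


def save_geometry_json(path: str | Path, geom) -> None:
    Path(path).write_text(json.dumps(geom.to_dict(), indent=2))
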