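"""File I/O: TIFF movies, label maps, CSV tables, carpets, configs.

TIFF is the only image format (acquisitions are exported as TIFF); tables
are CSV with documented headers; FRAP carpets are CSV matrices with a JSON
geometry sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from locreset.frap import FRAPCarpet
from locreset.synthetic import Movie

__all__ = [
    "write_movie",
    "read_movie",
    "write_labels",
    "read_labels",
    "write_table",
    "write_carpet",
    "read_carpet",
]


def write_movie(path: str | Path, movie: Movie) -> None:
    """Write a (T, C, Z, Y, X) movie as an interleaved multi-page TIFF.

    Channel names, pixel size and frame interval go into the TIFF
    description as JSON so :func:`read_movie` can round-trip them.
    """
    meta = {
        "channels": list(movie.channels),
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval": movie.frame_interval,
        "axes": "TCZYX",
    }
    tifffile.imwrite(str(path), movie.data.astype(np.float32),
                     description=json.dumps(meta))


def read_movie(path: str | Path) -> Movie:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    data = data.reshape((-1, len(meta["channels"])) + data.shape[-3:])
    return Movie(data=np.asarray(data, dtype=float),
                 channels=tuple(meta["channels"]),
                 pixel_size_um=float(meta["pixel_size_um"]),
                 frame_interval=float(meta["frame_interval"]))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """16-bit label TIFF (raises if more than 65535 labels)."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit output")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_carpet(path: str | Path, carpet: FRAPCarpet) -> None:
    """CSV matrix (rows = radial positions, columns = times) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(carpet.values, index=carpet.positions_um,
                      columns=carpet.times_s)
    df.to_csv(path, index_label="position_um")
    sidecar = {
        "bleach_radius_um": carpet.bleach_radius_um,
        "center_px": carpet.center_px,
        "metadata": carpet.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_carpet(path: str | Path) -> FRAPCarpet:
    path = Path(path)
    df = pd.read_csv(path, index_col="position_um")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return FRAPCarpet(
        values=df.to_numpy(),
        positions_um=df.index.to_numpy(dtype=float),
        times_s=df.columns.to_numpy(dtype=float),
        bleach_radius_um=sidecar["bleach_radius_um"],
        center_px=sidecar.get("center_px"),
        metadata=sidecar.get("metadata", {}),
    )
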