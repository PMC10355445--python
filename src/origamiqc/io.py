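"""File I/O: height maps as float TIFF, class maps as paletted PNG, tables as CSV.

Height maps are written as single-channel 32-bit float TIFFs with the
physical pixel size embedded as JSON in the ImageDescription tag, so a map
round-trips with its calibration. Plain-text matrix export is also accepted
on read for interoperability with AFM software text dumps.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .census import Particle, particles_to_frame
from .gradient import GradientProfile
from .mixture import HeightMap

__all__ = [
    "write_height_map",
    "read_height_map",
    "write_class_map",
    "read_class_map",
    "write_length_sample",
    "read_length_sample",
    "write_profiles",
    "read_profiles",
    "write_particles",
]

# palette: mica near-black, staple red, origami green
_CLASS_PALETTE = [0, 0, 32, 220, 50, 50, 60, 200, 90]


def write_height_map(path, hm: HeightMap) -> None:
    """Write a height map as a 32-bit float TIFF with nm calibration metadata."""
    desc = json.dumps({"nm_per_pixel": hm.nm_per_pixel, "units": "nm"})
    tifffile.imwrite(str(path), hm.heights.astype(np.float32), description=desc)


def read_height_map(path, nm_per_pixel: float | None = None) -> HeightMap:
    """Read a height map from TIFF (calibration from metadata) or a text matrix.

    ``nm_per_pixel`` overrides/provides the calibration; it is required for
    text matrices without metadata.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(str(path)) as tf:
            heights = tf.asarray().astype(float)
            if nm_per_pixel is None:
                desc = tf.pages[0].tags.get("ImageDescription")
                if desc is not None:
                    try:
                        nm_per_pixel = json.loads(desc.value).get("nm_per_pixel")
                    except (json.JSONDecodeError, AttributeError):
                        nm_per_pixel = None
    else:
        heights = np.loadtxt(str(path))
    if nm_per_pixel is None:
        raise ValueError("nm_per_pixel not found in metadata; pass it explicitly")
    return HeightMap(heights=heights, nm_per_pixel=float(nm_per_pixel))


def write_class_map(path, class_map: np.ndarray) -> None:
    """Write a ground-truth class map as an 8-bit paletted PNG (0=mica, 1=staple, 2=origami)."""
    img = Image.fromarray(class_map.astype(np.uint8), mode="P")
    img.putpalette(_CLASS_PALETTE)
    img.save(str(path))


def read_class_map(path) -> np.ndarray:
    return np.asarray(Image.open(str(path)), dtype=np.uint8)


def write_length_sample(path, sample: Sequence[tuple[float, str]]) -> None:
    pd.DataFrame(sample, columns=["length_nm", "label"]).to_csv(path, index=False)


def read_length_sample(path) -> list[tuple[float, str]]:
    df = pd.read_csv(path)
    return list(zip(df["length_nm"].astype(float), df["label"].astype(str)))


def write_profiles(path, profiles: Sequence[GradientProfile]) -> None:
    """Write gradient profiles as long-form CSV (depth, intensity, replicate)."""
    frames = [pd.DataFrame({"depth": p.depth, "intensity": p.intensity,
                            "replicate": i}) for i, p in enumerate(profiles)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles(path) -> list[GradientProfile]:
    df = pd.read_csv(path)
    profiles = []
    for _, grp in df.groupby("replicate", sort=True):
        profiles.append(GradientProfile(depth=grp["depth"].to_numpy(),
                                        intensity=grp["intensity"].to_numpy()))
    return profiles


def write_particles(path, particles: Sequence[Particle]) -> None:
    particles_to_frame(particles).to_csv(path, index=False)
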