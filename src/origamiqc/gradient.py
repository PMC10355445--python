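"""Gradient-tube densitometry: profile extraction, shape classification, QC.

A density gradient formed by rapid mixing should be reproducible from tube
to tube and close to linear in dye intensity versus depth. This module
extracts a depth-intensity trace from a photograph of a tube (per-row mean
over a region of interest, depth 0 = meniscus at the top), classifies the
trace as a step, a smooth gradient, or a uniform (fully mixed) solution,
and scores reproducibility across replicate tubes as the per-replicate mean
absolute deviation from the pointwise mean profile, in percent of the
normalized intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GradientProfile",
    "ReproReport",
    "extract_profile",
    "classify_profile",
    "mean_absolute_deviation",
]


@dataclass
class GradientProfile:
    """Normalized depth-vs-intensity trace of one gradient tube.

    ``depth`` is strictly increasing over [0, 1], top-to-bottom.
    ``raw_range`` is the pre-normalization intensity span on a [0, 1] scale
    (for an 8-bit photo, span/255); it drives the uniform test in
    :func:`classify_profile`. A constant trace is returned un-normalized
    with ``is_constant`` set.
    """

    depth: np.ndarray
    intensity: np.ndarray
    raw_range: Optional[float] = None
    is_constant: bool = False

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.depth.shape != self.intensity.shape:
            raise ValueError("depth and intensity must have equal length")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth must be strictly increasing")


@dataclass
class ReproReport:
    """Cross-replicate reproducibility of gradient profiles.

    ``per_replicate_mad`` is, for each tube, the mean over depth of the
    absolute difference from the pointwise mean profile, in % of the
    normalized intensity range; ``mean_mad``/``sd_mad`` summarise it.
    """

    per_replicate_mad: list[float]
    n_replicates: int
    mean_mad: float = field(init=False)
    sd_mad: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        mads = np.asarray(self.per_replicate_mad, dtype=float)
        self.mean_mad = float(mads.mean())
        self.sd_mad = float(mads.std(ddof=1))


def extract_profile(image: np.ndarray, roi: tuple[int, int, int, int] | None = None
                    ) -> GradientProfile:
    """Depth-intensity profile of a tube photograph.

    Parameters
    ----------
    image : 2-D grayscale array (any numeric dtype; 8/16-bit photos or floats).
    roi : (row, col, height, width) rectangle; defaults to the whole image.

    The per-row mean intensity over the ROI is mapped to depth [0, 1]
    top-to-bottom and min-max normalized. Integer images are referenced to
    their dtype range when recording ``raw_range``; a constant ROI yields a
    flagged, un-normalized profile.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if roi is None:
        roi = (0, 0, image.shape[0], image.shape[1])
    r, c, h, w = roi
    if w < 1 or h < 1 or r < 0 or c < 0 or r + h > image.shape[0] or c + w > image.shape[1]:
        raise ValueError("roi must lie within the image and have width >= 1")
    block = image[r:r + h, c:c + w].astype(float)
    trace = block.mean(axis=1)
    depth = np.linspace(0.0, 1.0, h)
    if np.issubdtype(image.dtype, np.integer):
        full_scale = float(np.iinfo(image.dtype).max)
    else:
        full_scale = 1.0
    span = float(trace.max() - trace.min())
    raw_range = span / full_scale
    if span == 0:
        return GradientProfile(depth=depth, intensity=trace, raw_range=0.0,
                               is_constant=True)
    intensity = (trace - trace.min()) / span
    return GradientProfile(depth=depth, intensity=intensity, raw_range=raw_range)


def classify_profile(p: GradientProfile, step_score_threshold: float = 0.5,
                     flatness_threshold: float = 0.05) -> str:
    """Classify a profile as "step", "smooth" or "uniform".

    Uniform: the raw (pre-normalization) intensity span is below
    ``flatness_threshold`` (default 5% of full scale) — the tube is a fully
    mixed solution. Step: a single depth increment carries more than
    ``step_score_threshold`` of the total rise — the two layers have not
    mixed. Anything else is a smooth gradient.
    """
    if p.depth.size < 4:
        raise ValueError("need at least 4 points to classify a profile")
    raw_range = p.raw_range
    if raw_range is None:
        raw_range = float(p.intensity.max() - p.intensity.min())
    if p.is_constant or raw_range < flatness_threshold:
        return "uniform"
    total = float(p.intensity.max() - p.intensity.min())
    max_step = float(np.max(np.abs(np.diff(p.intensity))))
    if max_step > step_score_threshold * total:
        return "step"
    return "smooth"


def mean_absolute_deviation(profiles: Sequence[GradientProfile]) -> ReproReport:
    """Cross-replicate absolute deviation from the mean profile.

    Profiles on different depth grids are resampled onto the first
    profile's grid by linear interpolation. For each replicate the mean
    over depth of |intensity − mean profile| is reported in % of the
    normalized intensity range, summarised as mean ± SD (ddof=1).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    grid = profiles[0].depth
    stack = np.vstack([
        p.intensity if p.depth.shape == grid.shape and np.allclose(p.depth, grid)
        else np.interp(grid, p.depth, p.intensity)
        for p in profiles
    ])
    mean_profile = stack.mean(axis=0)
    mads = np.abs(stack - mean_profile).mean(axis=1) * 100.0
    return ReproReport(per_replicate_mad=[float(x) for x in mads],
                       n_replicates=len(profiles))
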