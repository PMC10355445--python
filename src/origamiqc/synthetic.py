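"""Seeded generators for synthetic AFM scenes, length censuses and gradient profiles.

The generators emulate the inputs of a rate-zonal-centrifugation (RZC)
purification experiment on 6-helix-bundle (6-hb) DNA origami:

* flattened AFM height maps of origami deposited on mica, where three pixel
  populations coexist — the near-flat mica background, small excess
  staple-strand blobs, and rod-shaped 6-hb nanotubes (~460 nm monomers,
  ~920 nm dimers, ~8 nm wide) — each population a Gaussian in height;
* binary monomer/dimer label samples at a prescribed dimer fraction, the
  raw material of a dimer-content census;
* replicate densitometry traces of gradient tubes (step / linear / sigmoid /
  uniform shapes) for reproducibility QC.

Every generator is deterministic given its seed, and AFM scenes come with a
per-pixel ground-truth class map so parameter recovery can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gradient import GradientProfile
from .mixture import HeightMap

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "TrueParticle",
    "PlacementError",
    "generate_afm_scene",
    "generate_length_sample",
    "generate_gradient_replicates",
    "round_half_up",
]

# class codes used in GroundTruth.class_map
MICA, STAPLE, ORIGAMI = 0, 1, 2

# fraction of the nominal rod length used as SD when drawing individual
# rod lengths (real tube preps show a few percent length dispersion)
ROD_LENGTH_CV = 0.02

# staple blobs are rendered as a centre pixel plus its 4-neighbourhood
_STAPLE_OFFSETS = np.array([(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)])


class PlacementError(RuntimeError):
    """Raised when a rod cannot be placed without overlap in the allotted attempts."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic AFM scene.

    Heights are in nm. The three populations must be strictly ordered
    mica < staple < origami, mirroring how the groups separate by height
    on a real micrograph.
    """

    width_px: int = 256
    height_px: int = 256
    nm_per_pixel: float = 4.0
    mica_mu: float = 0.0
    staple_mu: float = 0.5
    origami_mu: float = 2.0
    mica_sigma: float = 0.15
    staple_sigma: float = 0.3
    origami_sigma: float = 0.5
    n_monomers: int = 3
    n_dimers: int = 1
    n_staples: int = 800
    monomer_len_nm: float = 460.0
    dimer_len_nm: float = 920.0
    tube_width_nm: float = 8.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be > 0")
        if not (self.mica_mu < self.staple_mu < self.origami_mu):
            raise ValueError("component heights must satisfy mica < staple < origami")
        for name in ("mica_sigma", "staple_sigma", "origami_sigma", "noise_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_monomers", "n_dimers", "n_staples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.monomer_len_nm < self.dimer_len_nm:
            raise ValueError("monomer_len_nm must be < dimer_len_nm")


@dataclass(frozen=True)
class TrueParticle:
    """Ground-truth record of one placed nanotube."""

    centroid: tuple[float, float]  # (row, col), px
    length_nm: float
    label: str  # "monomer" | "dimer"


@dataclass
class GroundTruth:
    """Truth channel accompanying a synthetic scene."""

    class_map: np.ndarray  # uint8, codes MICA/STAPLE/ORIGAMI
    particles: list[TrueParticle] = field(default_factory=list)

    @property
    def pixel_fractions(self) -> tuple[float, float, float]:
        """(P_mica, P_staple, P_origami) — normalized class-map label counts."""
        counts = np.bincount(self.class_map.ravel(), minlength=3).astype(float)
        p = counts / counts.sum()
        return (p[0], p[1], p[2] if len(p) == 3 else 0.0)


def _capsule_mask(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray,
                  radius_px: float) -> np.ndarray:
    """Boolean mask of pixels within `radius_px` of segment p0-p1 (round caps)."""
    r0 = int(max(0, math.floor(min(p0[0], p1[0]) - radius_px - 1)))
    r1 = int(min(shape[0], math.ceil(max(p0[0], p1[0]) + radius_px + 2)))
    c0 = int(max(0, math.floor(min(p0[1], p1[1]) - radius_px - 1)))
    c1 = int(min(shape[1], math.ceil(max(p0[1], p1[1]) + radius_px + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        t = np.zeros_like(rr, dtype=float)
    else:
        t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / denom
        t = np.clip(t, 0.0, 1.0)
    dist2 = (rr - (p0[0] + t * d[0])) ** 2 + (cc - (p0[1] + t * d[1])) ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = dist2 <= radius_px**2
    return mask


def generate_afm_scene(spec: SceneSpec, max_attempts_per_rod: int = 500
                       ) -> tuple[HeightMap, GroundTruth]:
    """Render a synthetic AFM height map with ground truth.

    Rods (6-hb monomers and dimers) are straight capsules of width
    ``tube_width_nm`` placed uniformly at random orientation, rejected on
    overlap with previously placed rods so that every nanotube is a single
    connected object; staple strands are small 5-px blobs that may overlap
    each other and sit under rods (origami takes precedence, then staple,
    then mica). Each pixel's height is its class mean plus a Gaussian
    deviate of the class SD plus instrument noise of SD ``noise_sigma``.

    Raises
    ------
    PlacementError
        if a rod cannot be placed without overlap within
        ``max_attempts_per_rod`` rejection-sampling attempts.
    """
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height_px, spec.width_px)
    class_map = np.full(shape, MICA, dtype=np.uint8)
    rod_mask = np.zeros(shape, dtype=bool)

    radius_px = 0.5 * spec.tube_width_nm / spec.nm_per_pixel
    particles: list[TrueParticle] = []

    rod_plan = [("monomer", spec.monomer_len_nm)] * spec.n_monomers + \
               [("dimer", spec.dimer_len_nm)] * spec.n_dimers
    for label, nominal_len in rod_plan:
        placed = False
        for _ in range(max_attempts_per_rod):
            length_nm = rng.normal(nominal_len, ROD_LENGTH_CV * nominal_len)
            length_px = max(length_nm, 1.0) / spec.nm_per_pixel
            theta = rng.uniform(0, np.pi)
            half = 0.5 * length_px * np.array([math.sin(theta), math.cos(theta)])
            # sample the centre from the box of positions keeping both
            # endpoints (plus cap and buffer) inside the frame
            margin = radius_px + 1.5
            lo = np.abs(half) + margin
            hi = np.array([shape[0] - 1, shape[1] - 1]) - np.abs(half) - margin
            if np.any(lo > hi):
                continue  # rod cannot fit at this orientation
            center = rng.uniform(lo, hi)
            p0, p1 = center - half, center + half
            # keep a generous buffer between rods so they never touch,
            # even after morphological closing in the detection step
            mask = _capsule_mask(shape, p0, p1, radius_px + 4.0)
            if np.any(mask & rod_mask):
                continue
            body = _capsule_mask(shape, p0, p1, max(radius_px, 0.6))
            rod_mask |= mask
            class_map[body] = ORIGAMI
            particles.append(TrueParticle(centroid=tuple(center), length_nm=length_nm,
                                          label=label))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {label} rod after {max_attempts_per_rod} attempts; "
                "scene too small or too crowded")

    if spec.n_staples > 0:
        centers_r = rng.integers(1, shape[0] - 1, size=spec.n_staples)
        centers_c = rng.integers(1, shape[1] - 1, size=spec.n_staples)
        rr = (centers_r[:, None] + _STAPLE_OFFSETS[None, :, 0]).ravel()
        cc = (centers_c[:, None] + _STAPLE_OFFSETS[None, :, 1]).ravel()
        staple = np.zeros(shape, dtype=bool)
        staple[rr, cc] = True
        class_map[staple & (class_map != ORIGAMI)] = STAPLE

    mu = np.array([spec.mica_mu, spec.staple_mu, spec.origami_mu])
    sigma = np.array([spec.mica_sigma, spec.staple_sigma, spec.origami_sigma])
    heights = (mu[class_map]
               + sigma[class_map] * rng.standard_normal(shape)
               + spec.noise_sigma * rng.standard_normal(shape))
    return (HeightMap(heights=heights, nm_per_pixel=spec.nm_per_pixel),
            GroundTruth(class_map=class_map, particles=particles))


def generate_length_sample(n: int, dimer_fraction: float,
                           monomer_len_nm: float = 460.0,
                           dimer_len_nm: float = 920.0,
                           length_cv: float = 0.05,
                           seed: int = 0) -> list[tuple[float, str]]:
    """Draw ``n`` particle lengths with exactly ``round(n*dimer_fraction)``
    dimers (round half up), the rest monomers.

    Lengths are Gaussian around the class mean with SD ``length_cv * mean``,
    truncated to be positive. Returns ``(length_nm, label)`` pairs in a
    seeded random order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= dimer_fraction <= 1.0:
        raise ValueError("dimer_fraction must be in [0, 1]")
    if length_cv < 0:
        raise ValueError("length_cv must be >= 0")
    rng = np.random.default_rng(seed)
    n_dimer = round_half_up(n * dimer_fraction)
    labels = np.array(["dimer"] * n_dimer + ["monomer"] * (n - n_dimer))
    means = np.where(labels == "dimer", dimer_len_nm, monomer_len_nm)
    lengths = rng.normal(means, length_cv * means)
    while np.any(lengths <= 0):  # truncate at > 0 by redrawing
        bad = lengths <= 0
        lengths[bad] = rng.normal(means[bad], length_cv * means[bad])
    order = rng.permutation(n)
    return [(float(lengths[i]), str(labels[i])) for i in order]


_SHAPES = ("step", "linear", "sigmoid", "uniform")


def _base_curve(shape: str, depth: np.ndarray) -> np.ndarray:
    if shape == "step":
        return (depth >= 0.5).astype(float)
    if shape == "linear":
        return depth.copy()
    if shape == "sigmoid":
        return 1.0 / (1.0 + np.exp(-(depth - 0.5) / 0.06))
    if shape == "uniform":
        return np.full_like(depth, 0.5)
    raise ValueError(f"unknown gradient shape {shape!r}; expected one of {_SHAPES}")


def generate_gradient_replicates(n_replicates: int, shape: str = "linear",
                                 n_points: int = 100, noise_sd: float = 0.0,
                                 seed: int = 0) -> list[GradientProfile]:
    """Generate replicate depth-intensity traces of a gradient tube.

    ``depth`` runs over [0, 1] top-to-bottom (0 = meniscus). The noiseless
    base curve is a step at depth 0.5, a unit linear ramp, a logistic ramp,
    or a constant; i.i.d. Gaussian noise of SD ``noise_sd`` (on the
    normalized intensity scale) is added per point.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    depth = np.linspace(0.0, 1.0, n_points)
    base = _base_curve(shape, depth)  # validates the shape name
    rng = np.random.default_rng(seed)
    profiles = []
    for rep in range(n_replicates):
        intensity = base + noise_sd * rng.standard_normal(n_points)
        raw_range = float(intensity.max() - intensity.min())
        profiles.append(GradientProfile(depth=depth.copy(), intensity=intensity,
                                        raw_range=raw_range,
                                        is_constant=raw_range == 0.0))
    return profiles
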