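"""Three-Gaussian mixture decomposition of AFM pixel heights.

On a micrograph of DNA origami deposited on mica, pixel heights fall into
three populations: the mica background, excess staple strands, and the
origami nanostructures themselves. Modelling the height histogram n(z) as a
sum of three Gaussians,

    n(z) ∝ Σ_k  P_k / σ_k · exp(-(z - μ_k)² / 2σ_k²),   Σ_k P_k = 1,

and fitting the corresponding mixture CDF

    F(z) = Σ_k  P_k · Φ((z - μ_k) / σ_k)

to the empirical CDF of pixel heights by least squares yields the fraction
of pixels belonging to each population. P_staple before vs after
purification quantifies how much excess staple strand the purification
removed (the staple-reduction fold change).

Fitting the CDF rather than a binned histogram avoids bin-width choices and
uses every pixel. The nine parameters are reduced to eight free ones
(two fraction logits with the third fraction by complement, three means,
three log-SDs) and components are sorted by mean after optimisation so the
labels mica/staple/origami always refer to the lowest/middle/highest
population.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize
from scipy.special import ndtr  # fast standard normal CDF

__all__ = [
    "HeightMap",
    "EmpiricalCDF",
    "MixtureParams",
    "MixtureFit",
    "empirical_cdf",
    "model_cdf",
    "fit_height_mixture",
    "staple_reduction",
    "flatten_plane",
]

MIN_PIXELS = 100  # fits on fewer pixels are refused
DEFAULT_MAX_CDF_POINTS = 50_000


@dataclass
class HeightMap:
    """A calibrated 2-D grid of surface heights (nm)."""

    heights: np.ndarray
    nm_per_pixel: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must all be finite")
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be > 0")

    @property
    def n_pixels(self) -> int:
        return self.heights.size


@dataclass
class EmpiricalCDF:
    """Empirical CDF of pixel heights: F(z_i) = rank_i / n, ties collapsed."""

    z_sorted: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        if len(self.z_sorted) != len(self.F):
            raise ValueError("z_sorted and F must have equal length")


@dataclass
class MixtureParams:
    """The nine parameters of the three-Gaussian height model.

    Components are kept in canonical order mu_mica <= mu_staple <= mu_origami;
    fractions sum to 1.
    """

    p_mica: float
    p_staple: float
    p_origami: float
    mu_mica: float
    mu_staple: float
    mu_origami: float
    sigma_mica: float
    sigma_staple: float
    sigma_origami: float

    def __post_init__(self) -> None:
        p = self.fractions
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (within 1e-9)")
        if not (self.mu_mica <= self.mu_staple <= self.mu_origami):
            raise ValueError("means must be in canonical order mica <= staple <= origami")
        if min(self.sigma_mica, self.sigma_staple, self.sigma_origami) <= 0:
            raise ValueError("all sigmas must be > 0")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.p_mica, self.p_staple, self.p_origami])

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mu_mica, self.mu_staple, self.mu_origami])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_mica, self.sigma_staple, self.sigma_origami])

    @classmethod
    def from_components(cls, p, mu, sigma) -> "MixtureParams":
        """Build params from unordered component triples, sorting by mean.

        A component with negligible weight (< 1%) has an unidentifiable
        mean — a fit that collapsed onto fewer populations can leave such
        components anywhere on the height axis. They are therefore parked
        after the substantive components, with their mean snapped to the
        highest substantive mean so the canonical ordering is preserved.
        In the single-population limit this keeps the dominant population
        on the lowest (mica) label.
        """
        p, mu, sigma = (np.asarray(x, dtype=float) for x in (p, mu, sigma))
        real = p >= 0.01
        if real.all() or not real.any():
            order = np.argsort(mu, kind="stable")
        else:
            order = np.concatenate([np.flatnonzero(real)[np.argsort(mu[real], kind="stable")],
                                    np.flatnonzero(~real)[np.argsort(mu[~real], kind="stable")]])
            mu = mu.copy()
            mu[~real] = mu[real].max()
        p, mu, sigma = p[order], mu[order], sigma[order]
        return cls(p[0], p[1], p[2], mu[0], mu[1], mu[2], sigma[0], sigma[1], sigma[2])


@dataclass
class MixtureFit:
    """Result of a mixture-CDF fit."""

    params: MixtureParams
    objective: float  # sum of squared CDF residuals
    n_pixels: int
    converged: bool
    n_restarts_used: int

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MixtureFit":
        d = json.loads(text)
        return cls(params=MixtureParams(**d.pop("params")), **d)


def flatten_plane(heights: np.ndarray) -> np.ndarray:
    """Subtract the least-squares plane — a minimal AFM flattening step."""
    heights = np.asarray(heights, dtype=float)
    rows, cols = np.mgrid[: heights.shape[0], : heights.shape[1]]
    A = np.column_stack([rows.ravel(), cols.ravel(), np.ones(heights.size)])
    coef, *_ = np.linalg.lstsq(A, heights.ravel(), rcond=None)
    return heights - (A @ coef).reshape(heights.shape)


def empirical_cdf(map: HeightMap, max_points: int = DEFAULT_MAX_CDF_POINTS,
                  seed: int = 0) -> EmpiricalCDF:
    """Empirical CDF of the pixel heights.

    F(z_i) = i/n over the sorted heights; tied heights collapse to the
    highest rank. Maps with more than ``max_points`` pixels are uniformly
    subsampled (seeded) before sorting, for tractability.
    """
    z = map.heights.ravel()
    if z.size < MIN_PIXELS:
        raise ValueError(
            f"refusing to build a CDF from {z.size} pixels (< {MIN_PIXELS}); "
            "the fit would be meaningless")
    if max_points is not None and z.size > max_points:
        rng = np.random.default_rng(seed)
        z = rng.choice(z, size=max_points, replace=False)
    uniq, counts = np.unique(z, return_counts=True)
    F = np.cumsum(counts) / z.size
    return EmpiricalCDF(z_sorted=uniq, F=F)


def model_cdf(params: MixtureParams, z) -> np.ndarray | float:
    """Mixture CDF  Σ_k p_k Φ((z - μ_k)/σ_k)  evaluated at height(s) z (nm)."""
    z = np.asarray(z, dtype=float)
    p, mu, sigma = params.fractions, params.means, params.sigmas
    out = sum(p[k] * ndtr((z - mu[k]) / sigma[k]) for k in range(3))
    return float(out) if out.ndim == 0 else out


# --- internal parameterisation: theta = (a1, a2, mu1, mu2, mu3, log s1..s3) ---

def _theta_to_components(theta: np.ndarray):
    a = np.array([theta[0], theta[1], 0.0])
    a -= a.max()
    p = np.exp(a)
    p /= p.sum()
    mu = theta[2:5]
    sigma = np.exp(np.clip(theta[5:8], -30.0, 30.0))
    return p, mu, sigma


def _components_to_theta(p, mu, sigma) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-6, None)
    p = p / p.sum()
    return np.concatenate([[math.log(p[0] / p[2]), math.log(p[1] / p[2])],
                           np.asarray(mu, dtype=float),
                           np.log(np.asarray(sigma, dtype=float))])


def _residuals(theta: np.ndarray, z: np.ndarray, F_emp: np.ndarray) -> np.ndarray:
    p, mu, sigma = _theta_to_components(theta)
    model = (p[0] * ndtr((z - mu[0]) / sigma[0])
             + p[1] * ndtr((z - mu[1]) / sigma[1])
             + p[2] * ndtr((z - mu[2]) / sigma[2]))
    return model - F_emp


def _default_init(z: np.ndarray) -> np.ndarray:
    mu = np.percentile(z, [25, 60, 95])
    iqr = np.subtract(*np.percentile(z, [75, 25]))
    sigma = np.full(3, max(iqr / 1.35 / 2.0, 1e-3))
    return _components_to_theta([0.6, 0.3, 0.1], mu, sigma)


def fit_height_mixture(map: HeightMap, init: MixtureParams | None = None,
                       n_restarts: int = 5, seed: int = 0,
                       max_points: int = DEFAULT_MAX_CDF_POINTS,
                       flatten: bool = False) -> MixtureFit:
    """Fit the three-Gaussian mixture CDF to a height map by least squares.

    Minimises Σ_i (F_emp(z_i) - F_model(z_i))² over the nine parameters
    (Σp = 1 and σ > 0 enforced by reparameterisation). The best of
    ``n_restarts`` seeded initialisations is returned; restart 0 uses
    percentile-based starting values, later restarts jitter them.

    Parameters
    ----------
    init : optional starting parameters replacing the percentile heuristic.
    flatten : subtract the least-squares plane before fitting (off by
        default; synthetic maps are already flat).

    Raises
    ------
    ValueError
        for maps with fewer than 100 pixels or with constant heights.
    """
    heights = flatten_plane(map.heights) if flatten else map.heights
    flat_map = HeightMap(heights=heights, nm_per_pixel=map.nm_per_pixel)
    ecdf = empirical_cdf(flat_map, max_points=max_points, seed=seed)
    z, F_emp = ecdf.z_sorted, ecdf.F
    if z[-1] - z[0] <= 0:
        raise ValueError("degenerate map: all pixel heights identical")

    theta0 = (_components_to_theta(init.fractions, init.means, init.sigmas)
              if init is not None else _default_init(z))
    spread = z[-1] - z[0]
    rng = np.random.default_rng(seed)

    best = None
    n_used = 0
    for restart in range(max(1, n_restarts)):
        theta = theta0.copy()
        if restart > 0:
            theta = theta + np.concatenate([
                rng.normal(0, 0.5, size=2),
                rng.normal(0, 0.1 * spread, size=3),
                rng.normal(0, 0.3, size=3),
            ])
        n_used += 1
        try:
            res = optimize.least_squares(_residuals, theta, args=(z, F_emp),
                                         method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        # every restart raised: report a non-converged fit at the start point
        p, mu, sigma = _theta_to_components(theta0)
        return MixtureFit(params=MixtureParams.from_components(p, mu, sigma),
                          objective=float(np.sum(_residuals(theta0, z, F_emp) ** 2)),
                          n_pixels=flat_map.n_pixels, converged=False,
                          n_restarts_used=n_used)

    p, mu, sigma = _theta_to_components(best.x)
    params = MixtureParams.from_components(p, mu, sigma)
    return MixtureFit(params=params,
                      objective=float(2.0 * best.cost),
                      n_pixels=flat_map.n_pixels,
                      converged=bool(best.success),
                      n_restarts_used=n_used)


def staple_reduction(fit_before: MixtureFit, fit_after: MixtureFit) -> float:
    """Fold change in the staple pixel fraction, before / after purification.

    A value of 2.14 means purification removed a bit more than half of the
    excess staple material visible on the surface.
    """
    for name, fit in (("before", fit_before), ("after", fit_after)):
        if not fit.converged:
            raise ValueError(f"fit_{name} did not converge; fold change undefined")
    denom = fit_after.params.p_staple
    if denom < 1e-9:
        raise ValueError("p_staple after purification is zero; fold change undefined")
    return fit_before.params.p_staple / denom
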