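"""Half-subset bootstrap for the standard error of a binary fraction.

The counted monomer/dimer content of an AFM field is a binary fraction
(monomer = 0, dimer = 1). Its uncertainty is estimated by a subsampling
bootstrap: from the N counted particles, draw a subset of size round(N/2)
without replacement, record the subset mean, repeat 10,000 times, and
report the standard deviation of the subset means as the standard error.

Because the draws are without replacement from a binary population, the
subset mean is a scaled hypergeometric variable, so the scheme has the
closed form

    SE = sqrt( p(1-p)/m * (N-m)/(N-1) ),   m = round(N/2),

which `analytic_half_subset_se` provides as an exact oracle for the
Monte-Carlo routine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BootstrapResult", "half_subset_se", "analytic_half_subset_se"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate and half-subset bootstrap SE of a binary fraction."""

    point_estimate: float
    se: float
    n: int
    subset_size: int
    n_resamples: int
    seed: int


def half_subset_se(values, n_resamples: int = 10_000, seed: int = 0
                   ) -> BootstrapResult:
    """Standard error of the mean of binary values by half-subset resampling.

    Each resample draws round(n/2) elements without replacement and records
    their mean; the SE is the standard deviation (ddof=1) of the resample
    means. Deterministic for a given seed.

    Raises
    ------
    ValueError
        if fewer than 2 values are given or any value is not 0/1.
    """
    values = np.asarray(values)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError("values must be binary 0/1 (monomer=0, dimer=1)")
    values = values.astype(float).ravel()
    m = _round_half_up(n / 2)
    rng = np.random.default_rng(seed)
    # vectorised without-replacement subsets: first m columns of row-wise
    # random permutations
    idx = np.argsort(rng.random((n_resamples, n)), axis=1)[:, :m]
    means = values[idx].mean(axis=1)
    return BootstrapResult(point_estimate=float(values.mean()),
                           se=float(np.std(means, ddof=1)),
                           n=n, subset_size=m, n_resamples=n_resamples,
                           seed=seed)


def analytic_half_subset_se(p: float, n: int) -> float:
    """Exact SE of the half-subset scheme for a binary sample.

    For a population of n items of which n·p are ones, the mean of a
    without-replacement draw of size m = round(n/2) has standard deviation
    sqrt(p(1-p)/m · (n-m)/(n-1)) (hypergeometric variance with finite-
    population correction).

    ``n*p`` must be integral — the formula describes an actual sample
    composition, not an abstract rate.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n < 2:
        raise ValueError("n must be >= 2")
    if abs(n * p - round(n * p)) > 1e-9:
        raise ValueError("n*p must be an integer (a realisable sample count)")
    m = _round_half_up(n / 2)
    return math.sqrt(p * (1 - p) / m * (n - m) / (n - 1))
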