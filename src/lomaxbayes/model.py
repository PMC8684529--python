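"""Lomax (Pareto type-II) lifetime model with known scale.

The Lomax distribution is a heavy-tailed lifetime model on [0, inf) with
density

    f(x; beta, sigma) = (beta / sigma) (1 + x/sigma)^-(beta + 1),   x >= 0,

where ``sigma > 0`` is a known scale and ``beta > 0`` the shape parameter
to be estimated.  Because ``ln(1 + X/sigma)`` is Exponential with rate
``beta``, the statistic

    gamma = sum_i ln(1 + x_i / sigma)

is sufficient for ``beta`` and follows a Gamma(n, rate=beta) law; every
estimator in this package is a function of the sample only through
``(n, gamma)``.  This module provides the distribution primitives, the
inverse-CDF sampler used throughout the simulation study, the sufficient
statistic, and the maximum-likelihood estimator ``n / gamma``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DegenerateSampleError",
    "LomaxParams",
    "SampleStats",
    "pdf",
    "cdf",
    "reliability",
    "sample",
    "sufficient_statistic",
    "mle_shape",
    "read_sample",
    "write_sample",
]


class DegenerateSampleError(ValueError):
    """Every observation is zero, so gamma = 0 and the shape MLE is undefined."""


@dataclass(frozen=True)
class LomaxParams:
    """Shape ``beta`` and scale ``sigma`` of a Lomax distribution.

    Both must be finite and strictly positive; ``sigma`` carries the units
    of the data, ``beta`` is dimensionless and governs tail heaviness
    (smaller ``beta`` means heavier tail; moments of order >= beta do not
    exist).
    """

    beta: float
    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"shape beta must be finite and > 0, got {self.beta!r}")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"scale sigma must be finite and > 0, got {self.sigma!r}")


@dataclass(frozen=True)
class SampleStats:
    """A lifetime sample together with its sufficient statistic.

    Attributes
    ----------
    values : ndarray
        The observed nonnegative lifetimes (read-only copy).
    n : int
        Sample size, equal to ``len(values)``.
    gamma_stat : float
        ``sum_i ln(1 + x_i / sigma)`` for the scale the sample was reduced
        with; zero iff every observation is zero.
    """

    values: np.ndarray
    n: int
    gamma_stat: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("all sample values must be finite and >= 0")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        if self.n != arr.size or self.n < 1:
            raise ValueError(f"n must equal len(values) >= 1, got n={self.n}, len={arr.size}")
        if not (math.isfinite(self.gamma_stat) and self.gamma_stat >= 0):
            raise ValueError(f"gamma_stat must be finite and >= 0, got {self.gamma_stat!r}")
        if (self.gamma_stat == 0) != bool(np.all(arr == 0)):
            raise ValueError("gamma_stat is 0 iff all values are 0")

    @classmethod
    def from_values(cls, values, sigma: float) -> "SampleStats":
        """Reduce raw lifetimes to (values, n, gamma) for a known scale."""
        arr = np.asarray(values, dtype=float).ravel()
        return cls(arr, arr.size, sufficient_statistic(arr, sigma))


def pdf(x, p: LomaxParams):
    """Lomax density (beta/sigma)(1 + x/sigma)^-(beta+1); zero for x < 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0,
        (p.beta / p.sigma) * (1.0 + np.maximum(x, 0.0) / p.sigma) ** (-(p.beta + 1.0)),
        0.0,
    )
    return out if out.ndim else float(out)


def cdf(x, p: LomaxParams):
    """Lomax distribution function 1 - (1 + x/sigma)^-beta; zero for x < 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, -np.expm1(-p.beta * np.log1p(np.maximum(x, 0.0) / p.sigma)), 0.0)
    return out if out.ndim else float(out)


def reliability(t, p: LomaxParams):
    """Survival function R(t) = (1 + t/sigma)^-beta, the complement of the CDF."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("reliability is defined for t >= 0")
    out = np.exp(-p.beta * np.log1p(t / p.sigma))
    return out if out.ndim else float(out)


def sample(p: LomaxParams, n: int, rng) -> SampleStats:
    """Draw an i.i.d. Lomax sample by inverse-CDF transform.

    Uses ``x_i = sigma * ((1 - U_i)^(-1/beta) - 1)`` with ``U_i`` uniform on
    [0, 1); the generator never returns ``U = 1``, so ``x`` is always finite
    (``U = 0`` maps to ``x = 0``).  The same seeded ``rng`` reproduces the
    sample bit for bit.

    Parameters
    ----------
    p : LomaxParams
    n : int
        Sample size, >= 1.
    rng : numpy Generator, SeedSequence or int seed
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(rng)
    u = rng.random(n)
    x = p.sigma * ((1.0 - u) ** (-1.0 / p.beta) - 1.0)
    return SampleStats.from_values(x, p.sigma)


def sufficient_statistic(values, sigma: float) -> float:
    """gamma = sum_i ln(1 + x_i / sigma).

    Accumulated with numpy's pairwise summation so the reduction is
    reproducible to tight tolerances at any n used here.
    """
    if not (math.isfinite(sigma) and sigma > 0):
        raise ValueError(f"sigma must be finite and > 0, got {sigma!r}")
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("all values must be finite and >= 0")
    return float(np.sum(np.log1p(arr / sigma)))


def mle_shape(stats: SampleStats) -> float:
    """Maximum-likelihood estimate of the shape, n / gamma.

    Raises
    ------
    DegenerateSampleError
        If gamma = 0 (every observation zero): the likelihood is monotone
        in beta and no finite maximizer exists.
    """
    if stats.gamma_stat == 0:
        raise DegenerateSampleError("all observations are zero; the shape MLE n/gamma is undefined")
    return stats.n / stats.gamma_stat


def read_sample(path) -> np.ndarray:
    """Read one lifetime per line from delimited text; '#' starts a comment."""
    arr = np.loadtxt(Path(path), comments="#", ndmin=1, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{path}: expected a single column of lifetimes")
    return arr


def write_sample(path, values, header: str | None = None) -> None:
    """Write one lifetime per line; an optional header becomes '#' comments."""
    np.savetxt(Path(path), np.asarray(values, dtype=float), fmt="%.17g",
               header=header or "", comments="# ")
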