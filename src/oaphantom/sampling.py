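"""Distribution specifications for stochastic property assignment.

Tissue properties are drawn once per phantom from truncated Gaussian,
Gaussian, uniform, or degenerate (fixed) distributions. The truncated
Gaussian TN(mean, sd, low, high) is the plain normal restricted to
[low, high]; it is the maximum-entropy distribution on a bounded interval
with prescribed mean and standard deviation, which is why it is the
work-horse here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import InvalidArgumentError

__all__ = [
    "TruncatedGaussianSpec",
    "UniformSpec",
    "FixedSpec",
]


@dataclass(frozen=True)
class TruncatedGaussianSpec:
    """TN(mean, sd, low, high); unbounded limits give a plain Gaussian.

    ``sd == 0`` degenerates to a point mass at ``mean``.
    """

    mean: float
    sd: float
    low: float = -math.inf
    high: float = math.inf

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidArgumentError(f"sd must be >= 0, got {self.sd}")
        if self.low > self.high:
            raise InvalidArgumentError(
                f"low ({self.low}) must not exceed high ({self.high})"
            )

    @classmethod
    def normal(cls, mean: float, sd: float) -> "TruncatedGaussianSpec":
        return cls(mean, sd)

    def sample(self, rng: np.random.Generator, size=None):
        # inverse-CDF sampling: exact truncated-normal draws driven by a
        # single uniform variate each, much cheaper than rejection for the
        # mild truncations used here
        if self.sd == 0:
            if size is None:
                return self.mean
            return np.full(size, self.mean)
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        fa, fb = special.ndtr(a), special.ndtr(b)
        u = rng.uniform(size=size)
        x = self.mean + self.sd * special.ndtri(fa + u * (fb - fa))
        x = np.clip(x, self.low, self.high)
        return float(x) if size is None else x


@dataclass(frozen=True)
class UniformSpec:
    """U(low, high)."""

    low: float
    high: float

    def __post_init__(self):
        if self.low > self.high:
            raise InvalidArgumentError(
                f"low ({self.low}) must not exceed high ({self.high})"
            )

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class FixedSpec:
    """A degenerate distribution: always returns ``value``."""

    value: float

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)
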