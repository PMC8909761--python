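"""Radial placement laws for synthetic 2D cell scenes.

A radial law is a probability distribution over the *normalized* radial axis
used throughout the radial-profile analysis: 0 % is the nucleus centre, 25 %
the nuclear envelope and 100 % the cell periphery.  Mitochondria are excluded
from the nucleoplasm, so every law must be supported on [25, 100].

Each law knows its analytic median, which is by construction the ground-truth
mean distribution radius (MDR) of a scene drawn from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

NUCLEUS_EDGE = 25.0
PERIPHERY = 100.0


def _check_support(lo: float, hi: float) -> None:
    if lo < NUCLEUS_EDGE or hi > PERIPHERY:
        raise ValueError(
            f"radial law support [{lo}, {hi}] must lie within "
            f"[{NUCLEUS_EDGE}, {PERIPHERY}] (mitochondria are excluded from "
            "the nucleoplasm)"
        )


@dataclass(frozen=True)
class DeltaLaw:
    """All signal at a single normalized radius ``r0``."""

    r0: float

    def __post_init__(self) -> None:
        _check_support(self.r0, self.r0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, float(self.r0))

    def median(self) -> float:
        return float(self.r0)

    def pdf(self, r: np.ndarray) -> np.ndarray:  # for profile comparisons
        raise NotImplementedError("delta law has no density")


@dataclass(frozen=True)
class UniformLaw:
    """Signal uniform on normalized radii ``[a, b]``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError("uniform law requires a < b")
        _check_support(self.a, self.b)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.a, self.b, size=n)

    def median(self) -> float:
        return 0.5 * (self.a + self.b)

    def pdf(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.where((r >= self.a) & (r <= self.b), 1.0 / (self.b - self.a), 0.0)


@dataclass(frozen=True)
class GaussianLaw:
    """Gaussian over normalized radius, truncated to [25, 100]."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        _check_support(self.mu, self.mu)  # location itself must be admissible

    def _frozen(self):
        a = (NUCLEUS_EDGE - self.mu) / self.sigma
        b = (PERIPHERY - self.mu) / self.sigma
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sigma)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._frozen().rvs(size=n, random_state=rng)

    def median(self) -> float:
        return float(self._frozen().median())

    def pdf(self, r: np.ndarray) -> np.ndarray:
        return self._frozen().pdf(np.asarray(r, dtype=float))


RadialLaw = DeltaLaw | UniformLaw | GaussianLaw


def law_from_dict(d: dict) -> RadialLaw:
    """Build a radial law from a JSON-style dict, e.g. {"kind": "gaussian", "mu": 70, "sigma": 5}."""
    kind = d["kind"]
    if kind == "delta":
        return DeltaLaw(d["r0"])
    if kind == "uniform":
        return UniformLaw(d["a"], d["b"])
    if kind == "gaussian":
        return GaussianLaw(d["mu"], d["sigma"])
    raise ValueError(f"unknown radial law kind: {kind!r}")
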