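"""Declarative samplers for per-bout inactivity parameters.

Every time an agent becomes inactive it draws two durations: the spontaneous
activation time S (when it will self-activate) and the refractory period R
(until when it ignores tactile stimulation).  Both are described by a
:class:`DistributionSpec`, which supports the four families used across the
simulation campaigns:

``exponential``
    Continuous exponential with a given mean (rate 1/mean).
``uniform_range``
    Integer-valued uniform on the closed interval ``[lo, hi]``.
``uniform_mean_halfwidth``
    Integer-valued uniform on ``[mean - halfwidth, mean + halfwidth]``; the
    half-width is the refractory-noise amplitude Omega.  Omega = 0 degenerates
    to a fixed value.
``fixed``
    Degenerate point mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["DistributionSpec", "exponential", "uniform_range", "uniform_mean_halfwidth", "fixed"]

# integer codes shared with the compiled simulation kernel
KIND_FIXED = 0
KIND_EXPONENTIAL = 1
KIND_UNIFORM_RANGE = 2

_KINDS = ("exponential", "uniform_range", "uniform_mean_halfwidth", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of the distribution a bout parameter is drawn from.

    Parameters are in seconds.  Uniform families draw integers with equal
    probability; the exponential family draws continuous values.
    """

    kind: str
    mean: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None
    value: Optional[float] = None
    halfwidth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "exponential":
            if self.mean is None or self.mean <= 0:
                raise ValueError("exponential distribution requires mean > 0")
        elif self.kind == "uniform_range":
            if self.lo is None or self.hi is None or self.lo > self.hi:
                raise ValueError("uniform_range requires lo <= hi")
        elif self.kind == "uniform_mean_halfwidth":
            if self.mean is None or self.halfwidth is None:
                raise ValueError("uniform_mean_halfwidth requires mean and halfwidth")
            if self.halfwidth < 0:
                raise ValueError("halfwidth (Omega) must be >= 0")
            if self.mean - self.halfwidth < 1:
                raise ValueError(
                    f"halfwidth (Omega={self.halfwidth}) exceeds mean - 1 ({self.mean - 1}): "
                    "lower refractory bound would be non-positive"
                )
        elif self.kind == "fixed":
            if self.value is None or self.value < 0:
                raise ValueError("fixed distribution requires value >= 0")

    # -- sampling ---------------------------------------------------------
    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        """Draw from the distribution using ``rng``."""
        if self.kind == "exponential":
            return rng.exponential(self.mean, size=size)
        if self.kind == "uniform_range":
            return rng.integers(int(self.lo), int(self.hi) + 1, size=size).astype(float)
        if self.kind == "uniform_mean_halfwidth":
            lo = int(round(self.mean - self.halfwidth))
            hi = int(round(self.mean + self.halfwidth))
            return rng.integers(lo, hi + 1, size=size).astype(float)
        # fixed
        if size is None:
            return float(self.value)
        return np.full(size, float(self.value))

    @property
    def expected_value(self) -> float:
        """Analytic mean of the distribution (seconds)."""
        if self.kind == "exponential":
            return float(self.mean)
        if self.kind == "uniform_range":
            return (self.lo + self.hi) / 2.0
        if self.kind == "uniform_mean_halfwidth":
            return float(self.mean)
        return float(self.value)

    # -- kernel encoding --------------------------------------------------
    def encode(self) -> tuple[int, float, float]:
        """Encode as ``(kind_code, p1, p2)`` for the compiled kernel.

        Codes: 0 fixed(value in p1), 1 exponential(mean in p1),
        2 integer-uniform on [p1, p2].  The two uniform families share one
        code; ``uniform_mean_halfwidth`` is uniform on
        [mean - Omega, mean + Omega].
        """
        if self.kind == "fixed":
            return KIND_FIXED, float(self.value), 0.0
        if self.kind == "exponential":
            return KIND_EXPONENTIAL, float(self.mean), 0.0
        if self.kind == "uniform_range":
            return KIND_UNIFORM_RANGE, float(int(self.lo)), float(int(self.hi))
        lo = int(round(self.mean - self.halfwidth))
        hi = int(round(self.mean + self.halfwidth))
        return KIND_UNIFORM_RANGE, float(lo), float(hi)


def exponential(mean: float) -> DistributionSpec:
    return DistributionSpec("exponential", mean=mean)


def uniform_range(lo: float, hi: float) -> DistributionSpec:
    return DistributionSpec("uniform_range", lo=lo, hi=hi)


def uniform_mean_halfwidth(mean: float, halfwidth: float) -> DistributionSpec:
    if halfwidth == 0:
        return DistributionSpec("fixed", value=float(mean))
    return DistributionSpec("uniform_mean_halfwidth", mean=mean, halfwidth=halfwidth)


def fixed(value: float) -> DistributionSpec:
    return DistributionSpec("fixed", value=value)
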