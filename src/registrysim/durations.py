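"""Stochastic duration models for the reporting simulation.

All process durations in the model are expressed in fractional days and are
drawn from one of three families: triangular, uniform, or constant.  The
treatment-wait distributions are built from published three-point summaries
(mean; min-max) via :func:`triangular_from_summary`, the standard
discrete-event-simulation device for turning a three-point estimate into a
sampling distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

__all__ = [
    "MONTH_DAYS",
    "DistributionSpec",
    "constant",
    "uniform",
    "triangular",
    "triangular_from_summary",
    "sample",
    "draw_suspense_wait",
    "sample_suspense_wait",
    "ABSTRACTION_DEFAULT",
    "SUSPENSE_CALIBRATED",
    "SUSPENSE_FULL_BAND",
    "ZERO_DELAY",
]

#: One model month, in days.  The simulation uses a uniform 365-day year with
#: twelve equal months; no calendar dates, weekends or holidays.
MONTH_DAYS = 365.0 / 12.0

_FAMILIES = ("triangular", "uniform", "constant")


class DurationError(ValueError):
    """Raised for invalid distribution specifications."""


@dataclass(frozen=True)
class DistributionSpec:
    """A duration distribution: family name plus family-specific parameters.

    Parameters are in days:

    * ``triangular``: ``(lower, mode, upper)``
    * ``uniform``: ``(lower, upper)``
    * ``constant``: ``(value,)``
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise DurationError(f"unknown distribution family {self.family!r}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if not all(math.isfinite(p) and p >= 0.0 for p in params):
            raise DurationError(f"parameters must be finite and >= 0: {params}")
        if self.family == "triangular":
            if len(params) != 3:
                raise DurationError("triangular needs (lower, mode, upper)")
            lo, mode, hi = params
            if not lo <= mode <= hi:
                raise DurationError(
                    f"triangular requires lower <= mode <= upper, got {params}"
                )
        elif self.family == "uniform":
            if len(params) != 2:
                raise DurationError("uniform needs (lower, upper)")
            if not params[0] <= params[1]:
                raise DurationError(
                    f"uniform requires lower <= upper, got {params}"
                )
        else:  # constant
            if len(params) != 1:
                raise DurationError("constant needs (value,)")

    @property
    def support(self) -> tuple[float, float]:
        if self.family == "triangular":
            return (self.params[0], self.params[2])
        if self.family == "uniform":
            return (self.params[0], self.params[1])
        return (self.params[0], self.params[0])

    @property
    def mean(self) -> float:
        """Closed-form mean of the distribution."""
        if self.family == "triangular":
            return sum(self.params) / 3.0
        if self.family == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return self.params[0]

    def to_dict(self) -> dict[str, Any]:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DistributionSpec":
        unknown = set(d) - {"family", "params"}
        if unknown:
            raise DurationError(f"unknown distribution keys: {sorted(unknown)}")
        return cls(family=d["family"], params=tuple(d["params"]))


def constant(value: float) -> DistributionSpec:
    return DistributionSpec("constant", (value,))


def uniform(lower: float, upper: float) -> DistributionSpec:
    return DistributionSpec("uniform", (lower, upper))


def triangular(lower: float, mode: float, upper: float) -> DistributionSpec:
    return DistributionSpec("triangular", (lower, mode, upper))


def triangular_from_summary(mean: float, lo: float, hi: float) -> DistributionSpec:
    """Build a triangular distribution matching a (mean; min-max) summary.

    The mode is the one value that makes the analytic triangular mean
    ``(lo + mode + hi) / 3`` equal the stated mean::

        mode = 3 * mean - lo - hi

    A degenerate summary (``lo == hi``) collapses to a constant.  If the
    derived mode falls outside ``[lo, hi]`` the summary is not representable
    by a triangular distribution and an error is raised; the caller decides
    what to do about it.
    """
    if not lo <= mean <= hi:
        raise DurationError(
            f"summary mean {mean} outside its own range [{lo}, {hi}]"
        )
    if lo == hi:
        return constant(lo)
    mode = 3.0 * mean - lo - hi
    if not lo <= mode <= hi:
        raise DurationError(
            f"derived mode {mode} falls outside [{lo}, {hi}]; the summary "
            f"(mean={mean}, min={lo}, max={hi}) cannot be represented by a "
            "triangular distribution"
        )
    return triangular(lo, mode, hi)


def sample(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw from ``spec``; scalar if ``size`` is None, else an ndarray."""
    if spec.family == "triangular":
        lo, mode, hi = spec.params
        return rng.triangular(lo, mode, hi, size)
    if spec.family == "uniform":
        lo, hi = spec.params
        return rng.uniform(lo, hi, size)
    value = spec.params[0]
    if size is None:
        return value
    return np.full(size, value)


# --- shipped duration parameters -------------------------------------------

#: Abstraction of one case: registrar-estimated 45 minutes to 1.5 hours,
#: modeled as uniform over that range, expressed in days.
ABSTRACTION_DEFAULT = uniform(45.0 / 1440.0, 90.0 / 1440.0)

#: Suspense-file waiting policy, existing workflow.  Hospitals report waits
#: of three to six months, applied as a single facility-wide constant.  The
#: calibrated default concentrates waits around the four-month center of the
#: band; the per-case spread of the published latency figures is far too
#: small for facility waits spread over the full 90-180 day band.
SUSPENSE_CALIBRATED = uniform(105.0, 135.0)

#: Alternative policy spanning the whole reported three-to-six-month band.
SUSPENSE_FULL_BAND = uniform(90.0, 180.0)

ZERO_DELAY = constant(0.0)

#: Hard limits of the three-to-six-month suspense convention, in days.
SUSPENSE_BAND = (90.0, 180.0)


def draw_suspense_wait(
    policy: DistributionSpec,
    rng: np.random.Generator,
    *,
    enforce_band: bool = True,
) -> float:
    """Draw one facility's constant suspense wait from a policy distribution."""
    wait = float(sample(policy, rng))
    if enforce_band and not SUSPENSE_BAND[0] <= wait <= SUSPENSE_BAND[1]:
        raise DurationError(
            f"suspense wait {wait:.2f} outside the {SUSPENSE_BAND} day band"
        )
    return wait


def sample_suspense_wait(hospital, rng: np.random.Generator) -> float:
    """Suspense wait for a case at ``hospital``.

    The wait is a per-facility constant fixed when the hospital profile was
    built, so every call returns the same value; the signature mirrors the
    other samplers for uniformity.
    """
    return hospital.suspense_wait
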