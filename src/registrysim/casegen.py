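"""Synthetic case-stream generator.

Emulates one hospital's annual caseload of newly diagnosed reportable
tumors as a homogeneous Poisson arrival stream.  Each case carries a cancer
type drawn from a configurable mixture (breast / colorectal / lung by
default), an identification source (pathology report vs ICD disease index),
a flag for whether abstraction requires records from an external facility,
and a treatment-completion time drawn from the type's treatment-wait
distribution.

The treatment-wait summaries shipped here come from national
treatment-delay data (Bilimoria et al., J Clin Oncol 2011): days from
diagnosis to first treatment of (mean; min-max) = (24; 14-40) for breast,
(37; 20-63) for colorectal and (26; 13-46) for lung cancer.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .durations import (
    MONTH_DAYS,
    DistributionSpec,
    sample,
    triangular_from_summary,
)

__all__ = [
    "CancerTypeSpec",
    "Case",
    "HospitalProfile",
    "default_mixture",
    "DEFAULT_WEIGHTS",
    "CALIBRATED_WEIGHTS",
    "assign_cancer_type",
    "schedule_treatment",
    "generate_cases",
    "cases_to_frame",
    "cases_to_csv",
]

PATHOLOGY = "pathology"
DISEASE_INDEX = "disease_index"

#: Default fraction of cases identified through pathology reports
#: (registrars report 90-95%; midpoint).
P_PATHOLOGY_DEFAULT = 0.925
#: Default fraction of cases needing records from an external facility
#: (reported 10-40%; midpoint).
P_EXTERNAL_DEFAULT = 0.25
#: Default probability that a case never receives (recorded) treatment.
P_NO_TREATMENT_DEFAULT = 0.0

_WEIGHT_TOL = 1e-9


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class CancerTypeSpec:
    """One cancer type: treatment-wait summary (days) and mixture weight."""

    name: str
    wait_mean: float
    wait_min: float
    wait_max: float
    mixture_weight: float

    def __post_init__(self) -> None:
        if not self.wait_min <= self.wait_mean <= self.wait_max:
            raise ConfigurationError(
                f"{self.name}: need wait_min <= wait_mean <= wait_max, got "
                f"({self.wait_mean}; {self.wait_min}-{self.wait_max})"
            )
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ConfigurationError(
                f"{self.name}: mixture weight {self.mixture_weight} not in [0, 1]"
            )

    def wait_distribution(self) -> DistributionSpec:
        """Triangular treatment-wait sampler matching the printed summary."""
        return triangular_from_summary(self.wait_mean, self.wait_min, self.wait_max)


#: Neutral default: the three modeled types in equal proportion.
DEFAULT_WEIGHTS = {"breast": 1.0 / 3.0, "colorectal": 1.0 / 3.0, "lung": 1.0 / 3.0}

#: Calibrated mixture preset.  The registry's true type proportions are a
#: free calibration parameter of the model (they are not published with the
#: latency figures this package reproduces); this preset is the weighting
#: under which the shipped configuration reproduces those figures.
CALIBRATED_WEIGHTS = {"breast": 0.10, "colorectal": 0.80, "lung": 0.10}

_WAIT_SUMMARIES = {
    "breast": (24.0, 14.0, 40.0),
    "colorectal": (37.0, 20.0, 63.0),
    "lung": (26.0, 13.0, 46.0),
}


def default_mixture(
    weights: Mapping[str, float] | None = None,
) -> list[CancerTypeSpec]:
    """The shipped breast/colorectal/lung panel with the given weights."""
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    unknown = set(weights) - set(_WAIT_SUMMARIES)
    if unknown:
        raise ConfigurationError(f"unknown cancer types: {sorted(unknown)}")
    return [
        CancerTypeSpec(name, *_WAIT_SUMMARIES[name], mixture_weight=w)
        for name, w in weights.items()
    ]


def _check_weights(mixture: Sequence[CancerTypeSpec]) -> np.ndarray:
    weights = np.array([s.mixture_weight for s in mixture], dtype=float)
    if abs(weights.sum() - 1.0) > _WEIGHT_TOL:
        raise ConfigurationError(
            f"mixture weights sum to {weights.sum()!r}, expected 1"
        )
    return weights


@dataclass(frozen=True)
class Case:
    """One reportable tumor case and its pre-workflow attributes.

    Times are fractional days from simulation start; ``t_treatment_complete``
    is ``None`` for cases that never receive recorded treatment.
    """

    case_id: str
    hospital_id: str
    cancer_type: str
    t_diagnosis: float
    source: str
    needs_external: bool
    t_treatment_complete: float | None = None

    def __post_init__(self) -> None:
        if self.t_diagnosis < 0:
            raise ConfigurationError("t_diagnosis must be >= 0")
        if self.source not in (PATHOLOGY, DISEASE_INDEX):
            raise ConfigurationError(f"unknown source {self.source!r}")
        if (
            self.t_treatment_complete is not None
            and self.t_treatment_complete < self.t_diagnosis
        ):
            raise ConfigurationError(
                "t_treatment_complete must be >= t_diagnosis"
            )


@dataclass(frozen=True)
class HospitalProfile:
    """One reporting facility's static parameters.

    ``suspense_wait`` is the facility-wide constant holding time (days) a
    case spends in the suspense file under the existing workflow; the
    three-to-six-month convention bounds it to [90, 180].
    ``submission_interval`` is the caseload-tiered batch period (days).
    """

    hospital_id: str
    annual_caseload: float
    suspense_wait: float
    submission_interval: float
    pathology_scan_period: float = 1.0
    index_scan_period: float = MONTH_DAYS

    def __post_init__(self) -> None:
        if self.annual_caseload < 0:
            raise ConfigurationError("annual_caseload must be >= 0")
        if not 90.0 <= self.suspense_wait <= 180.0:
            raise ConfigurationError(
                f"suspense_wait {self.suspense_wait} outside the [90, 180] day band"
            )
        if self.pathology_scan_period <= 0 or self.index_scan_period <= 0:
            raise ConfigurationError("scan periods must be > 0")
        if self.submission_interval <= 0:
            raise ConfigurationError("submission_interval must be > 0")


def assign_cancer_type(
    mixture: Sequence[CancerTypeSpec], rng: np.random.Generator
) -> str:
    """Draw one cancer-type label according to the mixture weights."""
    weights = _check_weights(mixture)
    idx = rng.choice(len(mixture), p=weights)
    return mixture[int(idx)].name


def schedule_treatment(
    case: Case,
    spec: CancerTypeSpec,
    p_no_treatment: float,
    rng: np.random.Generator,
) -> Case:
    """Return ``case`` with its treatment-completion time drawn (or absent).

    With probability ``p_no_treatment`` the case receives no recorded
    treatment; otherwise the diagnosis-to-treatment offset is drawn from the
    type's triangular wait distribution, so it lies in
    ``[wait_min, wait_max]``.
    """
    if not 0.0 <= p_no_treatment <= 1.0:
        raise ConfigurationError("p_no_treatment must be in [0, 1]")
    if p_no_treatment > 0 and rng.random() < p_no_treatment:
        return dataclasses.replace(case, t_treatment_complete=None)
    offset = float(sample(spec.wait_distribution(), rng))
    return dataclasses.replace(
        case, t_treatment_complete=case.t_diagnosis + offset
    )


def generate_cases(
    hospital: HospitalProfile,
    horizon: float,
    mixture: Sequence[CancerTypeSpec],
    *,
    p_pathology: float = P_PATHOLOGY_DEFAULT,
    p_external: float = P_EXTERNAL_DEFAULT,
    p_no_treatment: float = P_NO_TREATMENT_DEFAULT,
    rng: np.random.Generator | None = None,
    streams: Mapping[str, np.random.Generator] | None = None,
) -> list[Case]:
    """Generate one hospital's case stream over ``horizon`` days.

    Arrivals follow a homogeneous Poisson process with rate
    ``annual_caseload / 365`` per day, so the expected count is
    ``annual_caseload * horizon / 365``.  Cases are returned sorted by
    diagnosis time.  Draws may come from a single generator (``rng``) or
    from named substreams (``streams`` with keys ``arrivals``, ``types``,
    ``sources``, ``treatment``).
    """
    if horizon <= 0:
        raise ConfigurationError("horizon must be > 0")
    for name, p in (("p_pathology", p_pathology), ("p_external", p_external)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    weights = _check_weights(mixture)
    if streams is None:
        if rng is None:
            raise ConfigurationError("provide rng or streams")
        streams = {k: rng for k in ("arrivals", "types", "sources", "treatment")}

    lam = hospital.annual_caseload * horizon / 365.0
    n = int(streams["arrivals"].poisson(lam))
    if n == 0:
        return []
    # Given the count, homogeneous-Poisson arrival times are iid uniform.
    times = np.sort(streams["arrivals"].uniform(0.0, horizon, n))
    type_idx = streams["types"].choice(len(mixture), size=n, p=weights)
    is_path = streams["sources"].random(n) < p_pathology
    needs_ext = streams["sources"].random(n) < p_external

    specs_by_idx = list(mixture)
    cases: list[Case] = []
    for i in range(n):
        spec = specs_by_idx[int(type_idx[i])]
        case = Case(
            case_id=f"{hospital.hospital_id}-{i:05d}",
            hospital_id=hospital.hospital_id,
            cancer_type=spec.name,
            t_diagnosis=float(times[i]),
            source=PATHOLOGY if is_path[i] else DISEASE_INDEX,
            needs_external=bool(needs_ext[i]),
        )
        cases.append(
            schedule_treatment(case, spec, p_no_treatment, streams["treatment"])
        )
    return cases


def cases_to_frame(cases: Iterable[Case]) -> pd.DataFrame:
    """Case stream as a DataFrame (one row per case, times in days)."""
    return pd.DataFrame(
        [
            {
                "case_id": c.case_id,
                "hospital_id": c.hospital_id,
                "cancer_type": c.cancer_type,
                "t_diagnosis": c.t_diagnosis,
                "source": c.source,
                "needs_external": c.needs_external,
                "t_treatment_complete": c.t_treatment_complete,
            }
            for c in cases
        ],
        columns=[
            "case_id",
            "hospital_id",
            "cancer_type",
            "t_diagnosis",
            "source",
            "needs_external",
            "t_treatment_complete",
        ],
    )


def cases_to_csv(cases: Iterable[Case]) -> str:
    buf = io.StringIO()
    cases_to_frame(cases).to_csv(buf, index=False)
    return buf.getvalue()
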