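"""Run configuration: a single serializable object describing an experiment.

A :class:`RunConfig` pins down everything a run needs — the hospital panel,
the cancer-type mixture, every duration distribution, the workflow
parameters, horizons, replicate count and seed — so that dumping and
re-loading a configuration reproduces the identical experiment.
Validation collects every problem before raising, so a bad file reports
all of its errors at once.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .casegen import (
    CancerTypeSpec,
    ConfigurationError,
    HospitalProfile,
    P_EXTERNAL_DEFAULT,
    P_NO_TREATMENT_DEFAULT,
    P_PATHOLOGY_DEFAULT,
)
from .durations import (
    ABSTRACTION_DEFAULT,
    MONTH_DAYS,
    DistributionSpec,
    SUSPENSE_CALIBRATED,
    ZERO_DELAY,
)
from .workflows import submission_interval

__all__ = ["HospitalSpec", "RunConfig", "load_config", "dump_config",
           "calibrated_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with every validation problem found, newline-separated."""


@dataclass(frozen=True)
class HospitalSpec:
    """Static description of one facility in the panel.

    ``suspense_wait`` may be pinned explicitly; when ``None`` each
    replicate draws the facility's constant wait from the panel-wide
    suspense policy distribution.
    """

    hospital_id: str
    annual_caseload: float
    pathology_scan_period: float = 1.0
    index_scan_period: float = MONTH_DAYS
    suspense_wait: float | None = None

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_HOSPITAL_KEYS = {
    "hospital_id",
    "annual_caseload",
    "pathology_scan_period",
    "index_scan_period",
    "suspense_wait",
}

_CONFIG_KEYS = {
    "seed",
    "horizon_days",
    "replicates",
    "hospitals",
    "mixture",
    "suspense_policy",
    "p_pathology",
    "p_external",
    "p_no_treatment",
    "abstraction",
    "external_delay",
    "fallback_days",
    "notification_enabled",
    "fallback_from",
    "capacity_model",
    "epath_review_period",
    "allow_out_of_band_suspense",
}


@dataclass
class RunConfig:
    hospitals: list[HospitalSpec]
    mixture: list[CancerTypeSpec]
    seed: int = 1
    horizon_days: float = 365.0
    replicates: int = 20
    suspense_policy: DistributionSpec = field(
        default_factory=lambda: SUSPENSE_CALIBRATED
    )
    p_pathology: float = P_PATHOLOGY_DEFAULT
    p_external: float = P_EXTERNAL_DEFAULT
    p_no_treatment: float = P_NO_TREATMENT_DEFAULT
    abstraction: DistributionSpec = field(
        default_factory=lambda: ABSTRACTION_DEFAULT
    )
    external_delay: DistributionSpec = field(default_factory=lambda: ZERO_DELAY)
    fallback_days: float = 180.0
    notification_enabled: bool = True
    fallback_from: str = "diagnosis"
    capacity_model: str = "unlimited"
    epath_review_period: float = 1.0
    allow_out_of_band_suspense: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        if self.horizon_days <= 0:
            problems.append("horizon_days must be > 0")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if not self.hospitals:
            problems.append("hospital panel is empty")
        seen: set[str] = set()
        for h in self.hospitals:
            if h.hospital_id in seen:
                problems.append(f"duplicate hospital_id {h.hospital_id!r}")
            seen.add(h.hospital_id)
            if h.annual_caseload < 0:
                problems.append(f"{h.hospital_id}: annual_caseload must be >= 0")
            if h.pathology_scan_period <= 0 or h.index_scan_period <= 0:
                problems.append(f"{h.hospital_id}: scan periods must be > 0")
            if h.suspense_wait is not None and not self.allow_out_of_band_suspense:
                if not 90.0 <= h.suspense_wait <= 180.0:
                    problems.append(
                        f"{h.hospital_id}: suspense_wait {h.suspense_wait} outside "
                        "[90, 180] (set allow_out_of_band_suspense to override)"
                    )
        weights = sum(s.mixture_weight for s in self.mixture) if self.mixture else 0.0
        if not self.mixture:
            problems.append("mixture is empty")
        elif abs(weights - 1.0) > 1e-9:
            problems.append(f"mixture weights sum to {weights!r}, expected 1")
        for name in ("p_pathology", "p_external", "p_no_treatment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if self.fallback_days <= 0:
            problems.append("fallback_days must be > 0")
        if self.fallback_from not in ("diagnosis", "identification"):
            problems.append(f"unknown fallback_from {self.fallback_from!r}")
        if self.capacity_model not in ("unlimited", "single_registrar"):
            problems.append(f"unknown capacity_model {self.capacity_model!r}")
        if self.epath_review_period <= 0:
            problems.append("epath_review_period must be > 0")
        if not self.allow_out_of_band_suspense:
            lo, hi = self.suspense_policy.support
            if lo < 90.0 - 1e-9 or hi > 180.0 + 1e-9:
                problems.append(
                    f"suspense_policy support [{lo}, {hi}] outside the 90-180 day "
                    "band (set allow_out_of_band_suspense to override)"
                )
        if problems:
            raise ConfigError("\n".join(problems))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "horizon_days": self.horizon_days,
            "replicates": self.replicates,
            "hospitals": [h.to_dict() for h in self.hospitals],
            "mixture": [
                {
                    "name": s.name,
                    "wait_mean": s.wait_mean,
                    "wait_min": s.wait_min,
                    "wait_max": s.wait_max,
                    "mixture_weight": s.mixture_weight,
                }
                for s in self.mixture
            ],
            "suspense_policy": self.suspense_policy.to_dict(),
            "p_pathology": self.p_pathology,
            "p_external": self.p_external,
            "p_no_treatment": self.p_no_treatment,
            "abstraction": self.abstraction.to_dict(),
            "external_delay": self.external_delay.to_dict(),
            "fallback_days": self.fallback_days,
            "notification_enabled": self.notification_enabled,
            "fallback_from": self.fallback_from,
            "capacity_model": self.capacity_model,
            "epath_review_period": self.epath_review_period,
            "allow_out_of_band_suspense": self.allow_out_of_band_suspense,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        problems: list[str] = []
        unknown = set(d) - _CONFIG_KEYS
        if unknown:
            problems.append(f"unknown config keys: {sorted(unknown)}")
        hospitals: list[HospitalSpec] = []
        for i, hd in enumerate(d.get("hospitals", []) or []):
            bad = set(hd) - _HOSPITAL_KEYS
            if bad:
                problems.append(f"hospitals[{i}]: unknown keys {sorted(bad)}")
                continue
            hospitals.append(HospitalSpec(**hd))
        mixture: list[CancerTypeSpec] = []
        for i, md in enumerate(d.get("mixture", []) or []):
            try:
                mixture.append(CancerTypeSpec(**md))
            except (TypeError, ConfigurationError) as exc:
                problems.append(f"mixture[{i}]: {exc}")
        kwargs: dict[str, Any] = {
            k: v
            for k, v in d.items()
            if k in _CONFIG_KEYS and k not in ("hospitals", "mixture")
        }
        for key in ("suspense_policy", "abstraction", "external_delay"):
            if key in kwargs:
                try:
                    kwargs[key] = DistributionSpec.from_dict(kwargs[key])
                except Exception as exc:
                    problems.append(f"{key}: {exc}")
                    del kwargs[key]
        if problems:
            raise ConfigError("\n".join(problems))
        return cls(hospitals=hospitals, mixture=mixture, **kwargs)

    def replace(self, **changes: Any) -> "RunConfig":
        cfg = copy.copy(self)
        for k, v in changes.items():
            if not hasattr(cfg, k):
                raise ConfigError(f"unknown config field {k!r}")
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def build_profile(self, spec: HospitalSpec, suspense_wait: float) -> HospitalProfile:
        return HospitalProfile(
            hospital_id=spec.hospital_id,
            annual_caseload=spec.annual_caseload,
            suspense_wait=suspense_wait,
            submission_interval=submission_interval(spec.annual_caseload),
            pathology_scan_period=spec.pathology_scan_period,
            index_scan_period=spec.index_scan_period,
        )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def calibrated_config(seed: int = 1) -> RunConfig:
    """The shipped calibrated configuration.

    A ten-facility panel (~3,000 cases per year, dominated by monthly-tier
    hospitals), the calibrated suspense band and the calibrated cancer-type
    mixture.  This is the configuration under which the package reproduces
    the published latency comparison.
    """
    path = resources.files("registrysim").joinpath("data/calibrated.yaml")
    with resources.as_file(path) as p:
        cfg = load_config(p)
    cfg.seed = int(seed)
    return cfg
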