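"""Reporting-time summaries and existing-vs-redesigned comparison."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

from .workflows import CaseOutcome

__all__ = ["ReportingSummary", "ComparisonResult", "summarize", "compare",
           "render_table"]


def _times(outcomes) -> np.ndarray:
    """Accept a sequence of CaseOutcome or of raw reporting times."""
    arr = [
        o.reporting_time if isinstance(o, CaseOutcome) else float(o)
        for o in outcomes
    ]
    return np.asarray(arr, dtype=float)


@dataclass(frozen=True)
class ReportingSummary:
    """Sample statistics of per-case reporting time, in days.

    Quantiles interpolate linearly between closest order statistics; the
    standard deviation uses the n-1 denominator and is taken over the
    pooled per-case values.  An empty input yields the ``n == 0`` sentinel
    with NaN statistics.
    """

    n: int
    min: float
    mean: float
    max: float
    p25: float
    p75: float
    sd: float
    variant: str | None = None
    horizon: float | None = None

    @property
    def is_empty(self) -> bool:
        return self.n == 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "variant": self.variant,
            "horizon_days": self.horizon,
            "n": self.n,
            "min": self.min,
            "mean": self.mean,
            "max": self.max,
            "p25": self.p25,
            "p75": self.p75,
            "sd": self.sd,
            "quantile_method": "linear interpolation between order statistics",
            "sd_scope": "per-case, pooled across replicates, ddof=1",
        }


def summarize(
    outcomes: Sequence,
    *,
    variant: str | None = None,
    horizon: float | None = None,
) -> ReportingSummary:
    """Table-style summary of reporting times (n, min, mean, max, p25, p75, sd)."""
    x = _times(outcomes)
    if x.size == 0:
        nan = math.nan
        return ReportingSummary(0, nan, nan, nan, nan, nan, nan, variant, horizon)
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return ReportingSummary(
        n=int(x.size),
        min=float(np.min(x)),
        mean=float(np.mean(x)),
        max=float(np.max(x)),
        p25=float(np.quantile(x, 0.25)),
        p75=float(np.quantile(x, 0.75)),
        sd=sd,
        variant=variant,
        horizon=horizon,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Existing-minus-redesigned contrast in mean reporting time.

    ``mean_difference`` is computed on the pooled per-case reporting times;
    the significance test is Welch's unequal-variance t-test applied to the
    per-replicate mean reporting times (replicates are the independent
    sampling units of a simulation experiment).  With fewer than two
    replicates in either arm the difference is still reported but the test
    is not run.
    """

    mean_difference: float
    test_statistic: float | None
    p_value: float | None
    replicate_means: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "mean_difference_days": self.mean_difference,
            "test": "Welch two-sample t on replicate mean reporting times",
            "test_statistic": self.test_statistic,
            "p_value": self.p_value,
            "replicate_means": self.replicate_means,
        }


def compare(
    outcomes_existing: Sequence[Sequence],
    outcomes_redesigned: Sequence[Sequence],
) -> ComparisonResult:
    """Compare the two arms, each given as a list of per-replicate outcome sets."""
    ex_reps = [_times(rep) for rep in outcomes_existing]
    re_reps = [_times(rep) for rep in outcomes_redesigned]
    ex_all = np.concatenate(ex_reps) if ex_reps else np.array([])
    re_all = np.concatenate(re_reps) if re_reps else np.array([])
    if ex_all.size == 0 or re_all.size == 0:
        raise ValueError("both arms must contain at least one outcome")
    diff = float(np.mean(ex_all) - np.mean(re_all))
    ex_means = [float(np.mean(r)) for r in ex_reps if r.size]
    re_means = [float(np.mean(r)) for r in re_reps if r.size]
    statistic = p_value = None
    if len(ex_means) >= 2 and len(re_means) >= 2:
        if np.var(ex_means) == 0 and np.var(re_means) == 0:
            # Degenerate: no replicate variability; identical means => p=1.
            statistic = 0.0 if np.mean(ex_means) == np.mean(re_means) else math.inf
            p_value = 1.0 if statistic == 0.0 else 0.0
        else:
            res = stats.ttest_ind(ex_means, re_means, equal_var=False)
            statistic = float(res.statistic)
            p_value = float(res.pvalue)
    return ComparisonResult(
        mean_difference=diff,
        test_statistic=statistic,
        p_value=p_value,
        replicate_means={"existing": ex_means, "redesigned": re_means},
    )


def render_table(summaries: Sequence[ReportingSummary]) -> str:
    """Plain-text table of summaries, one block per variant x horizon."""
    lines = [
        f"{'variant':<12} {'horizon':>8} {'n':>7} {'min':>8} {'mean':>8} "
        f"{'max':>8} {'p25':>8} {'p75':>8} {'sd':>7}"
    ]
    for s in summaries:
        if s.is_empty:
            lines.append(f"{s.variant or '-':<12} {s.horizon or 0:>8.0f} "
                         f"{0:>7} {'-':>8} {'-':>8} {'-':>8} {'-':>8} {'-':>8} {'-':>7}")
            continue
        lines.append(
            f"{s.variant or '-':<12} {s.horizon or 0:>8.0f} {s.n:>7} "
            f"{s.min:>8.1f} {s.mean:>8.1f} {s.max:>8.1f} "
            f"{s.p25:>8.1f} {s.p75:>8.1f} {s.sd:>7.1f}"
        )
    return "\n".join(lines)
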