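"""Cohort aggregation (mean ± SEM) and one-tailed paired t-tests vs controls.

Eyes are the analysis unit and treated as independent. Test directions are
fixed a priori — on-vessel and near-bin percentages tested observed >
control, the far bin observed < control, the middle bin two-sided
(reported as twice the smaller one-tailed p) — and recorded in the output
so sign conventions are auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Iterable, Sequence

import numpy as np
from scipy import stats

from .colocalization import EyeResult
from .errors import DegenerateVarianceError, InsufficientDataError

#: metric name -> (attribute path, a-priori test direction)
METRIC_DIRECTIONS: dict[str, str] = {
    "pct_vessel": "greater",
    "pct_near_1_3": "greater",
    "pct_mid_4_6": "two-sided",
    "pct_far_ge7": "less",
}


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample SD with n-1, over sqrt n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("mean_sem requires at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    direction: str


def paired_one_tailed_t(observed: Sequence[float], control: Sequence[float],
                        direction: str = "greater") -> TTestResult:
    """Student's t on per-eye differences with a one-tailed p.

    ``direction='greater'`` tests observed > control; ``'less'`` the
    reverse. Identical differences (zero variance) raise
    :class:`DegenerateVarianceError` rather than reporting a silent p = 0.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    obs = np.asarray(observed, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if obs.shape != ctl.shape:
        raise ValueError("observed and control must have equal length")
    n = obs.size
    if n < 2:
        raise InsufficientDataError("paired t-test requires at least 2 pairs")
    diff = obs - ctl
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("all paired differences are identical")
    t = float(diff.mean() / (sd / math.sqrt(n)))
    df = n - 1
    p = float(stats.t.sf(t, df)) if direction == "greater" else float(stats.t.cdf(t, df))
    return TTestResult(t=t, df=df, p=p, direction=direction)


def unpaired_welch_t(observed: Sequence[float], control: Sequence[float],
                     direction: str = "greater") -> TTestResult:
    """Welch's unequal-variance t, for sensitivity analysis only."""
    alt = direction if direction in ("greater", "less") else "two-sided"
    res = stats.ttest_ind(observed, control, equal_var=False, alternative=alt)
    return TTestResult(t=float(res.statistic), df=int(math.floor(res.df)),
                       p=float(res.pvalue), direction=direction)


@dataclass(frozen=True)
class MetricSummary:
    metric: str
    direction: str
    observed_mean: float
    observed_sem: float
    control_mean: float
    control_sem: float
    mean_diff: float
    sem_diff: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "metric": self.metric,
            "direction": self.direction,
            "observed_mean": self.observed_mean,
            "observed_sem": self.observed_sem,
            "control_mean": self.control_mean,
            "control_sem": self.control_sem,
            "mean_diff": self.mean_diff,
            "sem_diff": self.sem_diff,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class CohortSummary:
    n_eyes: int
    metrics: dict[str, MetricSummary]
    alpha: float = 0.05

    def to_dict(self) -> dict[str, Any]:
        return {"n_eyes": self.n_eyes, "alpha": self.alpha,
                "metrics": {k: v.to_dict() for k, v in self.metrics.items()}}

    def format_text(self) -> str:
        lines = [f"Cohort of {self.n_eyes} eyes (alpha = {self.alpha})"]
        for m in self.metrics.values():
            star = " *" if m.p_value < self.alpha else ""
            lines.append(
                f"  {m.metric:<14} observed {m.observed_mean:5.1f} ± {m.observed_sem:.1f}%"
                f"  control {m.control_mean:5.1f} ± {m.control_sem:.1f}%"
                f"  diff {m.mean_diff:+.1f} ± {m.sem_diff:.2f}"
                f"  t({m.degrees_of_freedom}) = {m.t_statistic:.2f}"
                f"  p = {m.p_value:.4g} [{m.direction}]{star}")
        return "\n".join(lines)


def _metric_values(eyes: Sequence[EyeResult], metric: str) -> tuple[np.ndarray, np.ndarray]:
    obs = np.array([getattr(e.observed, metric) for e in eyes], dtype=float)
    ctl = np.array([getattr(e.control, metric) for e in eyes], dtype=float)
    return obs, ctl


def summarize_cohort(eyes: Sequence[EyeResult], alpha: float = 0.05,
                     paired: bool = True) -> CohortSummary:
    """Per-metric cohort summary with the a-priori one-tailed tests.

    Eyes whose value for a metric is undefined (e.g. no stroma points, so no
    bin percentages) are dropped pairwise for that metric.
    """
    eyes = list(eyes)
    if len(eyes) < 2:
        raise InsufficientDataError("cohort summary requires at least 2 eyes")
    metrics: dict[str, MetricSummary] = {}
    for metric, direction in METRIC_DIRECTIONS.items():
        obs, ctl = _metric_values(eyes, metric)
        ok = ~(np.isnan(obs) | np.isnan(ctl))
        obs, ctl = obs[ok], ctl[ok]
        if obs.size < 2:
            raise InsufficientDataError(f"fewer than 2 eyes with defined {metric}")
        om, os_ = mean_sem(obs)
        cm, cs = mean_sem(ctl)
        dm, ds = mean_sem(obs - ctl)
        if direction == "two-sided":
            res = paired_one_tailed_t(obs, ctl, "greater")
            p = 2.0 * min(res.p, 1.0 - res.p)
        else:
            res = paired_one_tailed_t(obs, ctl, direction)
            p = res.p
        metrics[metric] = MetricSummary(
            metric=metric, direction=direction,
            observed_mean=om, observed_sem=os_, control_mean=cm, control_sem=cs,
            mean_diff=dm, sem_diff=ds, t_statistic=res.t,
            degrees_of_freedom=res.df, p_value=p)
    return CohortSummary(n_eyes=len(eyes), metrics=metrics, alpha=alpha)
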