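"""Per-subject PK metrics and population summaries.

Conventions match the reporting style of phenotype-stratified population
simulations: linear trapezoidal AUC on the simulation output grid, AUC
windows tagged explicitly (0-24, 0-12, 0-96, 0-inf), Cmin defined as the
end-of-interval (pre-dose) trough, and population statistics as arithmetic
mean, SD, CV% and empirical 5th/95th percentiles pooled over all subjects
(trial structure retained for per-trial means only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ConcentrationProfile, PopulationProfiles

__all__ = [
    "auc_trapezoid",
    "auc_to_infinity",
    "trough_and_peak",
    "summarize",
    "fold_ratio",
    "PKSummary",
    "population_metrics",
]


class MetricValidationError(ValueError):
    pass


class ExtrapolationError(RuntimeError):
    pass


def _times_conc(profile):
    if isinstance(profile, ConcentrationProfile):
        return profile.times, np.atleast_2d(profile.c_plasma)
    if isinstance(profile, PopulationProfiles):
        return profile.times, profile.conc
    raise TypeError(type(profile))


def auc_trapezoid(profile, t0: float, t1: float) -> np.ndarray | float:
    """Linear trapezoidal AUC over [t0, t1] on the output grid (ng.h/mL)."""
    times, conc = _times_conc(profile)
    if t0 >= t1:
        raise MetricValidationError("need t0 < t1")
    if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
        raise MetricValidationError(
            f"window [{t0}, {t1}] outside profile span [{times[0]}, {times[-1]}]"
        )
    mask = (times >= t0 - 1e-9) & (times <= t1 + 1e-9)
    out = np.trapezoid(conc[:, mask], times[mask], axis=1)
    return float(out[0]) if out.size == 1 and conc.shape[0] == 1 else out


def _lambda_z_single(times, conc):
    """Terminal log-linear rate constant from the last third of post-Tmax points."""
    imax = int(np.argmax(conc))
    post = np.arange(imax + 1, times.size)
    post = post[conc[post] > 0]
    if post.size < 3:
        raise ExtrapolationError("need >= 3 positive terminal points past Tmax")
    tail = post[-max(3, post.size // 3) :]
    y = np.log(conc[tail])
    if np.any(np.diff(y) > 1e-12):
        raise ExtrapolationError("terminal phase is not monotonically declining")
    slope, _ = np.polyfit(times[tail], y, 1)
    lam = -slope
    if lam <= 0:
        raise ExtrapolationError("non-positive terminal slope")
    return lam


def auc_to_infinity(profile, warn_frac: float = 0.20):
    """Single-dose AUC(0-inf): trapezoid to t_last plus C_last/lambda_z.

    lambda_z comes from an unweighted log-linear fit over the last third of
    the post-Tmax points. Warns when the extrapolated fraction exceeds
    ``warn_frac`` (standard noncompartmental practice).
    """
    times, conc = _times_conc(profile)
    out = np.empty(conc.shape[0])
    for i in range(conc.shape[0]):
        lam = _lambda_z_single(times, conc[i])
        auc_t = np.trapezoid(conc[i], times)
        extra = conc[i, -1] / lam
        if extra / (auc_t + extra) > warn_frac:
            warnings.warn(
                f"extrapolated AUC fraction {extra / (auc_t + extra):.1%} exceeds "
                f"{warn_frac:.0%} for subject {i}",
                stacklevel=2,
            )
        out[i] = auc_t + extra
    return float(out[0]) if out.size == 1 else out


def lambda_z(profile):
    """Terminal elimination rate constant(s), 1/h."""
    times, conc = _times_conc(profile)
    lams = np.array([_lambda_z_single(times, c) for c in conc])
    return float(lams[0]) if lams.size == 1 else lams


def trough_and_peak(window_profile):
    """(Cmin, Cmax) over a steady-state dosing-interval window.

    Cmax is the maximum over the window; Cmin is the concentration at the
    window end, i.e. the pre-dose trough.
    """
    _, conc = _times_conc(window_profile)
    cmin = conc[:, -1]
    cmax = conc.max(axis=1)
    if conc.shape[0] == 1:
        return float(cmin[0]), float(cmax[0])
    return cmin, cmax


@dataclass(frozen=True)
class PKSummary:
    """Population summary of per-subject PK metrics."""

    per_subject: pd.DataFrame   # one row per subject, incl. 'trial'
    stats: pd.DataFrame         # index: metric; cols: mean, sd, cv_pct, p5, p95
    per_trial: pd.DataFrame     # trial-level means
    n_subjects: int
    n_trials: int
    auc_window: str = ""        # e.g. "0-24", "0-12", "0-96", "0-inf"

    def mean(self, metric: str) -> float:
        return float(self.stats.loc[metric, "mean"])

    def cv_pct(self, metric: str) -> float:
        return float(self.stats.loc[metric, "cv_pct"])


def summarize(
    per_subject: pd.DataFrame, auc_window: str = ""
) -> PKSummary:
    """Population statistics (mean, SD, CV%, 5th/95th percentiles).

    ``per_subject`` holds one row per subject with a ``trial`` column plus
    numeric metric columns (e.g. cmax, cmin, auc).
    """
    if len(per_subject) < 2:
        raise MetricValidationError("need >= 2 subjects to summarize")
    if "trial" not in per_subject:
        raise MetricValidationError("per-subject frame must carry a 'trial' column")
    metrics = [c for c in per_subject.columns if c != "trial"]
    rows = {}
    for mcol in metrics:
        v = per_subject[mcol].to_numpy(dtype=float)
        mean = v.mean()
        sd = v.std(ddof=1)
        rows[mcol] = {
            "mean": mean,
            "sd": sd,
            "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
            "p5": np.percentile(v, 5),
            "p95": np.percentile(v, 95),
        }
    stats = pd.DataFrame(rows).T[["mean", "sd", "cv_pct", "p5", "p95"]]
    per_trial = per_subject.groupby("trial")[metrics].mean()
    return PKSummary(
        per_subject=per_subject,
        stats=stats,
        per_trial=per_trial,
        n_subjects=len(per_subject),
        n_trials=per_subject["trial"].nunique(),
        auc_window=auc_window,
    )


def fold_ratio(summary_a: PKSummary, summary_b: PKSummary, metric: str) -> float:
    """Ratio of population means of ``metric``, A over B."""
    if metric.startswith("auc") and summary_a.auc_window != summary_b.auc_window:
        raise MetricValidationError(
            f"AUC windows differ: {summary_a.auc_window!r} vs {summary_b.auc_window!r}"
        )
    return summary_a.mean(metric) / summary_b.mean(metric)


def population_metrics(
    window: PopulationProfiles,
    trials: np.ndarray,
    auc_window: str,
    auc_t1: float | None = None,
) -> PKSummary:
    """Cmax/Cmin/AUC summary for a steady-state window of a population."""
    cmin, cmax = window.conc[:, -1], window.conc.max(axis=1)
    t1 = auc_t1 if auc_t1 is not None else float(window.times[-1])
    auc = auc_trapezoid(window, 0.0, t1)
    per_subject = pd.DataFrame(
        {"trial": trials, "cmax": cmax, "cmin": cmin, "auc": np.atleast_1d(auc)}
    )
    return summarize(per_subject, auc_window=auc_window)
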