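"""Degradation-rate estimation and phase labeling for batch trajectories.

Rates are local ordinary-least-squares slopes of concentration against
time over a short index window centered on each sampling day (weekly
sampling makes wide windows smear phase boundaries, so the default
window is five points).  The rate-vs-hydrogen correlation quantifies
thermodynamic throttling of acid oxidation by the methanogenic partner:
the H2 stoichiometric coefficients (4 for acetate, 3 for propionate
oxidation) make dG steeply dependent on pH2, so high pH2 should slow
degradation (a negative Pearson r against degradation rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

LAG = "lag"
DEG1 = "degradation-1"
PLATEAU = "plateau"
DEG2 = "degradation-2"


class DynamicsError(ValueError):
    pass


@dataclass
class RatePoint:
    """Local slope at one sampling day.

    ``rate`` keeps the mathematical sign of the slope (consumption is
    negative); ``r2`` is NaN for a perfectly constant window.
    """

    day: float
    rate: float  # mM/day
    window: list[float]  # days used in the fit
    r2: float


def local_slope(
    series: list[tuple[float, float]],
    focal_day: float,
    window_halfwidth: int = 2,
) -> RatePoint:
    """OLS slope over the index window centered on ``focal_day``.

    The window spans ``window_halfwidth`` points on each side of the
    focal day and is truncated at the ends of the series.
    """
    days = [d for d, _ in series]
    if focal_day not in days:
        raise DynamicsError(f"focal day {focal_day} not in series")
    i = days.index(focal_day)
    lo = max(0, i - window_halfwidth)
    hi = min(len(series), i + window_halfwidth + 1)
    window = series[lo:hi]
    if len(window) < 2:
        raise DynamicsError("need at least 2 points in the fitting window")
    x = np.array([d for d, _ in window], dtype=float)
    y = np.array([c for _, c in window], dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    r2 = math.nan if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    return RatePoint(day=focal_day, rate=slope, window=list(x), r2=r2)


def rate_series(
    series: list[tuple[float, float]], window_halfwidth: int = 2
) -> list[RatePoint]:
    """Local slope at every sampling day."""
    return [local_slope(series, d, window_halfwidth) for d, _ in series]


def rate_pressure_correlation(
    rates: list[RatePoint],
    pressures: list[tuple[float, float]],
    negate_consumption: bool = True,
) -> tuple[float, float, int]:
    """Pearson correlation of H2 partial pressure with degradation rate.

    Days present in both inputs are matched.  With the default sign
    convention, consumption slopes are negated so that a positive value
    means faster degradation; a negative r then reads "high pH2, slow
    degradation".  Returns (r, two-sided p, n).
    """
    rate_by_day = {rp.day: rp.rate for rp in rates}
    pairs = [(p, rate_by_day[d]) for d, p in pressures if d in rate_by_day]
    if len(pairs) < 3:
        raise DynamicsError("need at least 3 matched days for a correlation")
    p = np.array([a for a, _ in pairs])
    r_ = np.array([b for _, b in pairs])
    if negate_consumption:
        r_ = -r_
    if np.ptp(p) == 0 or np.ptp(r_) == 0:
        raise DynamicsError("zero variance in rates or pressures")
    res = stats.pearsonr(p, r_)
    return float(res.statistic), float(res.pvalue), len(pairs)


def label_phases(
    series: list[tuple[float, float]],
    rate_threshold: float = 0.5,
    min_run: int = 2,
    window_halfwidth: int = 2,
) -> list[tuple[float, str]]:
    """Partition a concentration trajectory into lag / degradation /
    plateau / second-degradation phases.

    A point is "active" when |local slope| >= ``rate_threshold`` mM/day.
    The initial inactive run is the lag; active runs are degradation
    phases (first and second); interior inactive runs are plateaus.
    Runs shorter than ``min_run`` are merged into the preceding label.
    This labeling is descriptive plumbing, never used in thermodynamic
    computations; a trailing inactive run is labeled "plateau".
    """
    if not series:
        return []
    rates = rate_series(series, window_halfwidth)
    active = [abs(rp.rate) >= rate_threshold for rp in rates]

    # run-length encode, merging short runs into the previous run
    runs: list[tuple[bool, int]] = []
    for a in active:
        if runs and runs[-1][0] == a:
            runs[-1] = (a, runs[-1][1] + 1)
        else:
            runs.append((a, 1))
    merged: list[tuple[bool, int]] = []
    for a, n in runs:
        if merged and n < min_run:
            prev_a, prev_n = merged[-1]
            merged[-1] = (prev_a, prev_n + n)
        elif merged and merged[-1][0] == a:
            merged[-1] = (a, merged[-1][1] + n)
        else:
            merged.append((a, n))

    labels: list[str] = []
    n_deg = 0
    for idx, (a, n) in enumerate(merged):
        if a:
            n_deg += 1
            lab = DEG1 if n_deg == 1 else DEG2
        else:
            lab = LAG if idx == 0 else PLATEAU
        labels.extend([lab] * n)
    return [(d, lab) for (d, _), lab in zip(series, labels)]
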