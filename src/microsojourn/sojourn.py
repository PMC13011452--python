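"""Sojourn, residence and return statistics of rescaled abundance series.

A *sojourn trajectory* is a maximal run of consecutive observations in
which the deviation y(t) - ybar keeps one sign, bounded on both sides by
an observed crossing.  Runs touching either end of a series are discarded
(the return to steady state was not observed), which also removes the
length-biased "inspection" runs and leaves the interior run-length
distribution unbiased.

Gap handling for near-daily sampling: a sampling gap of up to
``max_gap_days`` is bridged when the sign is unchanged on both sides; a
sign change across any gap longer than one day is an unobserved crossing
and breaks the series; a day dropped because its count was zero always
breaks the series (the taxon's state there is unknown on the log scale).
T counts observations, not calendar days.

Residence and return times are the presence/absence analogues: interior
maximal runs of non-zero and zero counts respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptySummaryError, InsufficientDataError, MissingTError
from .inference import AbundanceSeries, RescaledSeries

__all__ = [
    "SojournTrajectory",
    "RunLengthSummary",
    "ScalingFit",
    "extract_sojourns",
    "sojourn_time_distribution",
    "run_length_summary",
    "mean_deviation_profile",
    "fit_alpha",
    "residence_return_times",
    "mean_sojourn_time",
    "interior_run_bounds",
]


@dataclass(frozen=True)
class SojournTrajectory:
    """One interior same-sign excursion of y(t) - ybar."""

    asv_id: str
    sign: int                 # +1 above the time-averaged mean, -1 below
    start_day: int
    end_day: int
    T: int                    # duration in observations
    H: float                  # peak |y - ybar| within the run
    deviations: np.ndarray    # ordered y - ybar values inside the run
    area: float = 0.0         # sum |y - ybar|, auxiliary height variant
    host_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.T != len(self.deviations) or self.T < 1:
            raise ValueError("T must equal len(deviations) >= 1")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if np.any(np.sign(self.deviations) != self.sign):
            raise ValueError("all deviations must share the trajectory sign")


@dataclass(frozen=True)
class RunLengthSummary:
    """Empirical pmf of run lengths of one kind (sojourn/residence/return)."""

    kind: str
    support: np.ndarray       # sorted distinct T values
    pmf: np.ndarray
    mean_T: float
    n_runs: int

    def __post_init__(self) -> None:
        if abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValueError("pmf must sum to 1")

    def as_dict(self) -> dict[int, float]:
        return {int(t): float(p) for t, p in zip(self.support, self.pmf)}


@dataclass(frozen=True)
class ScalingFit:
    """Log-log slope of the mean within-sojourn deviation against T."""

    alpha: float
    slope_ci: tuple[float, float]
    n_points: int
    t_values: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    profile_means: np.ndarray = field(default_factory=lambda: np.array([]))


# --------------------------------------------------------------------------
# Run scanning core
# --------------------------------------------------------------------------

def interior_run_bounds(
    days: np.ndarray,
    dev: np.ndarray,
    *,
    missing_days: np.ndarray | None = None,
    max_gap_days: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Locate interior same-sign runs of ``dev`` along ``days``.

    Returns (starts, ends, signs) as index arrays into ``dev``: run k spans
    ``dev[starts[k]:ends[k]]`` with sign ``signs[k]``.  A run is interior
    when the observation on each side exists within the same unbroken
    stretch and carries a different sign (an observed crossing); exact
    zeros of ``dev`` terminate runs and start none.
    """
    days = np.asarray(days)
    dev = np.asarray(dev, dtype=float)
    n = dev.size
    if n < 3:
        return (np.array([], int), np.array([], int), np.array([], int))
    sgn = np.sign(dev).astype(int)

    gap = np.diff(days)
    hard = gap > max_gap_days
    # unobserved crossing: sign differs across a multi-day gap
    hard |= (gap > 1) & (sgn[1:] != sgn[:-1])
    if missing_days is not None and len(missing_days):
        md = np.asarray(missing_days)
        lo = np.searchsorted(md, days[:-1], side="right")
        hi = np.searchsorted(md, days[1:], side="left")
        hard |= hi > lo  # a zero-count day falls inside the gap

    boundary = (sgn[1:] != sgn[:-1]) | hard
    starts = np.concatenate([[0], np.flatnonzero(boundary) + 1])
    ends = np.concatenate([starts[1:], [n]])
    signs = sgn[starts]

    # interior: flanked on both sides by an in-stretch observed crossing
    ok_left = np.zeros(starts.size, bool)
    ok_right = np.zeros(starts.size, bool)
    ok_left[1:] = ~hard[starts[1:] - 1]
    ok_right[:-1] = ~hard[ends[:-1] - 1]
    keep = ok_left & ok_right & (signs != 0)
    return starts[keep], ends[keep], signs[keep]


def extract_sojourns(
    series: RescaledSeries, max_gap_days: int = 2
) -> list[SojournTrajectory]:
    """Extract all interior sojourn trajectories from a rescaled series."""
    if len(series.y) < 3:
        raise InsufficientDataError(
            f"{series.asv_id}: need >= 3 retained observations"
        )
    dev = series.deviations
    starts, ends, signs = interior_run_bounds(
        series.days, dev,
        missing_days=series.missing_days, max_gap_days=max_gap_days,
    )
    out = []
    for s, e, sg in zip(starts, ends, signs):
        d = dev[s:e]
        out.append(SojournTrajectory(
            asv_id=series.asv_id, sign=int(sg),
            start_day=int(series.days[s]), end_day=int(series.days[e - 1]),
            T=int(e - s), H=float(np.abs(d).max()), deviations=d,
            area=float(np.abs(d).sum()), host_id=series.host_id,
        ))
    return out


def run_length_summary(lengths, kind: str) -> RunLengthSummary:
    """Empirical pmf, mean and count of a collection of run lengths."""
    lengths = np.asarray(list(lengths), dtype=int)
    if lengths.size == 0:
        raise EmptySummaryError(f"no {kind} runs to summarise")
    support, counts = np.unique(lengths, return_counts=True)
    pmf = counts / counts.sum()
    return RunLengthSummary(
        kind=kind, support=support, pmf=pmf,
        mean_T=float((support * pmf).sum()), n_runs=int(lengths.size),
    )


def sojourn_time_distribution(
    trajectories: list[SojournTrajectory],
) -> RunLengthSummary:
    """Pool sojourn durations into the empirical p(T)."""
    return run_length_summary([t.T for t in trajectories], "sojourn")


# --------------------------------------------------------------------------
# Within-sojourn deviation profiles and the T^alpha scaling
# --------------------------------------------------------------------------

def _folded(trajectories, T: int) -> np.ndarray:
    rows = [t.sign * t.deviations for t in trajectories if t.T == T]
    if not rows:
        raise MissingTError(f"no trajectory of duration T={T}")
    return np.asarray(rows)


def mean_deviation_profile(
    trajectories: list[SojournTrajectory], T: int
) -> np.ndarray:
    """Position-wise mean deviation over all trajectories of duration T.

    Above- and below-mean trajectories are folded by multiplying their
    deviations by the trajectory sign, so the profile is positive.
    """
    return _folded(trajectories, T).mean(axis=0)


def fit_alpha(
    trajectories: list[SojournTrajectory],
    t_values: list[int] | None = None,
    *,
    min_per_t: int = 20,
    n_boot: int = 200,
    seed: int = 0,
) -> ScalingFit:
    """Least-squares exponent alpha of mean sojourn deviation against T.

    For each duration T the profile magnitude is the mean over positions of
    the folded mean-deviation profile; alpha is the slope of its logarithm
    against ln T.  The confidence interval is a stratified bootstrap over
    trajectories within each T class (2.5/97.5 percentiles).
    """
    counts: dict[int, int] = {}
    for t in trajectories:
        counts[t.T] = counts.get(t.T, 0) + 1
    if t_values is None:
        t_values = sorted(T for T, c in counts.items() if c >= min_per_t)
    else:
        t_values = sorted(t_values)
        short = [T for T in t_values if counts.get(T, 0) < min_per_t]
        if short:
            raise InsufficientDataError(
                f"fewer than {min_per_t} trajectories for T in {short}"
            )
    if len(t_values) < 3:
        raise InsufficientDataError(
            f"need profiles for >= 3 distinct T, have {len(t_values)}"
        )
    folded = {T: _folded(trajectories, T) for T in t_values}
    lt = np.log(np.asarray(t_values, float))

    def slope(mats: dict[int, np.ndarray]) -> float:
        m = np.array([mats[T].mean(axis=0).mean() for T in t_values])
        return float(np.polyfit(lt, np.log(m), 1)[0])

    alpha = slope(folded)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        resampled = {
            T: mat[rng.integers(mat.shape[0], size=mat.shape[0])]
            for T, mat in folded.items()
        }
        boot[b] = slope(resampled)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    means = np.array([folded[T].mean(axis=0).mean() for T in t_values])
    return ScalingFit(alpha=alpha, slope_ci=ci, n_points=len(t_values),
                      t_values=np.asarray(t_values, int), profile_means=means)


# --------------------------------------------------------------------------
# Presence/absence run lengths
# --------------------------------------------------------------------------

def residence_return_times(
    series: AbundanceSeries, max_gap_days: int = 2
) -> tuple[RunLengthSummary | None, RunLengthSummary | None]:
    """Interior runs of presence (residence) and absence (return) of a taxon.

    Operates on the raw count series including its zeros; boundary runs are
    discarded as for sojourns.  Either summary is None when no interior run
    of that kind exists.
    """
    presence = np.where(series.counts > 0, 1.0, -1.0)
    starts, ends, signs = interior_run_bounds(
        series.days, presence, max_gap_days=max_gap_days
    )
    lengths = ends - starts
    res = lengths[signs > 0]
    ret = lengths[signs < 0]
    residence = run_length_summary(res, "residence") if res.size else None
    ret_summary = run_length_summary(ret, "return") if ret.size else None
    return residence, ret_summary


def mean_sojourn_time(
    trajectories: list[SojournTrajectory], n_min: int = 5
) -> tuple[pd.Series, dict[str, str]]:
    """Per-taxon mean sojourn time <T>; taxa with < n_min trajectories excluded."""
    by_asv: dict[str, list[int]] = {}
    for t in trajectories:
        by_asv.setdefault(t.asv_id, []).append(t.T)
    means = {}
    excluded = {}
    for asv, ts in sorted(by_asv.items()):
        if len(ts) < n_min:
            excluded[asv] = f"only {len(ts)} trajectories (< {n_min})"
        else:
            means[asv] = float(np.mean(ts))
    return pd.Series(means, name="mean_T", dtype=float), excluded
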