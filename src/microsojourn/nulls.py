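"""Temporal-structure-free null models and the divergence statistic.

Two nulls destroy temporal ordering while preserving the marginal
abundance distribution:

* the **gamma i.i.d. null** draws abundances independently from the fitted
  stationary gamma and pushes them through the same sequencing observation
  (Poisson reads at the empirical depths), rescaling and run-extraction
  machinery as the data, so it differs from the data only in temporal
  ordering and the stationarity assumption;
* the **permutation null** shuffles the observed y values over the observed
  days, preserving the empirical marginal exactly.

Run-length distributions are compared with a Kullback-Leibler divergence
D(empirical || null) computed on the union support after pooling the null's
upper tail into one bin and epsilon-smoothing the null.  A calibration band
(mean +/- sd of the divergence of same-size resamples of the null against
itself) says how large a divergence pure sampling noise produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptySummaryError, InsufficientDataError
from .inference import AbundanceSeries, GammaFit, RescaledSeries, rescale_log
from .sojourn import RunLengthSummary, interior_run_bounds, run_length_summary

__all__ = [
    "DivergenceResult",
    "gamma_iid_null",
    "permutation_null",
    "distribution_divergence",
    "compare_quantities",
]

EPSILON = 1e-6


@dataclass(frozen=True)
class DivergenceResult:
    """Divergence of an empirical run-length pmf from a null pmf."""

    kind: str                 # sojourn | residence | return
    divergence: float
    null_kind: str            # gamma_iid | permutation
    n_null_replicates: int
    null_mean: float          # calibration: null resampled against itself
    null_sd: float

    def __post_init__(self) -> None:
        if self.divergence < -1e-12:
            raise ValueError("divergence must be non-negative")

    @property
    def exceeds_band(self) -> bool:
        """True when the divergence exceeds null_mean + 3 * null_sd."""
        return bool(self.divergence > self.null_mean + 3.0 * self.null_sd)


# --------------------------------------------------------------------------
# Nulls
# --------------------------------------------------------------------------

def _run_lengths(days, y, missing_days=None, max_gap_days: int = 2) -> np.ndarray:
    dev = y - y.mean()
    starts, ends, _ = interior_run_bounds(
        days, dev, missing_days=missing_days, max_gap_days=max_gap_days
    )
    return ends - starts


def gamma_iid_null(
    fit: GammaFit,
    n_timepoints: int,
    depths: np.ndarray,
    n_replicates: int = 20,
    seed: int = 0,
    *,
    max_gap_days: int = 2,
) -> RunLengthSummary:
    """Sojourn-time pmf when abundances are i.i.d. stationary-gamma draws.

    Each replicate draws gamma abundances with the fitted mean and CV,
    samples Poisson reads at the given depths, log-rescales the non-zero
    days and extracts interior runs exactly as for the data; run lengths
    are pooled over replicates.
    """
    if n_timepoints < 10:
        raise InsufficientDataError("need >= 10 timepoints for the null")
    depths = np.asarray(depths)
    if depths.size != n_timepoints:
        depths = np.resize(depths, n_timepoints)
    rng = np.random.default_rng(seed)
    shape = fit.beta
    scale = fit.mean / fit.beta
    days = np.arange(n_timepoints)
    lengths = []
    for _ in range(n_replicates):
        x = rng.gamma(shape, scale, size=n_timepoints)
        counts = rng.poisson(depths * x)
        keep = counts > 0
        if keep.sum() < 3:
            continue
        y = np.log(counts[keep] / depths[keep])
        lengths.append(_run_lengths(days[keep], y, days[~keep], max_gap_days))
    if not lengths:
        raise EmptySummaryError("gamma i.i.d. null produced no interior runs")
    return run_length_summary(np.concatenate(lengths), "sojourn")


def permutation_null(
    series: RescaledSeries,
    n_permutations: int = 200,
    seed: int = 0,
    *,
    max_gap_days: int = 2,
) -> RunLengthSummary:
    """Sojourn-time pmf after shuffling y over the observed days.

    Missing days stay missing; only the assignment of observed values to
    observed days is permuted, so the marginal distribution of y (and hence
    the above/below-mean fraction) is preserved exactly.
    """
    if len(series.y) < 10:
        raise InsufficientDataError("need >= 10 retained observations")
    rng = np.random.default_rng(seed)
    lengths = []
    y = series.y.copy()
    for _ in range(n_permutations):
        rng.shuffle(y)
        lengths.append(
            _run_lengths(series.days, y, series.missing_days, max_gap_days)
        )
    if not any(len(l) for l in lengths):
        raise EmptySummaryError("permutation null produced no interior runs")
    return run_length_summary(np.concatenate(lengths), "sojourn")


# --------------------------------------------------------------------------
# Divergence
# --------------------------------------------------------------------------

def _pool_tail(support, p, t_cut):
    head = support <= t_cut
    out_s = np.append(support[head], t_cut + 1)
    out_p = np.append(p[head], p[~head].sum())
    return out_s, out_p


def _aligned(p_emp: RunLengthSummary, p_null: RunLengthSummary,
             tail_quantile: float):
    # pool everything above the null's tail quantile into one overflow bin
    cdf = np.cumsum(p_null.pmf)
    t_cut = int(p_null.support[np.searchsorted(cdf, tail_quantile)])
    se, pe = _pool_tail(p_emp.support, p_emp.pmf, t_cut)
    sn, pn = _pool_tail(p_null.support, p_null.pmf, t_cut)
    support = np.union1d(se, sn)
    e = np.zeros(support.size)
    n = np.zeros(support.size)
    e[np.searchsorted(support, se)] = pe
    n[np.searchsorted(support, sn)] = pn
    occupied = (e > 0) | (n > 0)
    return e[occupied], n[occupied]


def _kl(p: np.ndarray, q: np.ndarray, eps: float) -> float:
    # pseudo-mass only where the null is empty: identical pmfs then give
    # exactly zero, and unseen support stays finite
    q = np.where(q > 0, q, eps)
    q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _divergence(p: np.ndarray, q: np.ndarray, eps: float, measure: str) -> float:
    if measure == "kl":
        return _kl(p, q, eps)
    if measure == "js":
        m = 0.5 * (p + q)
        return 0.5 * _kl(p, m, eps) + 0.5 * _kl(q, m, eps)
    raise ValueError(f"unknown divergence measure {measure!r}")


def distribution_divergence(
    p_emp: RunLengthSummary,
    p_null: RunLengthSummary,
    *,
    eps: float = EPSILON,
    tail_quantile: float = 0.99,
    measure: str = "kl",
    null_kind: str = "permutation",
    n_boot: int = 100,
    seed: int = 0,
) -> DivergenceResult:
    """KL (or Jensen-Shannon) divergence of an empirical pmf from a null pmf.

    The null receives pseudo-mass ``eps`` in its empty bins and is
    renormalised, and T
    values above its ``tail_quantile`` are pooled into one bin, stabilising
    the epsilon-dependent tail.  With ``n_boot > 0`` the calibration draws
    ``p_emp.n_runs`` samples from the null pmf ``n_boot`` times and reports
    the mean and sd of their divergence from the null: the size of
    divergence expected from sampling noise alone.
    """
    e, n = _aligned(p_emp, p_null, tail_quantile)
    div = _divergence(e, n, eps, measure)
    null_mean = null_sd = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        sims = np.empty(n_boot)
        for b in range(n_boot):
            samp = rng.multinomial(p_emp.n_runs, n / n.sum()) / p_emp.n_runs
            sims[b] = _divergence(samp, n, eps, measure)
        null_mean = float(sims.mean())
        null_sd = float(sims.std(ddof=1))
    return DivergenceResult(
        kind=p_emp.kind, divergence=div, null_kind=null_kind,
        n_null_replicates=n_boot, null_mean=null_mean, null_sd=null_sd,
    )


def compare_quantities(
    host_results: dict[str, dict[str, dict[str, tuple[RunLengthSummary, RunLengthSummary]]]],
    **divergence_kwargs,
) -> pd.DataFrame:
    """Tabulate divergences for sojourn/residence/return runs per host.

    ``host_results[host][kind][null_kind] = (empirical, null)`` summaries.
    The returned table has one row per (host, kind, null_kind) with the
    divergence, its calibration band, an ``exceeds_band`` flag, and a
    per-(host, null_kind) ``sojourn_greatest`` flag marking whether the
    sojourn divergence exceeds both the residence and return divergences.
    """
    rows = []
    for host, kinds in host_results.items():
        for kind, nulls in kinds.items():
            for null_kind, (emp, null) in nulls.items():
                r = distribution_divergence(
                    emp, null, null_kind=null_kind, **divergence_kwargs
                )
                rows.append({
                    "host_id": host, "kind": kind, "null_kind": null_kind,
                    "divergence": r.divergence, "null_mean": r.null_mean,
                    "null_sd": r.null_sd, "exceeds_band": r.exceeds_band,
                })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    flags = []
    for _, row in df.iterrows():
        grp = df[(df.host_id == row.host_id) & (df.null_kind == row.null_kind)]
        soj = grp[grp.kind == "sojourn"]["divergence"]
        others = grp[grp.kind != "sojourn"]["divergence"]
        flags.append(
            bool(len(soj)) and (others.empty or float(soj.iloc[0]) > others.max())
        )
    df["sojourn_greatest"] = flags
    return df
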