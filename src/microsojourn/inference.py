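"""Sampling-aware inference of per-taxon abundance statistics.

A taxon's relative abundance across time is modelled as gamma distributed
(the stationary abundance fluctuation distribution of the SLM) and its
reads as Poisson given the latent abundance and the sample's sequencing
depth.  Integrating out the latent abundance gives a negative-binomial
marginal for the counts,

    n_t ~ NB(mean = N_t * xbar, shape = beta),   beta = 1 / CV^2,

which is maximised jointly in (xbar, CV).  This "sampling-aware" likelihood
corrects the upward bias that naive moment estimates of the CV suffer when
the expected count N_t * xbar is small.

The module also builds the log-rescaled series y(t) = ln(x(t)/xbar) whose
deviations from the time average ybar define sojourn trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    FitFailureError,
    InsufficientDataError,
    NoSignalError,
    ParameterError,
)
from .synthetic import SyntheticCommunity

__all__ = [
    "AbundanceSeries",
    "GammaFit",
    "RescaledSeries",
    "PluginMoments",
    "fit_gamma_sampling_mle",
    "plugin_moments",
    "rescale_log",
    "filter_asvs",
    "community_to_series",
    "read_community_tsv",
    "write_fits_csv",
]

CV_MIN = 0.01
CV_MAX = 50.0


@dataclass(frozen=True)
class AbundanceSeries:
    """One taxon's read counts, depths and observation days in one host."""

    asv_id: str
    days: np.ndarray      # ordered integer collection days
    counts: np.ndarray    # non-negative reads n_t
    depths: np.ndarray    # positive totals N_t
    host_id: str = "unknown"

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        depths = np.asarray(self.depths, dtype=int)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "depths", depths)
        if not (len(days) == len(counts) == len(depths)):
            raise ParameterError("days, counts and depths must share a length")
        if np.any(np.diff(days) <= 0):
            raise ParameterError("days must be strictly increasing")
        if np.any(counts < 0) or np.any(depths <= 0):
            raise ParameterError("counts must be >= 0 and depths > 0")
        if np.any(counts > depths):
            raise ParameterError("counts cannot exceed depths")

    def __len__(self) -> int:
        return len(self.days)

    @property
    def ratios(self) -> np.ndarray:
        return self.counts / self.depths

    @property
    def occupancy(self) -> float:
        return float(np.mean(self.counts > 0))


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma abundance parameters for one taxon."""

    mean: float           # mean relative abundance xbar
    cv: float             # coefficient of variation
    beta: float           # gamma shape, 1/cv^2
    loglik: float
    n_obs: int
    censored: bool = False  # cv pinned at the optimisation box boundary

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.cv > 0):
            raise ParameterError("mean and cv must be positive")
        if abs(self.beta * self.cv**2 - 1.0) > 1e-10:
            raise ParameterError("beta must equal 1/cv^2")


class PluginMoments(NamedTuple):
    """Naive sample moments of the count ratios (no sampling correction)."""

    mean: float
    cv: float
    is_constant: bool


@dataclass(frozen=True)
class RescaledSeries:
    """Log abundance rescaled by the mean: y(t) = ln(x(t)/xbar).

    Zero-count days cannot be log-transformed; they are recorded in
    ``missing_days`` and treated downstream as run-breaking gaps.
    """

    asv_id: str
    days: np.ndarray
    y: np.ndarray
    y_bar: float
    reference: str = "mle"        # which mean rescaled the series
    missing_days: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    host_id: str = "unknown"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.y)):
            raise ParameterError("y must be finite at every retained day")
        if abs(float(np.mean(self.y)) - self.y_bar) > 1e-12:
            raise ParameterError("y_bar must equal mean(y)")

    @property
    def deviations(self) -> np.ndarray:
        return self.y - self.y_bar


# --------------------------------------------------------------------------
# Likelihood
# --------------------------------------------------------------------------

def _nb_negloglik(theta: np.ndarray, counts: np.ndarray, depths: np.ndarray) -> float:
    log_mean, log_beta = theta
    mean = np.exp(log_mean)
    beta = np.exp(log_beta)
    mu = depths * mean
    p = beta / (beta + mu)
    ll = stats.nbinom.logpmf(counts, beta, p)
    if not np.all(np.isfinite(ll)):
        return 1e30
    return -float(ll.sum())


def fit_gamma_sampling_mle(
    series: AbundanceSeries,
    *,
    cv_bounds: tuple[float, float] = (CV_MIN, CV_MAX),
) -> GammaFit:
    """Sampling-aware MLE of (mean, CV) under the gamma-Poisson marginal.

    The negative-binomial log-likelihood is maximised in (log mean, log beta)
    with L-BFGS-B from a 3x3 multiplicative grid of starts centred on the
    plug-in moments, making the fit deterministic and order-invariant.  A CV
    pinned at the box boundary is reported with ``censored=True`` (constant
    counts drive the CV to its lower bound).
    """
    if len(series) < 10:
        raise InsufficientDataError(
            f"{series.asv_id}: need >= 10 observations, have {len(series)}"
        )
    # canonical observation order: the likelihood is order-invariant, and
    # sorting makes the floating-point sum (hence the fit) exactly so
    order = np.lexsort((series.depths, series.counts))
    counts, depths = series.counts[order], series.depths[order]
    if np.all(counts == 0):
        raise NoSignalError(f"{series.asv_id}: all counts are zero")

    pm = plugin_moments(series)
    m0 = min(max(pm.mean, 1e-12), 0.5)
    cv0 = min(max(pm.cv, 2 * cv_bounds[0]), cv_bounds[1] / 2)
    lb_beta = np.log(cv_bounds[1] ** -2)
    ub_beta = np.log(cv_bounds[0] ** -2)
    bounds = [(np.log(1e-12), np.log(1.0 - 1e-9)), (lb_beta, ub_beta)]

    best = None
    for fm in (0.5, 1.0, 2.0):
        for fc in (0.5, 1.0, 2.0):
            start = np.array([
                np.log(np.clip(m0 * fm, 1e-12, 1 - 1e-9)),
                np.clip(np.log((cv0 * fc) ** -2), lb_beta, ub_beta),
            ])
            res = optimize.minimize(
                _nb_negloglik, start, args=(counts, depths),
                method="L-BFGS-B", bounds=bounds,
            )
            if res.success and (best is None or res.fun < best.fun):
                best = res
    if best is None:
        raise FitFailureError(
            f"{series.asv_id}: optimiser failed from all 9 starts "
            f"(plug-in mean={pm.mean:.3g}, cv={pm.cv:.3g})"
        )
    mean = float(np.exp(best.x[0]))
    beta = float(np.exp(best.x[1]))
    cv = beta ** -0.5
    tol = 1e-6
    censored = cv <= cv_bounds[0] * (1 + tol) or cv >= cv_bounds[1] * (1 - tol)
    return GammaFit(mean=mean, cv=cv, beta=cv ** -2.0, loglik=-float(best.fun),
                    n_obs=len(series), censored=censored)


def plugin_moments(series: AbundanceSeries) -> PluginMoments:
    """Sample mean and CV of the count ratios n_t/N_t (population convention)."""
    if len(series) < 2:
        raise InsufficientDataError("need >= 2 observations for moments")
    r = series.ratios
    mean = float(r.mean())
    if mean == 0:
        raise NoSignalError(f"{series.asv_id}: all counts are zero")
    sd = float(r.std(ddof=0))
    if sd == 0:
        warnings.warn(
            f"{series.asv_id}: constant ratios, plug-in cv = 0", stacklevel=2
        )
        return PluginMoments(mean=mean, cv=0.0, is_constant=True)
    return PluginMoments(mean=mean, cv=sd / mean, is_constant=False)


def rescale_log(
    series: AbundanceSeries,
    fit: GammaFit | float,
    *,
    reference: str | None = None,
    min_retained: int = 10,
) -> RescaledSeries:
    """Build y(t) = ln((n_t/N_t)/xbar) on the days with non-zero counts.

    ``fit`` may be a GammaFit (its MLE mean is used; reference "mle") or a
    plain positive float (reference "plugin" unless overridden).  y is
    invariant to uniform rescaling of depths and counts.
    """
    if isinstance(fit, GammaFit):
        xbar = fit.mean
        ref = reference or "mle"
    else:
        xbar = float(fit)
        ref = reference or "plugin"
    if not xbar > 0:
        raise ParameterError("reference mean must be positive")
    keep = series.counts > 0
    if int(keep.sum()) < min_retained:
        raise InsufficientDataError(
            f"{series.asv_id}: only {int(keep.sum())} non-zero days "
            f"(need >= {min_retained})"
        )
    y = np.log(series.ratios[keep] / xbar)
    return RescaledSeries(
        asv_id=series.asv_id,
        days=series.days[keep],
        y=y,
        y_bar=float(y.mean()),
        reference=ref,
        missing_days=series.days[~keep],
        host_id=series.host_id,
    )


def filter_asvs(
    series_list: list[AbundanceSeries],
    occupancy_min: float = 0.9,
    n_obs_min: int = 50,
) -> tuple[list[AbundanceSeries], dict[str, str]]:
    """Retain consistently observed taxa; report a discard reason per taxon.

    A taxon is kept when it has non-zero counts in at least ``occupancy_min``
    of its samples and at least ``n_obs_min`` samples overall, matching the
    restriction of sojourn analyses to taxa present throughout the series.
    """
    retained: list[AbundanceSeries] = []
    reasons: dict[str, str] = {}
    for s in series_list:
        if len(s) < n_obs_min:
            reasons[s.asv_id] = f"n_obs {len(s)} < {n_obs_min}"
        elif s.occupancy < occupancy_min:
            reasons[s.asv_id] = f"occupancy {s.occupancy:.3f} < {occupancy_min}"
        else:
            retained.append(s)
    return retained, reasons


# --------------------------------------------------------------------------
# Container/format glue
# --------------------------------------------------------------------------

def community_to_series(community: SyntheticCommunity) -> list[AbundanceSeries]:
    """Split a synthetic community into per-taxon abundance series."""
    return [
        AbundanceSeries(
            asv_id=asv,
            days=community.days,
            counts=community.counts[i],
            depths=community.depths,
            host_id=community.host_id,
        )
        for i, asv in enumerate(community.asv_ids)
    ]


def read_community_tsv(
    counts_path: str | Path, metadata_path: str | Path
) -> dict[str, list[AbundanceSeries]]:
    """Read a counts TSV (ASV x sample) and sample metadata into series per host.

    The metadata must contain columns sample_id, host_id and collection_day;
    per-sample depth is the column sum of the counts table.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample_id", "host_id", "collection_day"}
    if not required.issubset(meta.columns):
        raise ParameterError(f"metadata must contain columns {sorted(required)}")
    out: dict[str, list[AbundanceSeries]] = {}
    for host, sub in meta.groupby("host_id", sort=True):
        sub = sub.sort_values("collection_day")
        cols = [c for c in sub["sample_id"] if c in counts.columns]
        block = counts[cols]
        depths = block.sum(axis=0).to_numpy()
        days = sub.set_index("sample_id").loc[cols, "collection_day"].to_numpy()
        out[str(host)] = [
            AbundanceSeries(
                asv_id=str(asv), days=days,
                counts=block.loc[asv].to_numpy(),
                depths=depths, host_id=str(host),
            )
            for asv in block.index
        ]
    return out


def write_fits_csv(
    fits: dict[str, GammaFit], path: str | Path, host_id: str = "unknown"
) -> pd.DataFrame:
    """Write per-taxon fits as CSV and return the table."""
    df = pd.DataFrame(
        [
            {
                "asv_id": asv, "host_id": host_id, "mean": f.mean, "cv": f.cv,
                "beta": f.beta, "loglik": f.loglik, "n_obs": f.n_obs,
                "censored_flag": f.censored,
            }
            for asv, f in fits.items()
        ]
    )
    df.to_csv(path, index=False)
    return df
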