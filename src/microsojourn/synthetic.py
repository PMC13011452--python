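"""Synthetic communities under the stochastic logistic model (SLM).

Each taxon i follows independent logistic growth with multiplicative
environmental noise,

    dx/dt = (x / tau) * (1 - x / K) + sqrt(sigma / tau) * x * eta(t),

where eta is Gaussian white noise (zero mean, delta correlation).  For
sigma < 2 the stationary abundance distribution is a gamma with shape
2/sigma - 1 and scale K*sigma/2, hence mean K*(1 - sigma/2) and squared
coefficient of variation sigma/(2 - sigma).

The community is observed the way a 16S amplicon survey observes it: on a
grid of collection days, a sequencing depth is drawn per sample and reads
are drawn multinomially from the relative-abundance composition, with an
optional fraction of days missing.  This reproduces the statistical
structure of daily gut-microbiome time series (sampling noise, finite
depth, compositionality) without modelling reads at the sequence level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CompositionError, IntegrationError, ParameterError

__all__ = [
    "SLMParams",
    "SamplingScheme",
    "SyntheticCommunity",
    "simulate_slm",
    "sample_stationary_gamma",
    "observe_counts",
    "generate_community",
    "write_community",
]

# Positivity floor, as a fraction of K.  The true process is strictly
# positive; a discretisation step that lands at or below zero is reflected
# to this floor.  Events are rare at the noise levels considered.
FLOOR_FRACTION = 1e-12

# Integration chunk length: Gaussian increments are pre-generated in blocks
# of this many steps so the numba fast path and the numpy fallback consume
# the identical random stream.
_CHUNK = 2048


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SLMParams:
    """SLM parameters for one taxon.

    Parameters
    ----------
    tau : float
        Growth timescale in days (inverse of the maximum growth rate).
    K : float
        Carrying capacity on the relative-abundance scale.
    sigma : float
        Environmental noise strength.  Must satisfy 0 <= sigma < 2;
        sigma = 0 is the deterministic logistic limit, and the stationary
        gamma distribution exists only for 0 < sigma < 2.
    """

    tau: float
    K: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ParameterError(f"tau must be positive, got {self.tau}")
        if not (self.K > 0):
            raise ParameterError(f"K must be positive, got {self.K}")
        if not (0 <= self.sigma < 2):
            raise ParameterError(
                f"sigma must lie in [0, 2) for the SLM (got {self.sigma}); "
                "no stationary distribution exists at sigma >= 2"
            )

    @property
    def stationary_shape(self) -> float:
        """Shape of the stationary gamma, 2/sigma - 1."""
        if self.sigma <= 0:
            raise ParameterError("stationary gamma requires sigma > 0")
        return 2.0 / self.sigma - 1.0

    @property
    def stationary_scale(self) -> float:
        """Scale of the stationary gamma, K*sigma/2."""
        if self.sigma <= 0:
            raise ParameterError("stationary gamma requires sigma > 0")
        return self.K * self.sigma / 2.0

    @property
    def stationary_mean(self) -> float:
        """Stationary mean abundance K*(1 - sigma/2)."""
        return self.K * (1.0 - self.sigma / 2.0)

    @property
    def stationary_cv(self) -> float:
        """Stationary coefficient of variation sqrt(sigma/(2 - sigma))."""
        return float(np.sqrt(self.sigma / (2.0 - self.sigma)))


@dataclass(frozen=True)
class SamplingScheme:
    """Observation design: daily grid, sequencing depth, missingness."""

    delta_t: float = 1.0          # days between scheduled observations
    n_days: int = 300             # number of scheduled observations
    depth_mean: float = 1e4       # expected reads per sample
    missing_fraction: float = 0.0  # probability a scheduled day is unsampled
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.delta_t > 0):
            raise ParameterError("delta_t must be positive")
        if not (0 <= self.missing_fraction < 1):
            raise ParameterError("missing_fraction must lie in [0, 1)")
        if not (self.depth_mean >= 1):
            raise ParameterError("depth_mean must be >= 1")
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")


@dataclass
class SyntheticCommunity:
    """A simulated community plus its sequencing observation.

    ``latent_x`` holds the true relative abundances on the full scheduled
    grid (ASV x day); ``counts`` holds reads for the retained (sampled)
    days only, with ``days`` giving their collection days and ``depths``
    the per-sample totals (including the residual "other taxa" slot).
    """

    params_per_asv: list[SLMParams]
    latent_x: np.ndarray
    counts: np.ndarray
    depths: np.ndarray
    days: np.ndarray
    asv_ids: list[str] = field(default_factory=list)
    host_id: str = "synthetic"
    obs_seed: int | None = None   # seed used by the observation layer

    def __post_init__(self) -> None:
        if not self.asv_ids:
            self.asv_ids = [f"ASV{i:04d}" for i in range(self.counts.shape[0])]
        if np.any(self.counts < 0):
            raise CompositionError("negative counts")
        if np.any(self.latent_x <= 0):
            raise CompositionError("latent abundances must be strictly positive")


# --------------------------------------------------------------------------
# Euler-Maruyama core
# --------------------------------------------------------------------------

try:  # optional acceleration; identical arithmetic to the numpy fallback
    from numba import njit

    @njit(cache=True)
    def _em_block(x, Z, a, b, amp, floor, out, step0, stride):
        # x: (n_paths,) state, Z: (n_steps_block, n_paths) increments,
        # a = dt/tau, b = dt/(tau*K) per path; amp = sqrt(sigma*dt/tau).
        n_block, n_paths = Z.shape
        r = 0
        for j in range(n_block):
            for p in range(n_paths):
                xp = x[p]
                xp = xp + xp * (a[p] - b[p] * xp) + amp[p] * xp * Z[j, p]
                if xp < floor[p]:
                    xp = floor[p]
                x[p] = xp
            if (step0 + j + 1) % stride == 0:
                for p in range(n_paths):
                    out[p, r] = x[p]
                r += 1
        return r

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def _em_block_numpy(x, Z, a, b, amp, floor, out, step0, stride):
    n_block = Z.shape[0]
    r = 0
    for j in range(n_block):
        x += x * (a - b * x) + amp * x * Z[j]
        np.maximum(x, floor, out=x)
        if (step0 + j + 1) % stride == 0:
            out[:, r] = x
            r += 1
    return r


def _em_paths(
    tau: np.ndarray,
    K: np.ndarray,
    sigma: np.ndarray,
    x0: np.ndarray,
    n_steps: int,
    dt: float,
    *,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
    record_stride: int = 1,
) -> np.ndarray:
    """Integrate n_paths independent SLM paths; record every ``record_stride`` steps.

    Returns an array of shape (n_paths, n_steps // record_stride) holding the
    state after steps ``record_stride, 2*record_stride, ...``.  Gaussian
    increments come either from ``noise`` (shape (n_steps, n_paths)) or are
    drawn chunk-wise from ``rng``; both routes produce identical trajectories
    for the same increments.
    """
    x = np.array(x0, dtype=np.float64, copy=True)
    n_paths = x.shape[0]
    tau = np.broadcast_to(np.asarray(tau, float), (n_paths,)).copy()
    K = np.broadcast_to(np.asarray(K, float), (n_paths,)).copy()
    sigma = np.broadcast_to(np.asarray(sigma, float), (n_paths,)).copy()
    a = dt / tau
    b = dt / (tau * K)
    amp = np.sqrt(sigma * dt / tau)
    floor = FLOOR_FRACTION * K
    n_rec = n_steps // record_stride
    out = np.empty((n_paths, n_rec), dtype=np.float64)
    kernel = _em_block if _HAVE_NUMBA else _em_block_numpy

    step0 = 0
    r_off = 0
    while step0 < n_steps:
        nb = min(_CHUNK, n_steps - step0)
        if noise is not None:
            Z = np.ascontiguousarray(noise[step0:step0 + nb])
        else:
            Z = rng.standard_normal((nb, n_paths))
        r = kernel(x, Z, a, b, amp, floor, out[:, r_off:], step0, record_stride)
        step0 += nb
        r_off += r
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise IntegrationError(
                f"non-finite state in path {bad} at integration step {step0}"
            )
    return out


def simulate_slm(
    params: SLMParams,
    x0: float | np.ndarray,
    t_end: float,
    dt_int: float | None = None,
    seed: int = 0,
    *,
    n_paths: int = 1,
    record_every: int = 1,
) -> np.ndarray:
    """Euler-Maruyama (Ito) integration of the SLM.

    Parameters
    ----------
    params : SLMParams
    x0 : float or array
        Initial abundance(s); strictly positive.  A scalar is shared by all
        paths.
    t_end : float
        Total integrated time in days.
    dt_int : float, optional
        Integration step; defaults to tau/100 (small enough that the
        Euler-Maruyama stationary bias is below sampling noise even at
        sigma = 1.5) and must not exceed tau/10.
    seed : int
        Seed for the Gaussian increments.
    n_paths : int
        Number of independent paths integrated with the same parameters.
    record_every : int
        Record the state every this many integration steps.

    Returns
    -------
    ndarray
        Shape (n_rec,) for a single path or (n_paths, n_rec) otherwise,
        where the first recorded state is after ``record_every`` steps.
        The initial condition is prepended when ``record_every == 1`` so a
        single-path call returns the trajectory on the integration grid.
    """
    if dt_int is None:
        dt_int = params.tau / 100.0
    if dt_int > params.tau / 10.0:
        raise ParameterError(
            f"dt_int={dt_int} too coarse; must be <= tau/10 = {params.tau / 10}"
        )
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 <= 0):
        raise ParameterError("x0 must be strictly positive")
    if x0.shape[0] == 1 and n_paths > 1:
        x0 = np.full(n_paths, x0[0])
    n_paths = x0.shape[0]
    n_steps = int(round(t_end / dt_int))
    rng = np.random.default_rng(seed)
    rec = _em_paths(
        params.tau, params.K, params.sigma, x0, n_steps, dt_int,
        rng=rng, record_stride=record_every,
    )
    if record_every == 1:
        rec = np.concatenate([x0[:, None], rec], axis=1)
    if rec.shape[0] == 1:
        return rec[0]
    return rec


def sample_stationary_gamma(params: SLMParams, n: int, seed: int = 0) -> np.ndarray:
    """Draw n i.i.d. abundances from the SLM's stationary gamma distribution.

    Shape 2/sigma - 1 and scale K*sigma/2, so the mean is K*(1 - sigma/2).
    Raises ParameterError when no stationary distribution exists
    (sigma <= 0 or sigma >= 2; the latter is screened by SLMParams).
    """
    if n < 0:
        raise ParameterError("n must be non-negative")
    shape = params.stationary_shape  # raises for sigma <= 0
    scale = params.stationary_scale
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, scale, size=n)


# --------------------------------------------------------------------------
# Observation layer
# --------------------------------------------------------------------------

def observe_counts(
    latent_x: np.ndarray,
    scheme: SamplingScheme,
    *,
    params_per_asv: list[SLMParams] | None = None,
    asv_ids: list[str] | None = None,
    host_id: str = "synthetic",
    residual: bool = True,
    seed: int | None = None,
) -> SyntheticCommunity:
    """Observe latent relative abundances through multinomial sequencing.

    Each scheduled day is retained with probability 1 - missing_fraction;
    its depth is Poisson(depth_mean) truncated at >= 1; reads are drawn
    multinomially from the composition.  With ``residual=True`` the
    abundances x are mapped to x / (1 + sum(x)) so a passive "everything
    else" slot of weight 1 / (1 + sum(x)) absorbs the remainder while each
    taxon's marginal dynamics are preserved up to that slowly varying
    normalisation.
    """
    latent_x = np.asarray(latent_x, dtype=float)
    if latent_x.ndim != 2:
        raise CompositionError("latent_x must be 2-D (ASV x day)")
    n_asvs, n_days = latent_x.shape
    if n_days != scheme.n_days:
        raise CompositionError(
            f"latent_x has {n_days} days but scheme.n_days={scheme.n_days}"
        )
    if np.any(latent_x < 0):
        raise CompositionError("negative latent abundances")
    total = latent_x.sum(axis=0)
    if residual:
        probs = np.vstack([latent_x, np.ones(n_days)]) / (1.0 + total)
    else:
        if np.any(total > 1.0 + 1e-12):
            raise CompositionError(
                "latent abundances sum to more than 1 on some day and no "
                "residual component was requested"
            )
        probs = np.vstack([latent_x, np.clip(1.0 - total, 0.0, None)])
        probs /= probs.sum(axis=0)

    obs_seed = scheme.seed if seed is None else seed
    rng = np.random.default_rng(obs_seed)
    keep = rng.random(n_days) >= scheme.missing_fraction
    days_all = np.round(np.arange(n_days) * scheme.delta_t).astype(int)
    days = days_all[keep]
    depths = np.maximum(rng.poisson(scheme.depth_mean, size=days.size), 1)

    counts = np.empty((n_asvs, days.size), dtype=np.int64)
    kept_idx = np.flatnonzero(keep)
    for j, d in enumerate(kept_idx):
        draw = rng.multinomial(depths[j], probs[:, d])
        counts[:, j] = draw[:n_asvs]

    return SyntheticCommunity(
        params_per_asv=params_per_asv or [],
        latent_x=np.where(latent_x > 0, latent_x, np.finfo(float).tiny),
        counts=counts,
        depths=depths,
        days=days,
        asv_ids=asv_ids or [],
        host_id=host_id,
        obs_seed=int(obs_seed),
    )


def generate_community(
    n_asvs: int,
    K_range: tuple[float, float] = (1e-5, 1e-2),
    sigma_range: tuple[float, float] = (0.2, 1.5),
    tau: float = 1.0,
    scheme: SamplingScheme | None = None,
    *,
    host_id: str = "synthetic",
    burn_in_tau: float = 50.0,
) -> SyntheticCommunity:
    """Simulate an SLM community and observe it through sequencing.

    Taxa are independent (the SLM is a single-species model): carrying
    capacities are log-uniform on ``K_range``, noise strengths uniform on
    ``sigma_range``, the growth timescale ``tau`` is shared.  Each taxon is
    integrated from a stationary draw with its own child random stream
    derived from the scheme's master seed, burnt in for ``burn_in_tau``
    growth timescales, and recorded on the observation grid before
    multinomial read sampling.
    """
    if scheme is None:
        scheme = SamplingScheme()
    if not (0 < sigma_range[0] <= sigma_range[1] < 2):
        raise ParameterError(f"sigma_range {sigma_range} must lie inside (0, 2)")
    if not (0 < K_range[0] <= K_range[1]):
        raise ParameterError(f"invalid K_range {K_range}")

    ss = np.random.SeedSequence(scheme.seed)
    seed_param, seed_obs, *seed_asvs = ss.spawn(2 + n_asvs)
    rng_param = np.random.default_rng(seed_param)

    logK = rng_param.uniform(np.log(K_range[0]), np.log(K_range[1]), n_asvs)
    Ks = np.exp(logK)
    sigmas = rng_param.uniform(sigma_range[0], sigma_range[1], n_asvs)
    params = [SLMParams(tau=tau, K=float(k), sigma=float(s))
              for k, s in zip(Ks, sigmas)]

    dt_int = min(tau / 100.0, scheme.delta_t / 100.0)
    stride = max(1, int(round(scheme.delta_t / dt_int)))
    n_burn_rec = int(np.ceil(burn_in_tau * tau / scheme.delta_t))
    n_rec = n_burn_rec + scheme.n_days
    n_steps = stride * n_rec

    # Per-ASV child streams: trajectories are reproducible taxon by taxon.
    noise = np.empty((n_steps, n_asvs))
    x0 = np.empty(n_asvs)
    for i, child in enumerate(seed_asvs):
        rng_i = np.random.default_rng(child)
        x0[i] = rng_i.gamma(params[i].stationary_shape,
                            params[i].stationary_scale)
        noise[:, i] = rng_i.standard_normal(n_steps)

    rec = _em_paths(tau, Ks, sigmas, x0, n_steps, dt_int,
                    noise=noise, record_stride=stride)
    latent = rec[:, n_burn_rec:]

    return observe_counts(
        latent, scheme,
        params_per_asv=params,
        host_id=host_id,
        seed=np.random.default_rng(seed_obs).integers(2**31),
    )


# --------------------------------------------------------------------------
# On-disk formats shared with the empirical pipeline
# --------------------------------------------------------------------------

def write_community(community: SyntheticCommunity, outdir: str | Path) -> dict[str, Path]:
    """Write counts TSV, metadata TSV and truth JSON; returns the paths.

    The counts table has ASV ids as rows and sample ids as columns; the
    metadata table has columns (sample_id, host_id, collection_day).  These
    are the formats the inference module reads.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"{community.host_id}_s{j:05d}" for j in range(community.days.size)]
    counts = pd.DataFrame(community.counts, index=community.asv_ids,
                          columns=sample_ids)
    counts.index.name = "asv_id"
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "host_id": community.host_id,
        "collection_day": community.days,
    })
    truth = {
        asv: {"tau": p.tau, "K": p.K, "sigma": p.sigma}
        for asv, p in zip(community.asv_ids, community.params_per_asv)
    }
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    counts.to_csv(paths["counts"], sep="\t")
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
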