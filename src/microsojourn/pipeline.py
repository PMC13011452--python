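"""End-to-end orchestration: data (or synthesis) -> fits -> sojourns ->
nulls -> divergences -> SLM predictions -> relationship tests.

The pipeline processes hosts independently.  For each host it filters to
consistently observed taxa, fits the sampling-aware gamma likelihood,
builds rescaled series, extracts sojourn/residence/return runs, compares
the empirical run-length distributions against the permutation and gamma
i.i.d. nulls, produces SLM predictions, and tests the three focal
relationships with Spearman rank correlations and permutation p-values:

* mean sojourn time <T> versus mean abundance (SLM: no relationship),
* <T> versus CV (SLM: increasing),
* sojourn height H versus duration T (SLM at tau <~ delta_t: none).

Every output CSV starts with a comment line carrying the config hash and
master seed so any table can be traced to the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import (
    EmptySummaryError,
    InsufficientDataError,
    MicrosojournError,
    PipelineError,
    UndefinedCorrelationError,
)
from . import inference, nulls, sojourn, synthetic, theory

__all__ = [
    "RunConfig",
    "RelationshipResult",
    "assess_relationship",
    "run_pipeline",
    "OUTPUT_FILES",
]

logger = logging.getLogger("microsojourn")

OUTPUT_FILES = (
    "fits.csv",
    "trajectories.csv",
    "sojourn_pmf.csv",
    "residence_return_pmf.csv",
    "profiles.csv",
    "divergence.csv",
    "relationships.csv",
    "predictions.csv",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    # input: either both TSV paths, or synthetic-community settings
    counts_tsv: str | None = None
    metadata_tsv: str | None = None
    synthetic: dict | None = None        # kwargs for generate_community
    out_dir: str = "results"
    # filtering
    occupancy_min: float = 0.9
    n_obs_min: int = 50
    max_gap_days: int = 2
    # nulls / divergence
    divergence: str = "kl"
    n_permutations: int = 200
    n_null_replicates: int = 20
    # SLM predictions
    tau_grid: list = field(default_factory=lambda: list(range(1, 11)))
    fit_tau_t_total: float = 2e4
    sigma_grid: list = field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0, 1.25, 1.5])
    predict_t_total: float = 1e4
    run_fit_tau: bool = True
    # relationships
    n_perm_relationship: int = 999
    min_sojourns_per_asv: int = 5
    # reproducibility
    seed: int = 0
    host: str | None = None              # restrict to one host if set

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis settings (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class RelationshipResult:
    """Spearman rank correlation with a permutation p-value."""

    x_name: str
    y_name: str
    rho: float
    p_perm: float
    n: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError("rho outside [-1, 1]")
        if not (0.0 <= self.p_perm <= 1.0):
            raise ValueError("p_perm outside [0, 1]")


def assess_relationship(
    x,
    y,
    n_perm: int = 999,
    seed: int = 0,
    *,
    x_name: str = "x",
    y_name: str = "y",
) -> RelationshipResult:
    """Spearman rho between paired per-taxon values with a permutation test.

    The p-value shuffles y relative to x:
    p = (1 + #{|rho*| >= |rho|}) / (1 + n_perm), two-sided.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 10:
        raise InsufficientDataError("need >= 10 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input: rank correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    hits = 0
    for _ in range(n_perm):
        rho_star = np.corrcoef(rx, rng.permutation(ry))[0, 1]
        if abs(rho_star) >= abs(rho) - 1e-12:
            hits += 1
    return RelationshipResult(
        x_name=x_name, y_name=y_name, rho=rho,
        p_perm=(1 + hits) / (1 + n_perm), n=int(x.size),
    )


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _load_series(config: RunConfig) -> dict[str, list[inference.AbundanceSeries]]:
    if config.synthetic is not None:
        synth_kwargs = dict(config.synthetic)
        scheme_kwargs = synth_kwargs.pop("scheme", {})
        scheme_kwargs.setdefault("seed", config.seed)
        scheme = synthetic.SamplingScheme(**scheme_kwargs)
        community = synthetic.generate_community(scheme=scheme, **synth_kwargs)
        return {community.host_id: inference.community_to_series(community)}
    if not (config.counts_tsv and config.metadata_tsv):
        raise PipelineError(
            "config needs counts_tsv+metadata_tsv or synthetic settings"
        )
    return inference.read_community_tsv(config.counts_tsv, config.metadata_tsv)


def _weighted_median_sigma(fits: dict[str, inference.GammaFit]) -> float:
    """Abundance-weighted median of the per-taxon sigma = 2 CV^2/(1 + CV^2)."""
    sigmas = np.array([theory.sigma_from_cv(f.cv) for f in fits.values()])
    weights = np.array([f.mean for f in fits.values()])
    order = np.argsort(sigmas)
    cw = np.cumsum(weights[order])
    idx = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(np.clip(sigmas[order][min(idx, sigmas.size - 1)], 0.05, 1.95))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict and writes tables.

    Outputs (all under ``config.out_dir``): the files in ``OUTPUT_FILES``
    plus ``predicted_pmf.csv`` when the timescale fit runs, a ``figures/``
    directory with the pooled p(T) plot, and ``run.log`` with per-stage
    counts.  Re-running with an identical config reproduces every table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    chash = config.config_hash()
    header = f"# config_hash={chash} seed={config.seed}\n"

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)

    try:
        hosts = _load_series(config)
        if config.host is not None:
            hosts = {config.host: hosts[config.host]}

        fit_rows, traj_rows, pmf_rows, rr_rows, prof_rows, rel_rows = \
            [], [], [], [], [], []
        pred_rows = []
        fitted_pmf_rows = []
        div_input: dict = {}

        for host, series_list in sorted(hosts.items()):
            host_tag = int.from_bytes(
                hashlib.sha1(host.encode()).digest()[:4], "big")
            host_seed = int(np.random.SeedSequence(
                (config.seed, host_tag)).generate_state(1)[0] % 2**31)
            retained, reasons = inference.filter_asvs(
                series_list, config.occupancy_min, config.n_obs_min
            )
            logger.info("host=%s asvs=%d retained=%d", host,
                        len(series_list), len(retained))
            for asv, why in reasons.items():
                logger.info("host=%s discard asv=%s reason=%s", host, asv, why)

            fits: dict[str, inference.GammaFit] = {}
            rescaled: dict[str, inference.RescaledSeries] = {}
            trajectories: list[sojourn.SojournTrajectory] = []
            for s in retained:
                try:
                    fit = inference.fit_gamma_sampling_mle(s)
                    rs = inference.rescale_log(s, fit)
                except MicrosojournError as err:
                    logger.info("host=%s skip asv=%s (%s)", host, s.asv_id, err)
                    continue
                fits[s.asv_id] = fit
                rescaled[s.asv_id] = rs
                fit_rows.append({
                    "host_id": host, "asv_id": s.asv_id, "mean": fit.mean,
                    "cv": fit.cv, "beta": fit.beta, "loglik": fit.loglik,
                    "n_obs": fit.n_obs, "censored_flag": fit.censored,
                })
                try:
                    trajs = sojourn.extract_sojourns(rs, config.max_gap_days)
                except MicrosojournError as err:
                    raise PipelineError(
                        f"stage=extract_sojourns host={host} asv={s.asv_id}: {err}"
                    ) from err
                trajectories.extend(trajs)
                traj_rows.extend({
                    "host_id": host, "asv_id": t.asv_id, "sign": t.sign,
                    "start_day": t.start_day, "T": t.T, "H": t.H,
                    "area": t.area,
                } for t in trajs)
            logger.info("host=%s trajectories=%d", host, len(trajectories))
            if not trajectories:
                continue

            # empirical run-length distributions
            p_soj = sojourn.sojourn_time_distribution(trajectories)
            pmf_rows.extend({
                "host_id": host, "kind": "sojourn", "T": int(t), "probability": p,
            } for t, p in zip(p_soj.support, p_soj.pmf))
            res_lengths, ret_lengths = [], []
            for s in series_list:
                res, ret = sojourn.residence_return_times(s, config.max_gap_days)
                if res is not None:
                    res_lengths.extend((res.support.repeat(
                        np.round(res.pmf * res.n_runs).astype(int))).tolist())
                if ret is not None:
                    ret_lengths.extend((ret.support.repeat(
                        np.round(ret.pmf * ret.n_runs).astype(int))).tolist())
            p_res = (sojourn.run_length_summary(res_lengths, "residence")
                     if res_lengths else None)
            p_ret = (sojourn.run_length_summary(ret_lengths, "return")
                     if ret_lengths else None)
            for summ in (p_res, p_ret):
                if summ is not None:
                    rr_rows.extend({
                        "host_id": host, "kind": summ.kind, "T": int(t),
                        "probability": p,
                    } for t, p in zip(summ.support, summ.pmf))

            # profiles by T
            t_counts: dict[int, int] = {}
            for t in trajectories:
                t_counts[t.T] = t_counts.get(t.T, 0) + 1
            for T, c in sorted(t_counts.items()):
                if c < config.min_sojourns_per_asv:
                    continue
                prof = sojourn.mean_deviation_profile(trajectories, T)
                prof_rows.extend({
                    "host_id": host, "T": T, "position": k + 1,
                    "mean_deviation": v, "n": c,
                } for k, v in enumerate(prof))

            # nulls
            perm_lengths = []
            for i, (asv, rs) in enumerate(sorted(rescaled.items())):
                pn = nulls.permutation_null(
                    rs, config.n_permutations, seed=host_seed + i,
                    max_gap_days=config.max_gap_days,
                )
                perm_lengths.extend(pn.support.repeat(
                    np.round(pn.pmf * pn.n_runs).astype(int)).tolist())
            p_perm = sojourn.run_length_summary(perm_lengths, "sojourn")
            gi_lengths = []
            for i, (asv, fit) in enumerate(sorted(fits.items())):
                s = next(x for x in retained if x.asv_id == asv)
                try:
                    gn = nulls.gamma_iid_null(
                        fit, len(s), s.depths, config.n_null_replicates,
                        seed=host_seed + 10_000 + i,
                        max_gap_days=config.max_gap_days,
                    )
                except EmptySummaryError:
                    continue
                gi_lengths.extend(gn.support.repeat(
                    np.round(gn.pmf * gn.n_runs).astype(int)).tolist())
            div_input[host] = {"sojourn": {
                "permutation": (p_soj, p_perm),
            }}
            if gi_lengths:
                div_input[host]["sojourn"]["gamma_iid"] = (
                    p_soj, sojourn.run_length_summary(gi_lengths, "sojourn"))
            # permutation nulls for residence/return: shuffle presence labels
            for summ, lengths_name in ((p_res, "residence"), (p_ret, "return")):
                if summ is None:
                    continue
                rrnull = _presence_permutation_null(
                    series_list, lengths_name, config, host_seed
                )
                if rrnull is not None:
                    div_input[host].setdefault(lengths_name, {})[
                        "permutation"] = (summ, rrnull)

            # relationships
            mean_T, excluded = sojourn.mean_sojourn_time(
                trajectories, config.min_sojourns_per_asv
            )
            for asv, why in excluded.items():
                logger.info("host=%s <T> excluded asv=%s (%s)", host, asv, why)
            common = [a for a in mean_T.index if a in fits]
            if len(common) >= 10:
                xbar = [fits[a].mean for a in common]
                cv = [fits[a].cv for a in common]
                tvals = mean_T[common].to_numpy()
                for xs, xn in ((xbar, "mean_abundance"), (cv, "cv")):
                    try:
                        r = assess_relationship(
                            xs, tvals, config.n_perm_relationship,
                            seed=host_seed, x_name=xn, y_name="mean_T",
                        )
                        rel_rows.append({
                            "host_id": host, "x_name": r.x_name,
                            "y_name": r.y_name, "rho": r.rho,
                            "p_perm": r.p_perm, "n": r.n,
                        })
                    except MicrosojournError as err:
                        logger.info("host=%s relationship %s skipped (%s)",
                                    host, xn, err)
            if len(trajectories) >= 10:
                r = assess_relationship(
                    [t.H for t in trajectories], [t.T for t in trajectories],
                    config.n_perm_relationship, seed=host_seed,
                    x_name="H", y_name="T",
                )
                rel_rows.append({
                    "host_id": host, "x_name": "H", "y_name": "T",
                    "rho": r.rho, "p_perm": r.p_perm, "n": r.n,
                })

            # SLM predictions
            if fits:
                sigma_host = _weighted_median_sigma(fits)
                curve = theory.predict_mean_T(
                    tau=1.0, sigma_grid=config.sigma_grid,
                    t_total=config.predict_t_total, seed=host_seed,
                )
                pred_rows.extend({
                    "host_id": host, "sigma": row.sigma, "cv": row.cv,
                    "mean_T": row.mean_T,
                } for row in curve.itertuples())
                if config.run_fit_tau:
                    ft = theory.fit_tau(
                        p_soj, config.tau_grid, sigma=sigma_host,
                        t_total=config.fit_tau_t_total, seed=host_seed,
                    )
                    logger.info("host=%s fitted tau=%.1f sigma=%.2f",
                                host, ft.tau, sigma_host)
                    pred = theory.predict_sojourn_pmf(
                        ft.tau, sigma_host, t_total=config.fit_tau_t_total,
                        seed=host_seed,
                    )
                    fitted_pmf_rows.extend({
                        "host_id": host, "T": int(t), "probability": p,
                        "tau": ft.tau,
                    } for t, p in zip(pred.support, pred.pmf))

        div_df = nulls.compare_quantities(div_input, measure=config.divergence)

        _write_csv(pd.DataFrame(fit_rows), out / "fits.csv", header)
        _write_csv(pd.DataFrame(traj_rows), out / "trajectories.csv", header)
        _write_csv(pd.DataFrame(pmf_rows), out / "sojourn_pmf.csv", header)
        _write_csv(pd.DataFrame(rr_rows), out / "residence_return_pmf.csv", header)
        _write_csv(pd.DataFrame(prof_rows), out / "profiles.csv", header)
        _write_csv(div_df, out / "divergence.csv", header)
        _write_csv(pd.DataFrame(rel_rows), out / "relationships.csv", header)
        _write_csv(pd.DataFrame(pred_rows), out / "predictions.csv", header)
        if fitted_pmf_rows:
            _write_csv(pd.DataFrame(fitted_pmf_rows),
                       out / "predicted_pmf.csv", header)
        _plot_pt(pd.DataFrame(pmf_rows), pd.DataFrame(fitted_pmf_rows),
                 out / "figures" / "sojourn_pmf.png")

        return {
            "config_hash": chash,
            "hosts": sorted(hosts),
            "n_fits": len(fit_rows),
            "n_trajectories": len(traj_rows),
            "divergence": div_df,
            "relationships": pd.DataFrame(rel_rows),
            "out_dir": str(out),
        }
    finally:
        logger.removeHandler(fh)
        fh.close()


def _presence_permutation_null(series_list, kind, config, host_seed):
    """Permutation null for residence/return: shuffle each presence series."""
    rng = np.random.default_rng(host_seed + 77)
    lengths = []
    for s in series_list:
        pres = np.where(s.counts > 0, 1.0, -1.0)
        if np.all(pres > 0) or np.all(pres < 0):
            continue
        for _ in range(max(10, config.n_permutations // 10)):
            rng.shuffle(pres)
            starts, ends, signs = sojourn.interior_run_bounds(
                s.days, pres, max_gap_days=config.max_gap_days
            )
            want = signs > 0 if kind == "residence" else signs < 0
            lengths.extend((ends - starts)[want].tolist())
    if not lengths:
        return None
    return sojourn.run_length_summary(lengths, kind)


def _plot_pt(pmf_df: pd.DataFrame, pred_df: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if not pmf_df.empty:
        pooled = pmf_df.groupby("T")["probability"].mean()
        ax.semilogy(pooled.index, pooled.values, "o-", label="empirical p(T)")
    if pred_df is not None and not pred_df.empty:
        pooled = pred_df.groupby("T")["probability"].mean()
        ax.semilogy(pooled.index, pooled.values, "s--", label="SLM prediction")
    ax.set_xlabel("sojourn time T (observations)")
    ax.set_ylabel("p(T)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
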