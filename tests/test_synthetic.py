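"""Tests of the SLM simulator and the sequencing observation layer."""

import numpy as np
import pytest
from scipy import stats

from microsojourn import (
    CompositionError,
    ParameterError,
    SLMParams,
    SamplingScheme,
    generate_community,
    observe_counts,
    sample_stationary_gamma,
    simulate_slm,
    write_community,
    read_community_tsv,
)


class TestSLMParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(tau=-1, K=1, sigma=1), dict(tau=1, K=0, sigma=1),
                   dict(tau=1, K=1, sigma=2.0), dict(tau=1, K=1, sigma=2.5)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SLMParams(**kwargs)

    def test_stationary_moments_closed_form(self):
        p = SLMParams(tau=1.0, K=2.0, sigma=0.5)
        assert p.stationary_shape == pytest.approx(2 / 0.5 - 1)
        assert p.stationary_scale == pytest.approx(2.0 * 0.5 / 2)
        assert p.stationary_mean == pytest.approx(2.0 * (1 - 0.25))
        assert p.stationary_cv**2 == pytest.approx(0.5 / 1.5)


class TestSimulateSLM:
    def test_deterministic_logistic_limit(self):
        # sigma = 0: the trajectory relaxes monotonically onto K
        p = SLMParams(tau=1.0, K=1e-3, sigma=0.0)
        x = simulate_slm(p, x0=p.K / 2, t_end=50.0, seed=0)
        assert np.all(np.diff(x) >= -1e-18)
        assert abs(x[-1] - p.K) < 1e-6 * p.K

    def test_stationary_moments_match_gamma(self):
        # long-run ensemble mean K(1-sigma/2) and CV^2 = sigma/(2-sigma)
        p = SLMParams(tau=1.0, K=1e-3, sigma=1.0)
        x = simulate_slm(p, x0=p.K, t_end=1250.0, seed=1,
                         n_paths=40, record_every=50)
        samp = x[:, 40:]  # discard burn-in
        assert samp.mean() == pytest.approx(p.stationary_mean, rel=0.05)
        cv2 = samp.var() / samp.mean() ** 2
        assert cv2 == pytest.approx(1.0, rel=0.05)

    def test_identical_seeds_bit_identical(self):
        p = SLMParams(tau=1.0, K=1.0, sigma=0.8)
        a = simulate_slm(p, 0.5, 20.0, seed=42)
        b = simulate_slm(p, 0.5, 20.0, seed=42)
        assert np.array_equal(a, b)

    def test_coarse_step_rejected(self):
        p = SLMParams(tau=1.0, K=1.0, sigma=0.5)
        with pytest.raises(ParameterError):
            simulate_slm(p, 0.5, 10.0, dt_int=0.5)

    def test_trajectory_strictly_positive(self):
        p = SLMParams(tau=1.0, K=1.0, sigma=1.9)
        x = simulate_slm(p, 1.0, 200.0, seed=3)
        assert np.all(x > 0)

    @pytest.mark.parametrize("sigma", [0.25, 0.5, 1.0, 1.5])
    def test_stationary_distribution_ks(self, sigma):
        # thinned long-run samples vs the closed-form gamma
        p = SLMParams(tau=1.0, K=1.0, sigma=sigma)
        x = simulate_slm(p, 1.0, 1050.0, seed=11, n_paths=50,
                         record_every=1000)  # thin at 10 tau
        samp = x[:, 5:].ravel()[:5000]
        ks = stats.kstest(
            samp, "gamma", args=(p.stationary_shape, 0, p.stationary_scale)
        ).statistic
        assert ks < 0.02

    def test_noise_contract_standardised_increments(self):
        # recover z_t from the recorded path: mean ~ 0, no lag-1 correlation
        p = SLMParams(tau=1.0, K=1.0, sigma=0.5)
        dt = p.tau / 100
        x = simulate_slm(p, 1.0, 100.0, dt_int=dt, seed=7)
        drift = x[:-1] * (dt / p.tau) * (1 - x[:-1] / p.K)
        z = (x[1:] - x[:-1] - drift) / (np.sqrt(p.sigma * dt / p.tau) * x[:-1])
        n = z.size
        assert abs(z.mean()) < 3 / np.sqrt(n)
        rho = np.corrcoef(z[:-1], z[1:])[0, 1]
        assert abs(rho) < 3 / np.sqrt(n)


class TestStationaryGamma:
    def test_noiseless_limit_concentrates_at_K(self):
        p = SLMParams(tau=1.0, K=5.0, sigma=1e-4)
        x = sample_stationary_gamma(p, 10_000, seed=0)
        assert x.std() / x.mean() < 0.01
        assert x.mean() == pytest.approx(5.0, rel=0.01)

    def test_unit_sigma_cv(self):
        p = SLMParams(tau=1.0, K=1.0, sigma=1.0)
        x = sample_stationary_gamma(p, 100_000, seed=1)
        assert x.var() / x.mean() ** 2 == pytest.approx(1.0, rel=0.03)
        assert x.mean() == pytest.approx(0.5, rel=0.03)

    def test_empty_and_invalid(self):
        p = SLMParams(tau=1.0, K=1.0, sigma=1.0)
        assert sample_stationary_gamma(p, 0).size == 0
        with pytest.raises(ParameterError):
            sample_stationary_gamma(SLMParams(tau=1, K=1, sigma=0.0), 5)

    def test_matches_long_slm_run(self):
        # cross-check the i.i.d. sampler against the dynamical simulation
        p = SLMParams(tau=1.0, K=1.0, sigma=0.5)
        iid = sample_stationary_gamma(p, 5000, seed=2)
        dyn = simulate_slm(p, 1.0, 1050.0, seed=3, n_paths=50,
                           record_every=1000)[:, 5:].ravel()[:5000]
        assert stats.ks_2samp(iid, dyn).statistic < 0.04


class TestObserveCounts:
    def test_infinite_depth_limit(self):
        latent = np.full((1, 50), 0.01)
        scheme = SamplingScheme(n_days=50, depth_mean=1e9, seed=0)
        com = observe_counts(latent, scheme)
        ratios = com.counts[0] / com.depths
        assert np.allclose(ratios, 0.01 / 1.01, rtol=0.01)

    def test_missing_fraction_binomial(self):
        latent = np.full((2, 1000), 1e-3)
        scheme = SamplingScheme(n_days=1000, depth_mean=100,
                                missing_fraction=0.5, seed=1)
        com = observe_counts(latent, scheme)
        assert 400 <= com.days.size <= 600

    def test_absent_taxon_all_zero(self):
        latent = np.vstack([np.zeros(30), np.full(30, 1e-2)])
        scheme = SamplingScheme(n_days=30, depth_mean=1e4, seed=2)
        com = observe_counts(latent, scheme)
        assert np.all(com.counts[0] == 0)
        assert com.counts[1].sum() > 0

    def test_counts_within_depths(self):
        latent = np.full((3, 40), 0.05)
        scheme = SamplingScheme(n_days=40, depth_mean=500, seed=3)
        com = observe_counts(latent, scheme)
        assert np.all(com.counts.sum(axis=0) <= com.depths)
        assert np.all(com.depths >= 1)

    def test_overfull_composition_rejected_without_residual(self):
        latent = np.full((3, 10), 0.5)  # sums to 1.5
        scheme = SamplingScheme(n_days=10, depth_mean=100, seed=4)
        with pytest.raises(CompositionError):
            observe_counts(latent, scheme, residual=False)


class TestGenerateCommunity:
    def test_fixed_seed_identical_counts(self):
        scheme = SamplingScheme(n_days=60, depth_mean=1e3, seed=5)
        a = generate_community(4, scheme=scheme)
        b = generate_community(4, scheme=scheme)
        assert np.array_equal(a.counts, b.counts)

    def test_parameters_inside_requested_ranges(self):
        scheme = SamplingScheme(n_days=50, depth_mean=1e3, seed=6)
        com = generate_community(
            50, K_range=(1e-5, 1e-2), sigma_range=(0.2, 1.5), scheme=scheme
        )
        for p in com.params_per_asv:
            assert 1e-5 <= p.K <= 1e-2
            assert 0.2 <= p.sigma <= 1.5

    def test_single_asv_is_simulate_plus_observe(self):
        # generate_community composes the simulator with observe_counts
        scheme = SamplingScheme(n_days=80, depth_mean=1e4, seed=7)
        com = generate_community(1, scheme=scheme)
        redo = observe_counts(
            com.latent_x, scheme, seed=com.obs_seed,
            params_per_asv=com.params_per_asv, host_id=com.host_id,
        )
        assert np.array_equal(com.counts, redo.counts)

    def test_sigma_range_validated(self):
        with pytest.raises(ParameterError):
            generate_community(3, sigma_range=(0.5, 2.5),
                               scheme=SamplingScheme(n_days=20))


def test_write_and_read_roundtrip(tmp_path):
    scheme = SamplingScheme(n_days=40, depth_mean=1e3, seed=8)
    com = generate_community(3, K_range=(1e-3, 1e-2), scheme=scheme,
                             host_id="H9")
    paths = write_community(com, tmp_path)
    hosts = read_community_tsv(paths["counts"], paths["metadata"])
    assert list(hosts) == ["H9"]
    series = hosts["H9"]
    assert len(series) == 3
    np.testing.assert_array_equal(series[0].counts, com.counts[0])
    np.testing.assert_array_equal(series[0].days, com.days)
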