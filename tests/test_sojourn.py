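"""Tests of sojourn extraction, run-length summaries and scaling fits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsojourn import (
    AbundanceSeries,
    EmptySummaryError,
    InsufficientDataError,
    MissingTError,
    RescaledSeries,
    SojournTrajectory,
    extract_sojourns,
    fit_alpha,
    interior_run_bounds,
    mean_deviation_profile,
    mean_sojourn_time,
    residence_return_times,
    run_length_summary,
    sojourn_time_distribution,
)

from conftest import brute_force_interior_runs


def rescaled_from_dev(dev, days=None, missing=()):
    """Build a RescaledSeries whose deviations equal ``dev`` exactly."""
    dev = np.asarray(dev, float)
    y = dev - dev.mean() + 1.0  # arbitrary offset; deviations recentre it
    days = np.arange(dev.size) if days is None else np.asarray(days)
    return RescaledSeries(
        asv_id="a", days=days, y=y, y_bar=float(y.mean()),
        missing_days=np.asarray(missing, dtype=int),
    )


def traj(dev, sign=None, asv="a"):
    dev = np.asarray(dev, float)
    s = sign or int(np.sign(dev[0]))
    return SojournTrajectory(asv, s, 0, dev.size - 1, dev.size,
                            float(np.abs(dev).max()), dev,
                            area=float(np.abs(dev).sum()))


class TestInteriorRunBounds:
    def test_boundary_runs_discarded(self):
        # signs [+,+,-,-,-,+]: only the interior minus-run survives
        dev = np.array([1, 1, -1, -1, -1, 1], float)
        starts, ends, signs = interior_run_bounds(np.arange(6), dev)
        assert list(starts) == [2] and list(ends) == [5] and list(signs) == [-1]

    def test_alternating_signs(self):
        dev = np.tile([1.0, -1.0], 5)
        starts, ends, _ = interior_run_bounds(np.arange(10), dev)
        assert len(starts) == 8
        assert np.all(ends - starts == 1)

    def test_exhaustive_length_12_against_brute_force(self):
        days = np.arange(12)
        for bits in itertools.product([1, -1], repeat=12):
            dev = np.array(bits, float)
            starts, ends, signs = interior_run_bounds(days, dev)
            expected = brute_force_interior_runs(list(bits))
            assert list(zip(starts, ends, signs)) == expected

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=5, max_size=50))
    def test_matches_brute_force_with_ties(self, signs):
        dev = np.array(signs, float)
        starts, ends, sgs = interior_run_bounds(np.arange(len(signs)), dev)
        assert list(zip(starts, ends, sgs)) == brute_force_interior_runs(signs)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.sampled_from([-1, 1]), min_size=5, max_size=60))
    def test_conservation_of_observations(self, signs):
        # interior + boundary runs partition a gap-free +/-1 series
        dev = np.array(signs, float)
        starts, ends, _ = interior_run_bounds(np.arange(len(signs)), dev)
        interior = int((ends - starts).sum())
        all_runs = brute_force_interior_runs([0] + signs + [0])  # pad: all interior
        total = sum(e - s for s, e, _ in all_runs)
        assert total == len(signs)
        boundary = total - interior
        assert boundary >= 0 and interior + boundary == len(signs)

    def test_gap_bridged_only_when_sign_unchanged(self):
        # day gap of 2 within max_gap_days: same sign bridges ...
        dev = np.array([-1, 1, 1, 1, -1], float)
        days = np.array([0, 1, 2, 4, 5])
        starts, ends, _ = interior_run_bounds(days, dev, max_gap_days=2)
        assert list(zip(starts, ends)) == [(1, 4)]
        # ... opposite sign across the gap (unobserved crossing) discards
        # the runs on both sides
        dev2 = np.array([-1, 1, 1, -1, -1, 1], float)
        days2 = np.array([0, 1, 2, 4, 5, 6])
        starts2, _, _ = interior_run_bounds(days2, dev2, max_gap_days=2)
        assert starts2.size == 0

    def test_long_gap_breaks_run(self):
        dev = np.array([-1, 1, 1, 1, -1], float)
        days = np.array([0, 1, 2, 6, 7])  # gap of 4 > max_gap_days
        starts, _, _ = interior_run_bounds(days, dev, max_gap_days=2)
        assert starts.size == 0

    def test_missing_day_always_breaks(self):
        dev = np.array([-1, 1, 1, -1], float)
        days = np.array([0, 1, 3, 4])  # day 2 dropped for a zero count
        starts, _, _ = interior_run_bounds(days, dev, missing_days=[2],
                                           max_gap_days=2)
        assert starts.size == 0


class TestExtractSojourns:
    def test_height_and_area_consistency(self):
        rng = np.random.default_rng(4)
        rs = rescaled_from_dev(rng.standard_normal(200))
        for t in extract_sojourns(rs):
            assert t.H == pytest.approx(np.abs(t.deviations).max())
            assert t.area == pytest.approx(np.abs(t.deviations).sum())
            assert np.all(np.sign(t.deviations) == t.sign)

    def test_requires_three_observations(self):
        with pytest.raises(InsufficientDataError):
            extract_sojourns(rescaled_from_dev([1.0, -1.0]))


class TestRunLengthSummary:
    def test_hand_counted_pmf(self):
        summ = run_length_summary([1, 1, 2], "sojourn")
        assert summ.as_dict() == {1: pytest.approx(2 / 3), 2: pytest.approx(1 / 3)}
        assert summ.mean_T == pytest.approx(4 / 3)

    def test_empty_input_raises(self):
        with pytest.raises(EmptySummaryError):
            run_length_summary([], "sojourn")

    def test_pooling_order_invariant(self):
        a = sojourn_time_distribution([traj([1.0]), traj([-2.0, -1.0])])
        b = sojourn_time_distribution([traj([-2.0, -1.0]), traj([1.0])])
        assert a.as_dict() == b.as_dict()

    def test_iid_fair_signs_geometric_law(self, rng):
        # interior runs of i.i.d. symmetric signs are geometric: p(T) = 2^-T
        lengths = []
        for _ in range(200):
            dev = rng.choice([-1.0, 1.0], size=500)
            s, e, _ = interior_run_bounds(np.arange(500), dev)
            lengths.extend((e - s).tolist())
        summ = run_length_summary(lengths, "sojourn")
        assert summ.mean_T == pytest.approx(2.0, abs=0.05)
        for t in range(1, 6):
            assert summ.as_dict()[t] == pytest.approx(2.0**-t, abs=0.01)


class TestMeanDeviationProfile:
    def test_single_trajectory_returns_folded_self(self):
        t = traj([-0.5, -2.0, -1.0])
        np.testing.assert_allclose(
            mean_deviation_profile([t], 3), [0.5, 2.0, 1.0]
        )

    def test_mirror_trajectories_fold_identically(self):
        up = traj([0.5, 2.0])
        down = traj([-0.5, -2.0])
        np.testing.assert_allclose(
            mean_deviation_profile([up, down], 2),
            mean_deviation_profile([up], 2),
        )

    def test_hand_computed_position_means(self):
        ts = [traj([1.0, 3.0]), traj([2.0, 1.0]), traj([-3.0, -2.0])]
        np.testing.assert_allclose(mean_deviation_profile(ts, 2), [2.0, 2.0])

    def test_missing_duration_raises(self):
        with pytest.raises(MissingTError):
            mean_deviation_profile([traj([1.0])], 5)


class TestFitAlpha:
    def _power_law_trajectories(self, alpha, rng, n_per_t=800):
        ts = []
        for T in range(2, 9):
            scale = T**alpha
            for _ in range(n_per_t):
                dev = scale * (0.5 + rng.random(T))
                ts.append(traj(dev))
        return ts

    def test_recovers_constructed_exponent(self, rng):
        ts = self._power_law_trajectories(0.5, rng)
        fit = fit_alpha(ts, n_boot=50)
        assert fit.alpha == pytest.approx(0.5, abs=0.02)

    def test_identical_profiles_give_zero(self, rng):
        fit = fit_alpha(self._power_law_trajectories(0.0, rng), n_boot=50)
        assert fit.alpha == pytest.approx(0.0, abs=0.02)

    def test_scale_invariance(self, rng):
        ts = self._power_law_trajectories(0.3, rng)
        scaled = [traj(7.0 * t.deviations) for t in ts]
        a1 = fit_alpha(ts, n_boot=10, seed=1).alpha
        a2 = fit_alpha(scaled, n_boot=10, seed=1).alpha
        assert a1 == pytest.approx(a2, abs=1e-10)

    def test_insufficient_coverage_raises(self):
        ts = [traj([1.0, 1.0]) for _ in range(30)]
        with pytest.raises(InsufficientDataError):
            fit_alpha(ts)


class TestResidenceReturn:
    def _series(self, counts):
        counts = np.asarray(counts, int)
        return AbundanceSeries("a", np.arange(counts.size), counts,
                               np.full(counts.size, 100))

    def test_hand_scanned_example(self):
        res, ret = residence_return_times(self._series([0, 3, 5, 0, 0, 2, 0]))
        assert sorted(res.support.repeat(
            np.round(res.pmf * res.n_runs).astype(int))) == [1, 2]
        assert ret.as_dict() == {2: 1.0}

    def test_all_present_has_no_interior_runs(self):
        res, ret = residence_return_times(self._series([1] * 10))
        assert res is None and ret is None

    def test_exhaustive_length_10_against_brute_force(self):
        days = np.arange(10)
        for bits in itertools.product([0, 1], repeat=10):
            s = self._series(bits)
            pres = [1 if b else -1 for b in bits]
            expected = brute_force_interior_runs(pres)
            exp_res = sorted(e - s0 for s0, e, g in expected if g > 0)
            exp_ret = sorted(e - s0 for s0, e, g in expected if g < 0)
            res, ret = residence_return_times(s)
            got_res = sorted(res.support.repeat(np.round(
                res.pmf * res.n_runs).astype(int))) if res else []
            got_ret = sorted(ret.support.repeat(np.round(
                ret.pmf * ret.n_runs).astype(int))) if ret else []
            assert got_res == exp_res and got_ret == exp_ret


class TestMeanSojournTime:
    def test_hand_computed_mean(self):
        ts = [traj([1.0] * 2), traj([1.0] * 2), traj([1.0] * 4)]
        means, _ = mean_sojourn_time(ts, n_min=3)
        assert means["a"] == pytest.approx(8 / 3)

    def test_below_threshold_excluded(self):
        ts = [traj([1.0], asv="rare")] * 2 + [traj([1.0], asv="common")] * 5
        means, excluded = mean_sojourn_time(ts, n_min=5)
        assert "rare" in excluded and list(means.index) == ["common"]

    def test_two_asv_fixture_pooled_vs_per_asv(self):
        ts = ([traj([1.0] * t, asv="x") for t in (1, 2, 3, 2, 2)]
              + [traj([-1.0] * t, asv="y") for t in (4, 4, 1, 3, 3)])
        means, _ = mean_sojourn_time(ts, n_min=5)
        assert means["x"] == pytest.approx(2.0)
        assert means["y"] == pytest.approx(3.0)
        pooled = sojourn_time_distribution(ts).mean_T
        assert pooled == pytest.approx(2.5)
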