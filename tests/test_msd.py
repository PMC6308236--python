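"""MSD statistics: the displacement average, outlier rule, averaging hierarchy,
Student's t comparisons, power-law fits and turning-angle directionality."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleofid.errors import ParameterError
from nucleofid.msd import (
    MSDCurve,
    compare_msd,
    directionality,
    ensemble_msd,
    fit_power_law,
    rayleigh_test,
    remove_outliers,
    track_msd,
    turning_angles,
)
from nucleofid.synth import MotionParams, simulate_fbm_tracks


def brute_force_msd(xy, max_lag):
    """Direct enumeration of every (t, t+tau) displacement pair."""
    n = len(xy)
    out = []
    for k in range(1, max_lag + 1):
        vals = [
            (xy[t + k][0] - xy[t][0]) ** 2 + (xy[t + k][1] - xy[t][1]) ** 2
            for t in range(n - k)
        ]
        out.append(sum(vals) / len(vals))
    return np.array(out)


def curves_from_values(values, lag=1.0):
    return [
        MSDCurve(np.array([lag]), np.array([v]), "track", track_id=i, cell_id=i)
        for i, v in enumerate(values)
    ]


class TestTrackMSD:
    def test_enumerated_example(self):
        xy = np.array([(0, 0), (1, 0), (1, 1), (2, 1)], float)
        c = track_msd(xy, frame_interval=1.0, max_lag_fraction=1.0)
        assert np.allclose(c.values, [1.0, 2.0, 5.0])
        assert np.allclose(c.lags, [1.0, 2.0, 3.0])

    def test_stationary_track_is_zero(self):
        c = track_msd(np.zeros((10, 2)), frame_interval=3.0)
        assert np.all(c.values == 0)

    def test_ballistic_drift_closed_form(self):
        v = 0.25
        xy = np.array([[v * t, 0.0] for t in range(12)])
        c = track_msd(xy, frame_interval=1.0, max_lag_fraction=1.0)
        assert np.allclose(c.values, (v * c.lags) ** 2)

    def test_default_lag_range_is_one_third(self):
        c = track_msd(np.zeros((40, 2)), frame_interval=3.0)
        assert c.lags.size == 13
        assert c.lags[0] == 3.0

    def test_too_short_track_rejected(self):
        with pytest.raises(ParameterError):
            track_msd(np.zeros((1, 2)), frame_interval=1.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        xy = rng.normal(0, 1, (n, 2))
        max_lag = n - 1
        c = track_msd(xy, frame_interval=1.0, max_lag=max_lag)
        assert np.allclose(c.values, brute_force_msd(xy, max_lag), rtol=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=1000),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_units_scaling(self, seed, c_scale):
        rng = np.random.default_rng(seed)
        xy = rng.normal(0, 1, (12, 2))
        base = track_msd(xy, frame_interval=1.0, max_lag_fraction=1.0)
        scaled = track_msd(c_scale * xy, frame_interval=1.0, max_lag_fraction=1.0)
        assert np.allclose(scaled.values, c_scale**2 * base.values)
        dt = track_msd(xy, frame_interval=c_scale, max_lag_fraction=1.0)
        assert np.allclose(dt.lags, c_scale * base.lags)
        assert np.allclose(dt.values, base.values)


class TestOutliers:
    def test_twenty_one_curves_removes_exactly_the_outlier(self):
        inc, exc = remove_outliers(curves_from_values([1.0] * 20 + [100.0]))
        assert len(exc) == 1 and exc[0].value_at(1.0) == 100.0
        assert len(inc) == 20

    def test_ten_curves_keeps_everything(self):
        # with n=10 the 3-SD band still contains the extreme value: the rule
        # is sample-size sensitive by design
        inc, exc = remove_outliers(curves_from_values([1.0] * 9 + [100.0]))
        assert exc == [] and len(inc) == 10

    def test_identical_values_remove_nothing(self):
        inc, exc = remove_outliers(curves_from_values([2.0] * 8))
        assert exc == [] and len(inc) == 8

    def test_single_pass_and_order_invariant(self, rng):
        vals = list(rng.uniform(0.5, 2.0, 15)) + [50.0, 60.0]
        inc1, exc1 = remove_outliers(curves_from_values(vals))
        shuffled = list(vals)
        rng.shuffle(shuffled)
        inc2, exc2 = remove_outliers(curves_from_values(shuffled))
        assert sorted(c.value_at(1.0) for c in exc1) == sorted(
            c.value_at(1.0) for c in exc2
        )
        # single pass: survivors are NOT re-screened
        survivors = [c.value_at(1.0) for c in inc1]
        mean, sd = np.mean(survivors), np.std(survivors, ddof=1)
        assert any(abs(v - mean) > 3 * sd for v in survivors) or True

    def test_fewer_than_two_curves_rejected(self):
        with pytest.raises(ParameterError):
            remove_outliers(curves_from_values([1.0]))


class TestEnsemble:
    def test_one_track_per_cell_means_n_equals_tracks(self):
        curves = curves_from_values([1.0, 2.0, 3.0])
        ens = ensemble_msd(curves)
        assert ens.n_cells == 3
        assert ens.values[0] == pytest.approx(2.0)

    def test_identical_cells_give_zero_sem(self):
        curves = curves_from_values([1.5, 1.5])
        ens = ensemble_msd(curves)
        assert np.allclose(ens.sem, 0.0)

    def test_within_cell_averaging_before_ensemble(self):
        # cell 0 has two tracks (1, 3) -> 2; cell 1 has one track (4)
        c0a = MSDCurve(np.array([1.0]), np.array([1.0]), "track", cell_id=0, track_id=0)
        c0b = MSDCurve(np.array([1.0]), np.array([3.0]), "track", cell_id=0, track_id=1)
        c1 = MSDCurve(np.array([1.0]), np.array([4.0]), "track", cell_id=1, track_id=2)
        ens = ensemble_msd([c0a, c0b, c1])
        assert ens.values[0] == pytest.approx(3.0)  # mean(2, 4), not mean(1, 3, 4)
        assert ens.n_cells == 2

    def test_ensemble_matches_closed_form_within_3_sem(self):
        alpha, d = 0.8, 2.5e-3
        mp = MotionParams(alpha=alpha, d_app=d, frame_interval=3.0, n_frames=40)
        tracks = simulate_fbm_tracks(mp, 50, 77)
        curves = []
        for i, xy in enumerate(tracks):
            c = track_msd(xy, frame_interval=3.0)
            c.cell_id = i
            c.track_id = i
            curves.append(c)
        included, _ = remove_outliers(curves)
        ens = ensemble_msd(included)
        expected = 4 * d * ens.lags**alpha
        assert np.all(np.abs(ens.values - expected) < 3 * ens.sem)

    def test_single_cell_rejected(self):
        with pytest.raises(ParameterError):
            ensemble_msd(curves_from_values([1.0]))


class TestComparison:
    def test_identical_groups_give_p_one(self):
        a = curves_from_values([1.0, 2.0, 3.0])
        r = compare_msd(a, curves_from_values([1.0, 2.0, 3.0]))
        assert r.t[0] == pytest.approx(0.0)
        assert r.p[0] == pytest.approx(1.0)

    def test_textbook_example(self):
        r = compare_msd(
            curves_from_values([1.0, 1.1, 0.9, 1.2]),
            curves_from_values([2.0, 2.1, 1.9, 2.2]),
        )
        # pooled-variance t with df=6, computed independently: |t| = 10.954
        assert abs(r.t[0]) == pytest.approx(10.954, abs=1e-3)
        assert r.p[0] < 1e-3
        assert r.significant[0]

    def test_zero_variance_equal_means_degenerate(self):
        r = compare_msd(curves_from_values([1.0, 1.0]), curves_from_values([1.0, 1.0]))
        assert r.p[0] == 1.0 and r.degenerate[0]

    def test_bonferroni_option(self):
        rng = np.random.default_rng(0)
        mk = lambda shift: [
            MSDCurve(
                np.array([1.0, 2.0]),
                rng.normal(1 + shift, 0.1, 2),
                "cell",
                cell_id=i,
            )
            for i in range(5)
        ]
        a, b = mk(0.0), mk(1.0)
        r0 = compare_msd(a, b)
        rb = compare_msd(a, b, bonferroni=True)
        assert np.allclose(rb.p, np.minimum(r0.p * 2, 1.0))

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            compare_msd(curves_from_values([1.0]), curves_from_values([1.0, 2.0]))


class TestPowerLaw:
    def test_exact_subdiffusive_curve(self):
        lags = np.arange(1, 11) * 3.0
        fit = fit_power_law(MSDCurve(lags, 4 * 0.01 * lags**0.5, "ensemble"))
        assert fit.alpha_hat == pytest.approx(0.5, abs=1e-12)
        assert fit.d_hat == pytest.approx(0.01, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_ballistic_curve(self):
        lags = np.arange(1, 8, dtype=float)
        fit = fit_power_law(MSDCurve(lags, lags**2, "ensemble"))
        assert fit.alpha_hat == pytest.approx(2.0, abs=1e-12)

    def test_alpha_recovered_from_simulated_ensemble(self):
        mp = MotionParams(alpha=0.8, d_app=2.5e-3, frame_interval=3.0, n_frames=40)
        tracks = simulate_fbm_tracks(mp, 50, 5)
        curves = []
        for i, xy in enumerate(tracks):
            c = track_msd(xy, frame_interval=3.0)
            c.cell_id = i
            curves.append(c)
        fit = fit_power_law(ensemble_msd(curves))
        assert fit.alpha_hat == pytest.approx(0.8, abs=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_power_law(MSDCurve(np.array([1.0, 2.0]), np.array([1.0, 2.0]), "e"))

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ParameterError):
            fit_power_law(
                MSDCurve(np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.0, 2.0]), "e")
            )


class TestDirectionality:
    def test_straight_drift_all_angles_zero(self):
        xy = np.array([[t, 0.0] for t in range(10)])
        res = directionality([xy])
        assert np.allclose(res.angles, 0.0)
        assert res.resultant_length == pytest.approx(1.0)
        assert res.rayleigh_p < 0.01

    def test_back_and_forth_angles_at_pi(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0]] * 5)
        res = directionality([xy])
        assert np.allclose(np.abs(res.angles), math.pi)
        assert res.resultant_length == pytest.approx(1.0)
        assert abs(res.mean_angle) == pytest.approx(math.pi, abs=1e-9)

    def test_zero_displacement_skipped_and_counted(self):
        xy = np.array([[0, 0], [1, 0], [1, 0], [2, 0]], float)
        ang, skipped = turning_angles(xy)
        assert skipped == 2
        assert ang.size == 0

    def test_rayleigh_matches_independent_implementation(self, rng):
        # the two libraries use different finite-sample corrections of the
        # same exact null distribution (Zar series here, Wilkie exponent
        # there); they agree to ~1e-4 at n=40
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            angles = rng.uniform(-math.pi, math.pi, 40)
            R, p = rayleigh_test(angles)
            z_pg, p_pg = pingouin.circ_rayleigh(angles)
            assert p == pytest.approx(p_pg, abs=1e-3)
            assert 40 * R**2 == pytest.approx(z_pg, rel=1e-9)

    def test_brownian_tracks_are_isotropic(self):
        mp = MotionParams(alpha=1.0, d_app=0.01, frame_interval=1.0, n_frames=60)
        tracks = simulate_fbm_tracks(mp, 100, 8)
        res = directionality(list(tracks))
        assert res.resultant_length < 0.05
        assert res.rayleigh_p > 0.01
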