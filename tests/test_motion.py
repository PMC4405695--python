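"""Motion statistics: MSD, classification, pauses, reversals, comparison."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_track
from vesitrack.motion import (analyze_track, classify_track, compare_groups,
                              confinement_area, detect_pauses,
                              direction_changes, mean_speed, msd,
                              analyze_tracks)
from vesitrack.simulate import TrackSimParams, simulate_track


class TestMsd:
    def test_stationary_track_msd_zero(self):
        t = make_track([1.0] * 20)
        _, m = msd(t, 5)
        assert np.all(m == 0)

    def test_ballistic_identity(self):
        v, dt = 0.5, 2.0
        t = make_track(np.arange(30) * v * dt, frame_interval=dt)
        lag_t, m = msd(t, 10)
        assert m == pytest.approx(v**2 * lag_t**2, rel=1e-12)

    def test_confined_plateau_near_disc_value(self):
        # for positions ~uniform in a disc of radius R, E|x1-x2|^2 = R^2
        areas = []
        for seed in range(10):
            t = simulate_track(TrackSimParams(
                mode="confined", confinement_radius=0.5,
                diffusion_coefficient=0.05, n_frames=300,
                localization_noise_sd=0.0, seed=seed))
            _, m = msd(t, 20)
            areas.append(m[-1])
        assert np.mean(areas) == pytest.approx(0.25, rel=0.2)

    def test_max_lag_must_be_short_enough(self):
        with pytest.raises(ValueError):
            msd(make_track([0.0, 1.0]), 5)


class TestClassify:
    def test_directed_track_is_linear_with_exponent_two(self):
        t = make_track(np.arange(50) * 1.0, frame_interval=2.0)
        cls, alpha = classify_track(t)
        assert cls == "linear"
        assert alpha == pytest.approx(2.0, abs=1e-6)

    def test_confined_simulations_classified_confined(self):
        hits = 0
        for seed in range(30):
            t = simulate_track(TrackSimParams(
                mode="confined", confinement_radius=0.3,
                diffusion_coefficient=0.05, n_frames=200, seed=seed))
            hits += classify_track(t)[0] == "confined"
        assert hits >= 27

    def test_free_brownian_is_unclassified(self):
        # huge confinement radius = effectively free diffusion
        hits = 0
        for seed in range(30):
            t = simulate_track(TrackSimParams(
                mode="confined", confinement_radius=500.0,
                diffusion_coefficient=0.05, n_frames=200,
                localization_noise_sd=0.0, seed=seed))
            cls, alpha = classify_track(t)
            hits += cls == "unclassified"
            assert 0.4 < alpha < 1.6
        assert hits >= 24

    def test_short_track_unclassified(self):
        t = make_track(np.arange(10) * 1.0)
        assert classify_track(t)[0] == "unclassified"

    def test_degenerate_track_confined_by_convention(self):
        t = make_track([1.0] * 25)
        cls, alpha = classify_track(t)
        assert cls == "confined" and alpha == 0.0

    def test_threshold_ordering_enforced(self):
        t = make_track(np.arange(25) * 1.0)
        with pytest.raises(ValueError):
            classify_track(t, alpha_confined=1.5, alpha_linear=1.0)


class TestConfinementArea:
    def test_two_points_diameter_circle(self):
        t = make_track([0.0, 2.0])
        assert confinement_area(t) == pytest.approx(np.pi, rel=1e-12)

    def test_three_point_hand_case(self):
        t = make_track([0.0, 1.0, 0.5], [0.0, 0.0, 0.5])
        assert confinement_area(t) == pytest.approx(np.pi / 4, rel=1e-12)

    def test_identical_points_zero_area(self):
        t = make_track([1.0, 1.0, 1.0])
        assert confinement_area(t) == 0.0


class TestMeanSpeed:
    def test_hand_arithmetic(self):
        # displacements 0.2 and 0.4 µm over 2 s steps -> (0.1+0.2)/2
        t = make_track([0.0, 0.2, 0.6], frame_interval=2.0)
        assert mean_speed(t) == pytest.approx(0.15, abs=1e-12)

    def test_stationary_zero(self):
        assert mean_speed(make_track([0.0, 0.0, 0.0])) == 0.0

    def test_gap_uses_actual_elapsed_time(self):
        t = make_track([0.0, 0.2, 0.6], frames=[0, 1, 3], frame_interval=1.0)
        # steps: 0.2/1s and 0.4/2s -> (0.2 + 0.2)/2
        assert mean_speed(t) == pytest.approx(0.2, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        xy = rng.uniform(0, 5, (30, 2))
        t1 = make_track(xy[:, 0], xy[:, 1])
        theta = 1.234
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = xy @ R.T + np.array([10.0, -3.0])
        t2 = make_track(moved[:, 0], moved[:, 1])
        assert mean_speed(t1) == pytest.approx(mean_speed(t2), rel=1e-12)


class TestPauses:
    def test_fast_track_has_no_pauses(self):
        t = make_track(np.arange(10) * 0.5)
        assert detect_pauses(t).n_pauses == 0

    def test_hand_enumerated_onsets(self):
        # step speeds 0.5, 0.05, 0.05, 0.5, 0.05 at 1 s steps
        xs = np.cumsum([0.0, 0.5, 0.05, 0.05, 0.5, 0.05])
        res = detect_pauses(make_track(xs))
        assert res.n_pauses == 2
        assert res.pause_rate == pytest.approx(0.4, abs=1e-12)
        assert res.segments == [(1, 2), (4, 4)]

    def test_threshold_is_strict_less_than(self):
        t = make_track([0.0, 0.1, 0.2])   # steps at exactly 0.1 µm/s
        assert detect_pauses(t).n_pauses == 0
        t2 = make_track([0.0, 0.0999])
        assert detect_pauses(t2).n_pauses == 1


class TestDirectionChanges:
    def test_monotone_run_has_no_changes(self):
        res = direction_changes(make_track(np.arange(10) * 1.0))
        assert res.count == 0 and res.rate == 0.0

    def test_hand_enumerated_zigzag(self):
        res = direction_changes(make_track([0, 1, 2, 1, 0, 1, 2]))
        assert res.count == 2
        assert res.rate == pytest.approx(2 / 6, abs=1e-12)

    def test_reflection_invariance(self, rng):
        xy = rng.uniform(0, 3, (40, 2))
        t1 = make_track(xy[:, 0], xy[:, 1])
        t2 = make_track(-xy[:, 0], -xy[:, 1])
        assert direction_changes(t1).count == direction_changes(t2).count

    def test_all_paused_reports_missing_rate(self):
        t = make_track([0.0, 0.001, 0.002, 0.001])
        res = direction_changes(t)
        assert res.rate is None

    def test_paused_steps_excluded_from_tabulation(self):
        # out, pause-with-tiny-backstep, on: the sub-threshold backstep
        # must not register as two direction changes
        t = make_track([0.0, 1.0, 0.99, 1.99])
        assert direction_changes(t).count == 0


class TestCompareGroups:
    def _reports(self, values):
        import pandas as pd
        return pd.DataFrame({"mean_speed": values,
                             "track_id": [str(i) for i in range(len(values))]})

    def test_identical_groups_p_near_one(self):
        a = self._reports(np.linspace(0.1, 1.0, 20))
        res = compare_groups(a, a.copy(), "mean_speed")
        assert res.pvalue > 0.99
        assert res.fold_change == pytest.approx(1.0)

    def test_shifted_groups_detected(self, rng):
        hits = 0
        for _ in range(100):
            a = self._reports(rng.normal(0, 1, 50))
            b = self._reports(rng.normal(2, 1, 50))   # shift = 2 SD
            hits += compare_groups(a, b, "mean_speed").pvalue < 1e-3
        assert hits >= 95

    def test_absent_metric_rejected(self):
        a = self._reports([1.0, 2.0])
        with pytest.raises(ValueError, match="no_such"):
            compare_groups(a, a, "no_such")

    def test_single_observation_groups_still_valid(self):
        res = compare_groups(self._reports([1.0]), self._reports([2.0]),
                             "mean_speed")
        assert np.isfinite(res.statistic) and 0 <= res.pvalue <= 1


class TestAnalyzeTrack:
    def test_fields_match_class(self):
        lin = analyze_track(make_track(np.arange(40) * 1.0, frame_interval=2.0))
        assert lin.track_class == "linear"
        assert np.isnan(lin.confinement_area)
        assert np.isfinite(lin.direction_changes_per_s)
        conf = analyze_track(simulate_track(TrackSimParams(
            mode="confined", seed=4, n_frames=100)))
        assert conf.track_class == "confined"
        assert np.isfinite(conf.confinement_area)
        assert np.isnan(conf.direction_changes_per_s)

    def test_welch_null_pvalues_uniform(self, rng):
        # sanity of the downstream Welch comparison: p under the null is
        # uniform even with unequal variances
        from vesitrack.golgi import CellScore, compare_conditions

        def scores(sd, n):
            return [CellScore(i, 1, 1, 0.5, 1, float(v), 1, 4.11)
                    for i, v in enumerate(rng.normal(0, sd, n))]
        pvals = [compare_conditions(scores(1.0, 20), scores(3.0, 20)).pvalue
                 for _ in range(200)]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
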