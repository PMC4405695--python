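"""TIRF metrics: microtubule length, motor density, moving fraction, lifespans."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_track
from vesitrack.images import LabelImage
from vesitrack.simulate import simulate_motor_field
from vesitrack.single_molecule import (classify_moving, lifespan_stats,
                                       microtubule_length, motor_assay_report,
                                       motor_density, percent_moving)
from vesitrack.tracks import SpotTable


def _spots(rows, pixel_size=0.1):
    df = pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "intensity"])
    return SpotTable(df, pixel_size=pixel_size)


class TestMicrotubuleLength:
    def test_thin_horizontal_line_is_step_count(self):
        m = np.zeros((20, 120), dtype=np.int64)
        m[10, 10:110] = 1   # 100 px -> 99 axial steps
        _, total = microtubule_length(LabelImage(m, 0.1))
        assert total == pytest.approx(9.9, abs=1e-9)

    def test_wide_bar_close_to_axial_length(self):
        m = np.zeros((20, 120), dtype=np.int64)
        m[8:11, 10:110] = 1   # 3 px wide, 100 px long
        _, total = microtubule_length(LabelImage(m, 0.1))
        assert total == pytest.approx(9.9, abs=0.2)

    def test_diagonal_line_uses_sqrt2_steps(self):
        m = np.zeros((120, 120), dtype=np.int64)
        idx = np.arange(50)
        m[10 + idx, 10 + idx] = 1
        _, total = microtubule_length(LabelImage(m, 0.1))
        assert total == pytest.approx(49 * np.sqrt(2) * 0.1, abs=1e-9)

    def test_random_fields_recover_known_total_length(self):
        # digital straight lines carry the classical chain-code length
        # bias (up to ~+8% at 22.5 degrees, ~+5% on average); the
        # estimate must stay within that envelope of the true length
        errs = []
        for seed in range(10):
            fld = simulate_motor_field(60.0, 0.0, 0.0, 0.0, 1.0, 2, seed=seed)
            _, total = microtubule_length(fld.mask)
            rel = total / fld.total_length - 1
            assert abs(rel) < 0.10
            errs.append(rel)
        assert abs(np.mean(errs)) < 0.08

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            microtubule_length(LabelImage(np.zeros((5, 5), dtype=np.int64), 0.1))


class TestMotorDensity:
    def _mask(self):
        m = np.zeros((50, 450), dtype=np.int64)
        m[25, 20:421] = 1   # 401 px -> 400 steps -> 40 µm at 0.1 µm/px
        return LabelImage(m, 0.1)

    def test_hand_arithmetic(self):
        mask = self._mask()
        rows = [(f, 2.0 + 3.5 * i, 2.5, 1.0) for f in range(5)
                for i in range(10)]
        density = motor_density(_spots(rows), mask, mt_length=40.0)
        assert density == pytest.approx(10 / 40.0, abs=1e-12)

    def test_no_spots_zero_density(self):
        density = motor_density(_spots([(0, 2.0, 4.0, 1.0)]), self._mask(),
                                mt_length=40.0)
        assert density == 0.0   # single off-mask spot

    def test_rotation_invariance(self):
        mask = self._mask()
        rows = [(0, 2.0 + 3.5 * i, 2.5, 1.0) for i in range(10)]
        d0 = motor_density(_spots(rows), mask, 40.0)
        rot = LabelImage(np.rot90(mask.labels).copy(), 0.1)
        h_um = mask.labels.shape[1] * 0.1
        rot_rows = [(0, y, h_um - x - 0.1, 1.0) for _, x, y, _ in rows]
        d90 = motor_density(_spots(rot_rows), rot, 40.0)
        assert d90 == pytest.approx(d0, rel=1e-9)

    def test_requires_positive_length(self):
        with pytest.raises(ValueError):
            motor_density(_spots([(0, 1.0, 1.0, 1.0)]), self._mask(), 0.0)


class TestClassifyMoving:
    def test_clear_mover(self):
        t = make_track([0.0, 0.5], frame_interval=1.0)
        assert classify_moving(t) is True

    def test_boundaries_are_strict(self):
        assert classify_moving(make_track([0.0, 0.12], frame_interval=1.0)) is False
        assert classify_moving(make_track([0.0, 0.2], frame_interval=1.0)) is False
        assert classify_moving(make_track([0.0, 0.45], frame_interval=0.9)) is False

    def test_short_track_counts_in_denominator(self):
        fast_short = make_track([0.0, 0.3], frame_interval=0.5)
        mover = make_track([0.0, 0.5], frame_interval=1.0)
        assert classify_moving(fast_short) is False
        assert percent_moving([fast_short, mover]) == pytest.approx(50.0)

    def test_path_length_variant_differs_for_zigzag(self):
        zig = make_track([0, 0.1, 0, 0.1, 0, 0.1], frame_interval=0.2)
        assert classify_moving(zig) is False
        assert classify_moving(zig, use_path_length=True) is True

    def test_monotone_in_thresholds(self, rng):
        tracks = []
        for _ in range(50):
            n = int(rng.integers(2, 40))
            tracks.append(make_track(np.cumsum(rng.normal(0, 0.05, n)),
                                     np.cumsum(rng.normal(0, 0.05, n)),
                                     frame_interval=0.1))
        base = percent_moving(tracks)
        for kw in ({"speed_min": 0.2}, {"distance_min": 0.4},
                   {"duration_min": 1.5}):
            assert percent_moving(tracks, **kw) <= base


class TestLifespans:
    def test_median_of_three(self):
        tracks = [make_track([0, 1], frame_interval=s / 1)
                  for s in (0.4, 0.7, 5.0)]
        assert lifespan_stats(tracks)["median_lifespan"] == pytest.approx(0.7)

    def test_single_track(self):
        t = make_track([0, 1, 2], frame_interval=0.5)
        assert lifespan_stats([t])["median_lifespan"] == pytest.approx(1.0)

    def test_exponential_median_is_ln2_times_mean(self, rng):
        # observed lifespans of exponential(mean=1) tracks
        spans = rng.exponential(1.0, 1000)
        tracks = [make_track([0.0, 0.1], frame_interval=s) for s in spans]
        med = lifespan_stats(tracks)["median_lifespan"]
        # SE of the median of n exponentials ~ 1/sqrt(n) scaled
        se = np.log(2) / np.sqrt(len(spans))
        assert abs(med - np.log(2)) < 3 * se

    def test_survival_fraction(self):
        tracks = [make_track([0, 1], frame_interval=s) for s in (0.5, 1.5, 2.5)]
        out = lifespan_stats(tracks, cutoff=1.0)
        assert out["fraction_beyond_cutoff"] == pytest.approx(2 / 3)


class TestFullPipelineRecovery:
    def test_density_and_moving_fraction_recovered(self):
        # zero-noise end-to-end: field -> (truth spots) -> link -> metrics
        from vesitrack.tracks import link_spots
        densities, pms = [], []
        m_true = 0.3
        for seed in range(25):
            fld = simulate_motor_field(
                60.0, 0.25, m_true, 0.4, 20.0, 40, frame_interval=0.1,
                seed=seed, min_spot_separation=0.8)
            _, total = microtubule_length(fld.mask)
            densities.append(motor_density(fld.spots, fld.mask, total))
            tracks = link_spots(fld.spots, max_disp=0.15, frame_interval=0.1)
            if tracks:
                pms.append(percent_moving(tracks))
        densities = np.array(densities)
        assert abs(densities.mean() / 0.25 - 1) < 0.10
        # with 20 s lifespans nearly every truly moving track passes the
        # 0.9 s / 0.2 µm / 0.12 µm/s criteria, so percent moving tracks
        # the simulated moving fraction
        pms = np.array(pms)
        se = pms.std(ddof=1) / np.sqrt(len(pms))
        assert abs(pms.mean() - 100 * m_true) < 3 * se + 5.0


def test_report_assembly():
    fld = simulate_motor_field(50.0, 0.2, 0.0, 0.0, 50.0, 10,
                               frame_interval=0.1, seed=3)
    from vesitrack.tracks import link_spots
    tracks = link_spots(fld.spots, max_disp=0.2, frame_interval=0.1)
    rep = motor_assay_report(tracks, fld.spots, fld.mask)
    assert rep.mt_total_length > 0
    assert 0 <= rep.percent_moving <= 100
    assert rep.n_motors == len(tracks)
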