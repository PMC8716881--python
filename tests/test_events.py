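import numpy as np
import pytest

import landsyn as ls
from landsyn.events import LandingSegmentation
from landsyn.exceptions import SegmentationError


class TestTouchdownDetection:
    def test_first_sample_strictly_above_threshold(self):
        v = np.array([0.0, 5.0, 19.0, 21.0, 400.0])
        assert ls.detect_touchdown(v) == 3

    def test_flight_noise_at_threshold_not_detected(self):
        v = np.concatenate([np.full(50, 19.9), [20.0, 19.5, 25.0, 400.0]])
        assert ls.detect_touchdown(v) == 52  # 20.0 exactly does not cross

    def test_no_crossing_is_an_error(self):
        with pytest.raises(SegmentationError):
            ls.detect_touchdown(np.full(100, 5.0))

    def test_matches_generator_ground_truth(self, sg_cohort):
        for trial in sg_cohort:
            assert ls.detect_touchdown(trial.vgrf) == trial.touchdown_sample_true


class TestStanceEnd:
    def _landing(self, bw=700.0):
        # impact peak 3 BW at 10, dip to 0.6 BW at 30, linear rise after
        v = np.zeros(200)
        v[5:10] = np.linspace(25, 3 * bw, 5)
        v[10:30] = np.linspace(3 * bw, 0.6 * bw, 20)
        v[30:] = np.linspace(0.6 * bw, 1.1 * bw, 171)[1:]  # strict dip at 29
        return v

    def test_first_band_entry_after_post_impact_minimum(self):
        bw = 700.0
        v = self._landing(bw)
        idx = ls.detect_stance_end(v, touchdown=5, bodyweight=bw)
        rise = v[29:]
        expected = 29 + int(np.argmax(rise >= 0.975 * bw))
        assert idx == expected
        assert 0.975 * bw <= v[idx] <= 1.025 * bw

    def test_minimum_already_inside_band_returns_that_sample(self):
        bw = 100.0
        v = np.concatenate([[0, 50, 300, 200, 150], [98.0], np.full(20, 101.0)])
        assert ls.detect_stance_end(v, touchdown=1, bodyweight=bw) == 5

    def test_band_never_entered_is_an_error(self):
        v = np.concatenate([[0, 30, 900], np.linspace(900, 400, 50)])
        with pytest.raises(SegmentationError):
            ls.detect_stance_end(v, touchdown=1, bodyweight=700.0)


class TestTimeNormalization:
    def _seg(self, td=300, end=791):
        return LandingSegmentation(touchdown_index=td,
                                   interval_start_index=td - 300,
                                   stance_end_index=end)

    def test_output_has_exactly_300_points(self, sg_cohort):
        trial = sg_cohort[0]
        seg = ls.segment_landing(trial.vgrf, trial.bodyweight)
        out = ls.time_normalize(trial.emg_raw, trial.grf, seg, cop=trial.cop)
        assert out.emg.shape == (13, 300)
        assert out.grf_norm.shape == (300,)
        assert out.cop.shape == (2, 300)

    def test_affine_signals_resampled_exactly(self):
        seg = self._seg()
        x = np.arange(1000, dtype=float)[None, :]
        out = ls.time_normalize_channels(x, seg)
        flight, stance = out[0, :100], out[0, 100:]
        assert np.allclose(np.diff(flight), np.diff(flight)[0])
        assert np.allclose(np.diff(stance), np.diff(stance)[0])
        assert stance[0] == pytest.approx(seg.touchdown_index)

    def test_sg_mean_duration_maps_monotonically_without_nans(self):
        seg = self._seg(td=300, end=300 + 491)
        x = np.linspace(0, 1, 900)[None, :] ** 2
        out = ls.time_normalize_channels(x, seg)[0]
        assert np.all(np.isfinite(out))
        assert np.all(np.diff(out) >= 0)

    def test_stance_start_is_touchdown_sample(self, sg_cohort):
        for trial in sg_cohort:
            seg = ls.segment_landing(trial.vgrf, trial.bodyweight)
            assert abs(seg.touchdown_index - trial.touchdown_sample_true) <= 1

    def test_segmentation_deterministic(self, sg_cohort):
        trial = sg_cohort[0]
        a = ls.segment_landing(trial.vgrf, trial.bodyweight)
        b = ls.segment_landing(trial.vgrf, trial.bodyweight)
        assert a == b


class TestCopEllipse:
    def test_identical_points_give_zero_area(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert ls.cop_ellipse_area(np.ones((50, 2))) == 0.0

    def test_quadratic_scaling_with_coordinates(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((500, 2)) * 0.01
        a1 = ls.cop_ellipse_area(pts)
        a3 = ls.cop_ellipse_area(3.0 * pts)
        assert a3 == pytest.approx(9.0 * a1, rel=1e-9)

    def test_isotropic_normal_matches_analytic_area(self):
        sigma = 0.01
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((100_000, 2)) * sigma
        expected = np.pi * 5.991 * sigma**2
        assert ls.cop_ellipse_area(pts) == pytest.approx(expected, rel=0.05)


class TestMomentScalars:
    def _seg(self):
        return LandingSegmentation(touchdown_index=300,
                                   interval_start_index=0,
                                   stance_end_index=800)

    def test_triangle_peak_rate(self):
        m = np.zeros(900)
        m[300:351] = np.linspace(0, 100, 51)   # peak 100 Nm at +50 ms
        m[351:401] = np.linspace(100, 0, 51)[1:]
        res = ls.moment_scalars(m, self._seg())
        assert res.max == pytest.approx(100.0)
        assert res.time_to_peak == pytest.approx(0.050)
        assert res.rate == pytest.approx(2000.0)

    def test_constant_series_rate_undefined(self):
        with pytest.warns(UserWarning, match="rate undefined"):
            res = ls.moment_scalars(np.full(900, 5.0), self._seg())
        assert res.rate_undefined and res.rate is None

    def test_range_of_motion_zero_when_touchdown_is_minimum(self):
        angle = np.concatenate([np.full(300, 10.0), np.linspace(10, 40, 600)])
        m = np.zeros(900)
        m[400] = 1.0
        res = ls.moment_scalars(m, self._seg(), angle=angle)
        assert res.range_of_motion == pytest.approx(0.0)
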