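"""Fluorescence spot detection, cross-channel distances and time-lapse traces."""

import numpy as np
import pytest

from fixclust.exceptions import ParameterError
from fixclust.spots import (
    SpotField,
    TimeLapseTrace,
    condition_compare,
    cross_channel_nn,
    detect_aggregation_onset,
    detect_spots,
    equalize_density,
    track_spot,
)

PX = 0.05  # um per pixel


def _spot_image(centers_um, amps=1.0, fwhm=0.25, n=200):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    y, x = np.mgrid[0:n, 0:n] * PX
    img = np.zeros((n, n))
    amps = np.broadcast_to(np.asarray(amps, float), (len(centers_um),))
    for (cx, cy), a in zip(centers_um, amps):
        img += a * np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2)))
    return img


def _matched_diameter(fwhm=0.25):
    return 2 * np.sqrt(2) * fwhm / (2 * np.sqrt(2 * np.log(2)))


class TestDetect:
    def test_single_spot_localized_with_unit_quality(self):
        img = _spot_image([(5.0, 5.0)])
        sf = detect_spots(img, PX, diameter=_matched_diameter())
        assert len(sf) == 1
        assert sf.xy[0] == pytest.approx((5.0, 5.0), abs=0.02)
        assert sf.quality[0] == pytest.approx(1.0, rel=0.05)

    def test_blank_image(self):
        assert len(detect_spots(np.zeros((64, 64)), PX)) == 0

    def test_jittered_field_recall_and_precision(self, rng):
        """50 spots with 20% amplitude jitter: >=48 recovered, <=1 spurious."""
        centers = np.column_stack(
            [(0.8 + 1.24 * (np.arange(50) % 7)) + rng.uniform(-0.2, 0.2, 50),
             (0.8 + 1.24 * (np.arange(50) // 7)) + rng.uniform(-0.2, 0.2, 50)]
        )
        amps = 1.0 + rng.uniform(-0.2, 0.2, 50)
        img = _spot_image(centers, amps)
        img += rng.normal(0, 0.02, img.shape)
        sf = detect_spots(img, PX, diameter=_matched_diameter(), quality_threshold=0.2)
        d = np.sqrt(((sf.xy[:, None, :] - centers[None]) ** 2).sum(-1))
        matched = (d.min(axis=1) <= 0.05).sum()
        assert matched >= 48
        assert len(sf) - matched <= 1

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ParameterError):
            detect_spots(np.zeros((32, 32)), pixel_size=0.5, diameter=0.5)

    def test_crop_polygon_filters_spots(self):
        img = _spot_image([(2.0, 2.0), (8.0, 8.0)])
        crop = np.array([(0.0, 0.0), (5.0, 0.0), (5.0, 5.0), (0.0, 5.0)])
        sf = detect_spots(img, PX, diameter=_matched_diameter(), crop_polygon=crop)
        assert len(sf) == 1 and sf.xy[0] == pytest.approx((2.0, 2.0), abs=0.02)


class TestEqualize:
    def test_denser_channel_trimmed_by_quality(self, rng):
        a = SpotField(rng.uniform(0, 10, (100, 2)), rng.uniform(0, 1, 100))
        b = SpotField(rng.uniform(0, 10, (80, 2)), rng.uniform(0, 1, 80))
        a2, b2 = equalize_density(a, b)
        assert len(a2) == len(b2) == 80
        kept = set(map(tuple, a2.xy))
        top80 = a.xy[np.argsort(a.quality)[::-1][:80]]
        assert kept == set(map(tuple, top80))

    def test_equal_counts_unchanged(self, rng):
        a = SpotField(rng.uniform(0, 10, (30, 2)), rng.uniform(0, 1, 30))
        b = SpotField(rng.uniform(0, 10, (30, 2)), rng.uniform(0, 1, 30))
        a2, b2 = equalize_density(a, b)
        assert np.array_equal(a2.xy, a.xy) and np.array_equal(b2.xy, b.xy)

    def test_empty_channel_rejected(self):
        a = SpotField(np.empty((0, 2)), np.empty(0))
        b = SpotField(np.ones((3, 2)), np.ones(3))
        with pytest.raises(ParameterError):
            equalize_density(a, b)


class TestCrossChannelNN:
    def test_single_pair(self):
        a = SpotField(np.array([[0.0, 0.0]]), np.ones(1))
        b = SpotField(np.array([[0.3, 0.4]]), np.ones(1))
        res = cross_channel_nn(a, b)
        assert np.allclose(res.per_spot_distances, [0.5])
        assert res.cell_mean == pytest.approx(0.5)

    def test_identical_coordinates_zero(self, rng):
        xy = rng.uniform(0, 5, (20, 2))
        res = cross_channel_nn(SpotField(xy, np.ones(20)), SpotField(xy, np.ones(20)))
        assert np.all(res.per_spot_distances == 0.0)

    def test_matches_exhaustive_oracle(self, rng):
        a = SpotField(rng.uniform(0, 20, (300, 2)), np.ones(300))
        b = SpotField(rng.uniform(0, 20, (300, 2)), np.ones(300))
        res = cross_channel_nn(a, b)
        full = np.sqrt(((a.xy[:, None, :] - b.xy[None]) ** 2).sum(-1)).min(axis=1)
        assert np.array_equal(res.per_spot_distances, full)
        assert res.cell_mean == pytest.approx(full.mean())


def _textbook_t(a, b):
    """Pooled-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as tdist

    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / (n1 + n2 - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, 2 * tdist.sf(abs(t), n1 + n2 - 2)


class TestConditionCompare:
    def test_identical_groups_p_one(self):
        rep = condition_compare(
            {"living": np.array([1.0, 2.0, 3.0]), "ga": np.array([1.0, 2.0, 3.0])},
            reference="living",
        )
        assert rep["tests"]["ga"]["p"] == pytest.approx(1.0)

    def test_hand_computed_t(self):
        rep = condition_compare(
            {"living": np.array([4.0, 5.0, 6.0]), "fix": np.array([1.0, 2.0, 3.0])},
            reference="living",
        )
        assert rep["tests"]["fix"]["t"] == pytest.approx(-3.674, abs=1e-3)
        assert rep["tests"]["fix"]["p"] == pytest.approx(0.0214, abs=1e-3)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.normal(size=12), rng.normal(0.4, size=15)
        rep = condition_compare({"ref": a, "cond": b}, reference="ref")
        t, p = _textbook_t(b, a)
        assert rep["tests"]["cond"]["t"] == pytest.approx(t, abs=1e-9)
        assert rep["tests"]["cond"]["p"] == pytest.approx(p, abs=1e-9)

    def test_mean_sem_reported(self):
        rep = condition_compare(
            {"ref": np.array([1.0, 3.0]), "c": np.array([2.0, 4.0])}, reference="ref"
        )
        assert rep["conditions"]["ref"]["mean"] == pytest.approx(2.0)
        assert rep["conditions"]["ref"]["sem"] == pytest.approx(1.0)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ParameterError):
            condition_compare({"ref": np.array([1.0])}, reference="ref")


def _frames_stationary(n_frames, a_xy, b_xy):
    return [
        (
            SpotField(np.asarray(a_xy, float), np.ones(len(a_xy))),
            SpotField(np.asarray(b_xy, float), np.ones(len(b_xy))),
        )
        for _ in range(n_frames)
    ]


class TestTrackAndOnset:
    def test_stationary_pair_flat_trace(self):
        frames = _frames_stationary(10, [[1.0, 1.0]], [[1.4, 1.0]])
        trace = track_spot(frames, (1.0, 1.0), max_disp=0.2)
        assert len(trace.times) == 10
        assert np.allclose(trace.distances, 0.4)

    def test_vanishing_spot_truncates_trace(self):
        frames = _frames_stationary(10, [[1.0, 1.0]], [[1.4, 1.0]])
        for f in range(5, 10):
            frames[f] = (SpotField(np.array([[9.0, 9.0]]), np.ones(1)), frames[f][1])
        trace = track_spot(frames, (1.0, 1.0), max_disp=0.2)
        assert len(trace.times) == 5

    def test_missing_start_spot_rejected(self):
        frames = _frames_stationary(3, [[1.0, 1.0]], [[1.4, 1.0]])
        with pytest.raises(ParameterError):
            track_spot(frames, (5.0, 5.0), max_disp=0.2)

    def test_step_trace_onset(self):
        t = np.arange(-10.0, 30.0, 2.0)
        d = np.where(t < 10.0, 0.5, 0.1)
        trace = TimeLapseTrace(t, d, fixation_time=0.0)
        assert detect_aggregation_onset(trace, low_threshold=0.2, hold=3) == 10.0

    def test_never_below_threshold(self):
        t = np.arange(0.0, 20.0, 2.0)
        trace = TimeLapseTrace(t, np.full_like(t, 0.5), fixation_time=0.0)
        assert detect_aggregation_onset(trace, low_threshold=0.2) is None

    def test_short_dips_ignored(self):
        t = np.arange(0.0, 20.0, 2.0)
        d = np.full_like(t, 0.5)
        d[3:5] = 0.1  # two frames only
        trace = TimeLapseTrace(t, d, fixation_time=0.0)
        assert detect_aggregation_onset(trace, low_threshold=0.2, hold=3) is None
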