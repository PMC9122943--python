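"""Half-max protrusion detection, profiles, persistence and statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from conftest import HALF_MAX_AREA, gaussian_bump
from fixclust.afm import TopographyImage
from fixclust.exceptions import ParameterError
from fixclust.protrusions import (
    DetectParams,
    ProtrusionSet,
    detect_protrusions,
    fwhm_along_line,
    mann_whitney_u,
    match_across_frames,
    nearest_distances,
    summarize_condition,
)


def _detect(z, px=1.0, **kw):
    params = dict(min_prominence=1.0, background_radius=50.0, min_area=5.0)
    params.update(kw)
    return detect_protrusions(TopographyImage(z, px), DetectParams(**params))


class TestDetect:
    @pytest.mark.parametrize("sigma", [4.0, 8.0])
    def test_gaussian_half_max_area_closed_form(self, sigma):
        """Half-max contour of an isotropic Gaussian encloses 2*pi*ln2*sigma^2."""
        ps = _detect(gaussian_bump(int(16 * sigma), sigma), background_radius=6 * sigma)
        assert len(ps) == 1
        assert ps.areas[0] == pytest.approx(HALF_MAX_AREA * sigma**2, rel=0.05)

    def test_boundary_lies_at_half_max_level(self):
        """Interpolated height along the boundary equals b + peak_height/2."""
        z = gaussian_bump(96, 6.0)
        img = TopographyImage(z, 1.0)
        ps = _detect(z)
        p = ps.protrusions[0]
        level = p.peak_height / 2.0  # background is 0 here
        heights = ndimage.map_coordinates(
            img.heights, [p.boundary[:, 1], p.boundary[:, 0]], order=1
        )
        assert np.all(np.abs(heights - level) < 0.02 * p.peak_height)

    def test_area_matches_shoelace_of_boundary(self):
        ps = _detect(gaussian_bump(96, 6.0))
        p = ps.protrusions[0]
        x, y = p.boundary[:, 0], p.boundary[:, 1]
        shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert p.area == pytest.approx(shoelace, rel=1e-6)

    def test_peak_inside_boundary_and_centroid_near_peak(self):
        ps = _detect(gaussian_bump(96, 6.0, center=(40.0, 50.0)))
        p = ps.protrusions[0]
        assert p.peak_xy == pytest.approx((40.0, 50.0), abs=0.1)
        assert p.centroid_xy == pytest.approx((40.0, 50.0), abs=0.2)

    def test_two_bumps_nearest_distances(self):
        z = gaussian_bump(96, 4.0, center=(33.0, 48.0)) + gaussian_bump(
            96, 4.0, center=(63.0, 48.0)
        )
        ps = _detect(z)
        assert len(ps) == 2
        assert np.allclose(sorted(ps.nn_distances), [30.0, 30.0], atol=0.2)

    def test_flat_image_gives_empty_set(self):
        ps = _detect(np.zeros((32, 32)))
        assert len(ps) == 0 and len(ps.nn_distances) == 0

    def test_translation_equivariance(self):
        """Whole-pixel shifts move centroids by exactly the shift."""
        z = gaussian_bump(128, 5.0, center=(50.0, 60.0))
        a = _detect(z)
        b = _detect(np.roll(z, (7, 11), axis=(0, 1)))
        delta = np.asarray(b.protrusions[0].centroid_xy) - np.asarray(
            a.protrusions[0].centroid_xy
        )
        assert np.allclose(delta, [11.0, 7.0], atol=1e-6)

    def test_min_area_filters_small_bumps(self):
        z = gaussian_bump(96, 5.0) + gaussian_bump(96, 1.2, center=(20.0, 20.0))
        ps = _detect(z, min_area=20.0)
        assert len(ps) == 1

    def test_border_touching_excluded(self):
        z = gaussian_bump(64, 6.0, center=(2.0, 32.0))
        assert len(_detect(z)) == 0
        assert len(_detect(z, exclude_border=False)) == 1


class TestFWHM:
    def test_triangle_peak(self):
        z = np.tile(np.concatenate([np.zeros(10), 10 - np.abs(np.arange(-10, 11)), np.zeros(10)]), (5, 1)).astype(float)
        img = TopographyImage(z, 1.0)
        widths = fwhm_along_line(img, (0.0, 2.0), (40.0, 2.0))
        assert len(widths) == 1
        assert widths[0] == pytest.approx(10.0, rel=0.02)

    def test_gaussian_profile_closed_form(self):
        sigma = 5.0
        x = np.arange(80.0)
        z = np.tile(10 * np.exp(-((x - 40) ** 2) / (2 * sigma**2)), (5, 1))
        img = TopographyImage(z, 1.0)
        widths = fwhm_along_line(img, (0.0, 2.0), (79.0, 2.0))
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert widths[0] == pytest.approx(expected, rel=0.02)

    def test_no_peak_gives_empty(self):
        img = TopographyImage(np.zeros((8, 8)), 1.0)
        assert fwhm_along_line(img, (0.0, 4.0), (7.0, 4.0)) == []

    def test_endpoint_outside_rejected(self):
        img = TopographyImage(np.zeros((8, 8)), 1.0)
        with pytest.raises(ParameterError):
            fwhm_along_line(img, (0.0, 0.0), (100.0, 0.0))


class TestNearestDistances:
    def test_two_points(self):
        assert np.allclose(nearest_distances([(0, 0), (3, 4)]), [5.0, 5.0])

    def test_collinear(self):
        assert np.allclose(nearest_distances([(0, 0), (1, 0), (10, 0)]), [1, 1, 9])

    def test_fewer_than_two_points(self):
        assert nearest_distances([(1.0, 2.0)]).size == 0

    def test_matches_exhaustive_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(200, 2))
        d = nearest_distances(pts)
        diff = pts[:, None, :] - pts[None, :, :]
        full = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(full, np.inf)
        assert np.array_equal(d, full.min(axis=1))


def _sets_from_centroids(frames):
    from fixclust.protrusions import Protrusion

    out = []
    for pts in frames:
        prots = [
            Protrusion(
                peak_xy=tuple(p), peak_height=1.0,
                boundary=np.array([[p[0] - 1, p[1] - 1], [p[0] + 1, p[1] - 1],
                                   [p[0] + 1, p[1] + 1], [p[0] - 1, p[1] + 1]]),
                area=4.0, centroid_xy=tuple(p),
            )
            for p in pts
        ]
        out.append(ProtrusionSet(prots))
    return out


class TestPersistence:
    def test_identical_frames_all_persistent(self):
        pts = [(10.0, 10.0), (30.0, 10.0), (10.0, 30.0), (50.0, 50.0), (70.0, 20.0)]
        res = match_across_frames(_sets_from_centroids([pts] * 3), max_disp=5.0, k_min=3)
        assert res.persistent_count == 5
        assert res.drift_per_frame == (0.0, 0.0)

    def test_empty_frames(self):
        res = match_across_frames(_sets_from_centroids([[], [], []]), max_disp=5.0)
        assert res.persistent_count == 0

    def test_single_frame_feature_not_persistent(self):
        frames = [[(10.0, 10.0)], [(10.0, 10.0), (40.0, 40.0)], [(10.0, 10.0)]]
        res = match_across_frames(_sets_from_centroids(frames), max_disp=5.0, k_min=3)
        assert res.persistent_count == 1

    def test_too_few_frames_rejected(self):
        with pytest.raises(ParameterError):
            match_across_frames(_sets_from_centroids([[(0.0, 0.0)]]))


def _mwu_enumeration(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mu = n_a * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_separated_pairs_exact(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_exact_branch_equals_enumeration(self, data):
        """For small tie-free samples the p-value is the exact permutation p."""
        n_a = data.draw(st.integers(2, 5))
        n_b = data.draw(st.integers(2, 5))
        vals = data.draw(
            st.lists(
                st.integers(0, 10_000), min_size=n_a + n_b, max_size=n_a + n_b,
                unique=True,
            )
        )
        a, b = np.array(vals[:n_a], float), np.array(vals[n_a:], float)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(_mwu_enumeration(a, b), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(0.5, size=30)
        u, p = mann_whitney_u(a, b)
        # tie-corrected normal approximation with continuity correction
        n_a, n_b = 30, 30
        mu = n_a * n_b / 2
        sd = np.sqrt(n_a * n_b * (n_a + n_b + 1) / 12)
        from scipy.stats import norm

        expected = 2 * norm.sf((abs(u - mu) - 0.5) / sd)
        assert p == pytest.approx(min(expected, 1.0), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_u([], [1.0])


class TestSummarize:
    def test_single_set_mean_and_median(self):
        z = gaussian_bump(96, 5.0, center=(30.0, 30.0)) + gaussian_bump(
            96, 5.0, center=(65.0, 65.0)
        )
        df, summary = summarize_condition([_detect(z)])
        assert df.loc[0, "count"] == 2
        assert summary["median_of_image_mean_area_nm2"] == pytest.approx(
            df.loc[0, "mean_area_nm2"]
        )

    def test_empty_set_row(self):
        df, summary = summarize_condition([ProtrusionSet([])])
        assert df.loc[0, "count"] == 0
        assert np.isnan(df.loc[0, "mean_area_nm2"])
        assert summary["total_protrusions"] == 0
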