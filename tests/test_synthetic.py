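"""The sticky-diffusion fixation simulator and its renderers."""

import warnings

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from conftest import HALF_MAX_AREA
from fixclust.exceptions import ParameterError
from fixclust.protrusions import DetectParams, detect_protrusions
from fixclust.spots import detect_spots
from fixclust.synthetic import (
    FixationSimParams,
    RenderParams,
    fluor_sim_params,
    generate_force_curves,
    render_cluster_topograph,
    render_frame_series,
    render_spot_images,
    render_topography,
    simulate_fixation,
    topo_sim_params,
)


def _small_params(**kw):
    base = dict(
        n_a=30, n_b=30, box=(4.0, 4.0), D=0.01, dt=0.05,
        t_start=-4.0, t_fix=0.0, t_end=4.0, capture_radius=0.05,
        record_interval=1.0, seed=0,
    )
    base.update(kw)
    return FixationSimParams(**base)


class TestSimulator:
    def test_particle_count_and_bond_monotonicity(self):
        sim = simulate_fixation(_small_params(seed=3))
        assert sim.positions.shape[1] == 60
        times = [t for _, _, t in sim.bonds]
        assert times == sorted(times)
        assert all(t >= 0.0 for t in times)

    def test_clusters_are_connected_components_of_bonds(self):
        sim = simulate_fixation(_small_params(seed=5))
        n = sim.n_particles
        ij = np.array([(i, j) for i, j, _ in sim.bonds]).reshape(-1, 2)
        adj = coo_matrix(
            (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(adj, directed=False)
        # same partition as the recorded final-frame cluster labels
        ours = sim.cluster_labels[-1]
        for lab in np.unique(labels):
            members = np.nonzero(labels == lab)[0]
            assert len(np.unique(ours[members])) == 1

    def test_looseness_zero_never_bonds(self):
        sim = simulate_fixation(_small_params(looseness=0.0, seed=1))
        assert sim.bonds == []

    def test_free_diffusion_msd(self):
        """Mean squared displacement of free particles follows 4*D*t."""
        msds = []
        for s in range(40):
            p = FixationSimParams(
                n_a=25, n_b=25, box=(16.0, 16.0), looseness=0.0,
                t_start=0.0, t_fix=0.0, t_end=5.0, record_interval=5.0, seed=s,
            )
            sim = simulate_fixation(p)
            disp = sim.positions[-1] - sim.positions[0]
            msds.append((disp**2).sum(axis=1).mean())
        assert np.mean(msds) == pytest.approx(4 * 0.01 * 5.0, rel=0.1)

    def test_global_capture_forms_one_cluster(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = _small_params(
                capture_radius=10.0, t_start=0.0, t_end=0.1, dt=0.05,
                record_interval=0.05,
            )
            sim = simulate_fixation(p)
        assert len(np.unique(sim.cluster_labels[-1])) == 1

    def test_loose_bonding_forms_fewer_bonds(self):
        tight = simulate_fixation(_small_params(looseness=1.0, seed=9))
        loose = simulate_fixation(_small_params(looseness=0.3, seed=9))
        assert 0 < len(loose.bonds) < len(tight.bonds)

    def test_bit_reproducible(self):
        a = simulate_fixation(_small_params(seed=21))
        b = simulate_fixation(_small_params(seed=21))
        assert np.array_equal(a.positions, b.positions)
        assert a.bonds == b.bonds

    def test_pre_fixation_nn_distance_has_no_trend(self):
        """Before the fixative there is no systematic drift in cross-species
        nearest distances (fitted slope averages to ~0 across replicates)."""
        from scipy.spatial import cKDTree

        slopes = []
        for s in range(25):
            p = fluor_sim_params("living", seed=s, t_start=-20.0, t_end=0.0)
            sim = simulate_fixation(p)
            means = []
            for f in range(len(sim.times)):
                a = sim.positions[f][sim.species == 0]
                b = sim.positions[f][sim.species == 1]
                means.append(cKDTree(b).query(a, k=1)[0].mean())
            slopes.append(np.polyfit(sim.times, means, 1)[0])
        slopes = np.asarray(slopes)
        ci = 1.96 * slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean()) < ci + 1e-4

    def test_large_step_warns(self):
        with pytest.warns(UserWarning, match="capture"):
            simulate_fixation(_small_params(dt=2.0, capture_radius=0.01))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            FixationSimParams(looseness=1.5)
        with pytest.raises(ParameterError):
            FixationSimParams(t_start=5.0, t_fix=0.0)
        with pytest.raises(ParameterError):
            topo_sim_params("unknown-fixative")


class TestRenderTopography:
    def test_single_monomer_detected_at_closed_form_area(self):
        rp = RenderParams(roughness_rms=0.0, line_noise_sd=0.0, bump_sigma=4.0)
        img = render_topography(
            np.array([[100.0, 100.0]]), [10.0], [4.0], rp,
            rng=np.random.default_rng(0),
        )
        ps = detect_protrusions(
            img, DetectParams(min_prominence=1.0, background_radius=40.0)
        )
        assert len(ps) == 1
        assert ps.areas[0] == pytest.approx(HALF_MAX_AREA * 16.0, rel=0.05)

    def test_cluster_rendering_truth_sizes(self):
        sim = simulate_fixation(topo_sim_params("ga", seed=2))
        img, truth = render_cluster_topograph(sim, len(sim.times) - 1)
        assert img.pixel_size == RenderParams().topo_pixel_size
        assert truth["members"].sum() == sim.n_particles
        # aggregates widen as members^(1/4)
        big = truth["members"] > 1
        assert np.all(
            truth["sigmas_nm"][big]
            == RenderParams().bump_sigma * truth["members"][big] ** 0.25
        )

    def test_frame_series_truth_and_drift(self):
        rp = RenderParams(drift_per_frame=(2.0, 0.0), seed=0)
        frames, truth = render_frame_series(
            rp, n_persistent=5, n_spurious=3, n_frames=4, seed=0
        )
        assert len(frames) == 4
        assert truth["persistent_centers_nm"].shape == (5, 2)
        assert len(truth["spurious"]) == 3
        assert all(0 <= f < 4 for f, _ in truth["spurious"])


class TestRenderSpots:
    def test_single_particle_renders_single_spot(self):
        p = FixationSimParams(
            n_a=1, n_b=1, box=(4.0, 4.0), looseness=0.0,
            t_start=0.0, t_fix=0.0, t_end=0.1, dt=0.05, record_interval=0.1, seed=4,
        )
        sim = simulate_fixation(p)
        rp = RenderParams(noise_scale=0.0, amp_jitter=0.0, seed=1)
        stack, truth = render_spot_images(sim, rp, frame_indices=[0])
        assert stack.shape[:2] == (1, 2)
        sf = detect_spots(stack[0, 0], rp.fluo_pixel_size)
        assert len(sf) == 1
        assert sf.xy[0] == pytest.approx(truth["positions_um"][0][0][0], abs=0.05)

    def test_detection_recall_on_default_render(self):
        p = fluor_sim_params("living", seed=6, t_start=-1.0, t_end=0.0,
                             record_interval=1.0)
        sim = simulate_fixation(p)
        rp = RenderParams(seed=2)
        stack, truth = render_spot_images(sim, rp, frame_indices=[0])
        sf = detect_spots(stack[0, 0], rp.fluo_pixel_size)
        true_xy = truth["positions_um"][0][0]
        d = np.sqrt(((sf.xy[:, None] - true_xy[None]) ** 2).sum(-1))
        recall = (d.min(axis=0) <= 0.15).mean()
        assert recall >= 0.9


class TestForceCurveGenerator:
    def test_truth_recorded_and_noiseless_inverts(self):
        from fixclust.mechanics import fit_hertz_pyramid

        c = generate_force_curves(55.0, n=1, seed=0)[0]
        assert c.meta["E_true_kPa"] == 55.0
        assert fit_hertz_pyramid(c).youngs_modulus == pytest.approx(55.0, rel=1e-3)

    def test_reproducible_noise(self):
        a = generate_force_curves(30.0, noise_sd_frac=0.05, n=3, seed=7)
        b = generate_force_curves(30.0, noise_sd_frac=0.05, n=3, seed=7)
        assert all(np.array_equal(x.force, y.force) for x, y in zip(a, b))
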