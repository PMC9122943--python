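"""Synthetic data with the statistical structure of fixed-cell experiments.

The centrepiece is a quantitative "bond-on-contact" fixation simulator:
membrane proteins of two non-interacting species diffuse in a 2-D box; after
the fixative is added at ``t_fix``, any two proteins that come within the
capture radius become permanently bonded (with probability ``looseness`` per
step, modelling the looser aggregation of precipitating fixatives such as
MeOH versus crosslinking aldehydes).  Bonded clusters diffuse more slowly
(Stokes-like D/n) and arrest completely over a ramp ``tau_arrest`` after
their first bond, reproducing the ~10 s settling seen in fixation
time-lapses.

Renderers turn trajectories into the inputs the analysis modules consume:
bump-decorated rough AFM topographs over drifting consecutive frames,
two-channel fluorescence spot images with PSF blur and shot-like noise,
Hertzian approach force curves, and paired hole-lattice images for
registration.  Every generator is reproducible from (params, seed) and
returns ground-truth labels alongside the rendered data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .afm import TopographyImage
from .exceptions import ParameterError
from .mechanics import ForceCurve, hertz_force
from .registration import Transform2D

__all__ = [
    "FixationSimParams",
    "SimTrajectory",
    "RenderParams",
    "simulate_fixation",
    "render_topography",
    "render_cluster_topograph",
    "render_frame_series",
    "render_spot_images",
    "generate_force_curves",
    "generate_hole_lattice",
    "PRESETS",
    "fluor_sim_params",
    "topo_sim_params",
]


@dataclass
class FixationSimParams:
    """Sticky-diffusion simulation parameters (lengths um, times s).

    ``cluster_slowdown`` rules: ``"stokes"`` (D/n for an n-member cluster),
    ``"stokes_arrest"`` (D/n with a linear ramp to zero over ``tau_arrest``
    after the cluster's first bond; default), ``"freeze"`` (full mobility
    until ``tau_arrest`` after first bond, then zero).
    """

    n_a: int = 200
    n_b: int = 200
    box: tuple[float, float] = (16.0, 16.0)
    D: float = 0.01  # um^2/s
    dt: float = 0.05  # s
    t_start: float = -20.0
    t_fix: float = 0.0
    t_end: float = 60.0
    capture_radius: float = 0.05  # um
    cluster_slowdown: str = "stokes_arrest"
    tau_arrest: float = 10.0  # s
    looseness: float = 1.0
    record_interval: float = 2.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 0 or self.n_b < 0 or self.n_a + self.n_b == 0:
            raise ParameterError("need at least one particle")
        if min(self.box) <= 0 or self.D < 0 or self.dt <= 0:
            raise ParameterError("box, D, dt must be positive")
        if not (0.0 <= self.looseness <= 1.0):
            raise ParameterError("looseness must lie in [0, 1]")
        if self.capture_radius <= 0 or self.tau_arrest < 0:
            raise ParameterError("capture_radius must be > 0 and tau_arrest >= 0")
        if not (self.t_start <= self.t_fix <= self.t_end):
            raise ParameterError("need t_start <= t_fix <= t_end")
        if self.cluster_slowdown not in {"stokes", "stokes_arrest", "freeze"}:
            raise ParameterError(f"unknown cluster_slowdown {self.cluster_slowdown!r}")


@dataclass
class SimTrajectory:
    """Recorded trajectory: times (T,), positions (T, N, 2), species (N,) in
    {0, 1}, append-only bond list (i, j, t), per-frame cluster labels (T, N)."""

    times: np.ndarray
    positions: np.ndarray
    species: np.ndarray
    bonds: list[tuple[int, int, float]]
    cluster_labels: np.ndarray
    params: FixationSimParams | None = None

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def frame_at(self, t: float) -> int:
        """Index of the recorded frame closest to time ``t``."""
        return int(np.argmin(np.abs(self.times - t)))

    def cluster_sizes(self, frame: int) -> np.ndarray:
        """Size of each particle's cluster at a recorded frame."""
        labels = self.cluster_labels[frame]
        counts = np.bincount(labels)
        return counts[labels]


class _Clusters:
    """Flat union-find: every particle stores its root directly, so per-step
    lookups are O(1) array reads; merges relabel the smaller cluster."""

    def __init__(self, n: int) -> None:
        self.root_of = np.arange(n)
        self.size = np.ones(n, dtype=int)  # valid at roots
        self.t_bond = np.full(n, np.inf)  # valid at roots

    def union(self, i: int, j: int, t: float) -> bool:
        ri, rj = int(self.root_of[i]), int(self.root_of[j])
        if ri == rj:
            return False
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.root_of[self.root_of == rj] = ri
        self.size[ri] += self.size[rj]
        self.t_bond[ri] = min(self.t_bond[ri], self.t_bond[rj], t)
        return True


def _reflect(pos: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    for ax, L in enumerate(box):
        p = np.mod(pos[:, ax], 2.0 * L)
        pos[:, ax] = np.where(p > L, 2.0 * L - p, p)
    return pos


def simulate_fixation(p: FixationSimParams) -> SimTrajectory:
    """Run the sticky-diffusion fixation simulation.

    Before ``t_fix`` particles diffuse freely (no bonds can form), so the
    pre-fixation segment is advanced in single exact Brownian increments
    between recorded frames.  From ``t_fix`` on, the dynamics run at ``dt``:
    each step every unbonded pair within the capture radius bonds with
    probability ``looseness``, permanently; clusters move rigidly with the
    mobility given by the slowdown rule; walls reflect.
    """
    rng = np.random.default_rng(p.seed)
    step_sd = np.sqrt(2.0 * p.D * p.dt)
    if step_sd > p.capture_radius:
        warnings.warn(
            "Brownian step SD exceeds the capture radius; bond capture will be "
            "unreliable (reduce dt)",
            stacklevel=2,
        )
    n = p.n_a + p.n_b
    species = np.concatenate([np.zeros(p.n_a, int), np.ones(p.n_b, int)])
    pos = rng.uniform(0, 1, size=(n, 2)) * np.asarray(p.box)

    rec_times = _record_times(p)
    frames = np.empty((len(rec_times), n, 2))
    labels = np.empty((len(rec_times), n), dtype=int)
    clus = _Clusters(n)
    bonds: list[tuple[int, int, float]] = []
    rec_i = 0

    def record(t: float) -> None:
        nonlocal rec_i
        while rec_i < len(rec_times) and rec_times[rec_i] <= t + 1e-9:
            frames[rec_i] = pos
            _, labels[rec_i] = np.unique(clus.root_of, return_inverse=True)
            rec_i += 1

    record(p.t_start)
    # free-diffusion segment: exact increments between pre-fixation records
    t = p.t_start
    pre = rec_times[(rec_times > p.t_start) & (rec_times <= p.t_fix)]
    for t_next in pre:
        sd = np.sqrt(2.0 * p.D * (t_next - t))
        pos += rng.normal(0.0, sd, size=pos.shape)
        _reflect(pos, p.box)
        t = t_next
        record(t)
    if t < p.t_fix:
        sd = np.sqrt(2.0 * p.D * (p.t_fix - t))
        pos += rng.normal(0.0, sd, size=pos.shape)
        _reflect(pos, p.box)
        t = p.t_fix

    # fixation segment at full resolution
    n_steps = int(np.ceil((p.t_end - t) / p.dt - 1e-9))
    iu = np.triu_indices(n, k=1)
    for _ in range(n_steps):
        t_new = min(t + p.dt, p.t_end)
        uroots, inv = np.unique(clus.root_of, return_inverse=True)
        d_eff = _cluster_mobility(p, clus, uroots, t)
        disp = rng.normal(0.0, 1.0, size=(len(uroots), 2)) * np.sqrt(
            2.0 * d_eff * (t_new - t)
        )[:, None]
        pos += disp[inv]
        _reflect(pos, p.box)
        if p.looseness > 0.0:
            _form_bonds(p, pos, clus, bonds, rng, t_new, iu)
        t = t_new
        record(t)
    record(p.t_end)

    return SimTrajectory(
        times=rec_times,
        positions=frames,
        species=species,
        bonds=bonds,
        cluster_labels=labels,
        params=p,
    )


def _record_times(p: FixationSimParams) -> np.ndarray:
    n_rec = int(np.floor((p.t_end - p.t_start) / p.record_interval + 1e-9))
    times = p.t_start + p.record_interval * np.arange(n_rec + 1)
    if times[-1] < p.t_end - 1e-9:
        times = np.append(times, p.t_end)
    return times


def _cluster_mobility(p: FixationSimParams, clus: _Clusters, uroots: np.ndarray, t: float) -> np.ndarray:
    sizes = clus.size[uroots].astype(float)
    tb = clus.t_bond[uroots]
    bonded = np.isfinite(tb)
    if p.cluster_slowdown == "stokes":
        return p.D / sizes
    if p.cluster_slowdown == "freeze":
        d = np.full(len(uroots), p.D)
        d[bonded & (t >= tb + p.tau_arrest)] = 0.0
        return d
    # stokes_arrest: D/n with a linear ramp to zero over tau_arrest
    d = p.D / sizes
    if p.tau_arrest == 0:
        d[bonded] = 0.0
    else:
        ramp = np.clip(1.0 - (t - tb) / p.tau_arrest, 0.0, 1.0)
        d[bonded] *= ramp[bonded]
    return d


def _form_bonds(p, pos, clus, bonds, rng, t, iu) -> None:
    dist = cdist(pos, pos)
    close = dist[iu] < p.capture_radius
    ii, jj = iu[0][close], iu[1][close]
    for i, j in zip(ii, jj):
        if clus.root_of[i] == clus.root_of[j]:
            continue
        if p.looseness >= 1.0 or rng.uniform() < p.looseness:
            clus.union(i, j, t)
            bonds.append((int(i), int(j), float(t)))


# ---------------------------------------------------------------------------
# presets


PRESETS: dict[str, dict[str, float]] = {
    "living": {"looseness": 0.0, "capture_radius": 0.05, "tau_arrest": 10.0},
    "pfa": {"looseness": 1.0, "capture_radius": 0.05, "tau_arrest": 10.0},
    "ga": {"looseness": 1.0, "capture_radius": 0.06, "tau_arrest": 10.0},
    "meoh": {"looseness": 0.3, "capture_radius": 0.05, "tau_arrest": 10.0},
}


def fluor_sim_params(preset: str = "pfa", seed: int = 0, **overrides) -> FixationSimParams:
    """Fluorescence-scale simulation: 200+200 labelled proteins in 16x16 um.

    The box size makes the Poisson nearest-neighbour mean ~0.57 um for 200
    spots per channel, the scale of living-cell cross-channel distances.
    """
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}")
    kw: dict[str, Any] = dict(
        n_a=200, n_b=200, box=(16.0, 16.0), D=0.01, dt=0.05,
        t_start=-20.0, t_fix=0.0, t_end=60.0, record_interval=2.0, seed=seed,
    )
    kw.update(PRESETS[preset])
    kw.update(overrides)
    return FixationSimParams(**kw)


def topo_sim_params(preset: str = "pfa", seed: int = 0, **overrides) -> FixationSimParams:
    """Topography-scale simulation: 20+20 proteins in a 0.2x0.2 um patch.

    The density gives ~16 nm protein nearest-neighbour spacing, the scale of
    protrusion spacings on living cell surfaces; the capture radius is a
    protein diameter (5 nm).
    """
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}")
    kw: dict[str, Any] = dict(
        n_a=20, n_b=20, box=(0.2, 0.2), D=0.01, dt=0.001,
        t_start=-1.0, t_fix=0.0, t_end=5.0, capture_radius=0.005,
        record_interval=1.0, seed=seed,
    )
    kw.update({k: v for k, v in PRESETS[preset].items() if k != "capture_radius"})
    kw.update(overrides)
    return FixationSimParams(**kw)


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderParams:
    """Rendering parameters for topographs (nm) and fluorescence images (um)."""

    # topography
    topo_pixel_size: float = 1.5625  # nm/px (200 nm field at 128 px)
    topo_shape: tuple[int, int] = (128, 128)
    bump_height: float = 2.0  # nm per monomer
    bump_sigma: float = 2.7  # nm (FWHM ~6.4 nm, single membrane protein)
    height_cap: float = 5.0  # max amplitude in monomer heights
    roughness_rms: float = 0.2  # nm
    roughness_corr: float = 5.0  # nm
    line_noise_sd: float = 0.05  # nm per-line offset
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # nm
    # fluorescence
    fluo_pixel_size: float = 0.05  # um/px
    psf_fwhm: float = 0.25  # um (confocal; 0.06 for STED)
    amp_jitter: float = 0.2
    noise_scale: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topo_pixel_size <= 0 or self.fluo_pixel_size <= 0:
            raise ParameterError("pixel sizes must be positive")
        if self.bump_sigma <= 0 or self.psf_fwhm <= 0:
            raise ParameterError("bump_sigma and psf_fwhm must be positive")


def _add_gaussians(img: np.ndarray, centers_px: np.ndarray, amps, sigmas_px) -> None:
    """Add isotropic Gaussian bumps in place; centers are (x, y) pixels."""
    amps = np.broadcast_to(np.asarray(amps, float), (len(centers_px),))
    sigmas_px = np.broadcast_to(np.asarray(sigmas_px, float), (len(centers_px),))
    nr, nc = img.shape
    for (cx, cy), a, s in zip(centers_px, amps, sigmas_px):
        half = int(np.ceil(5 * s))
        r0, r1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        c0, c1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        r0c, r1c = max(r0, 0), min(r1, nr)
        c0c, c1c = max(c0, 0), min(c1, nc)
        if r0c >= r1c or c0c >= c1c:
            continue
        yy = np.arange(r0c, r1c)[:, None] - cy
        xx = np.arange(c0c, c1c)[None, :] - cx
        img[r0c:r1c, c0c:c1c] += a * np.exp(-(xx**2 + yy**2) / (2.0 * s**2))


def _rough_background(shape, rp: RenderParams, rng) -> np.ndarray:
    noise = rng.normal(size=shape)
    corr_px = max(rp.roughness_corr / rp.topo_pixel_size, 1e-6)
    rough = ndimage.gaussian_filter(noise, corr_px, mode="wrap")
    sd = rough.std()
    if sd > 0:
        rough *= rp.roughness_rms / sd
    rough += rng.normal(0.0, rp.line_noise_sd, size=(shape[0], 1))
    return rough


def render_topography(
    centers_nm: np.ndarray,
    amplitudes,
    sigmas_nm,
    rp: RenderParams | None = None,
    rng: np.random.Generator | None = None,
    frame_index: int = 0,
) -> TopographyImage:
    """Render Gaussian bumps plus correlated roughness and scan-line noise."""
    rp = rp or RenderParams()
    rng = rng if rng is not None else np.random.default_rng(rp.seed)
    img = _rough_background(rp.topo_shape, rp, rng)
    centers_px = np.asarray(centers_nm, float).reshape(-1, 2) / rp.topo_pixel_size
    _add_gaussians(img, centers_px, amplitudes, np.asarray(sigmas_nm, float) / rp.topo_pixel_size)
    return TopographyImage(
        heights=img,
        pixel_size=rp.topo_pixel_size,
        frame_index=frame_index,
        meta={"synthetic": True},
    )


def render_cluster_topograph(
    traj: SimTrajectory,
    frame: int,
    rp: RenderParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[TopographyImage, dict[str, Any]]:
    """Render one trajectory frame as a topograph; clusters become bumps.

    An n-member cluster renders as one Gaussian bump at the cluster centroid
    with amplitude ``bump_height * min(n, height_cap)`` and width
    ``bump_sigma * n**(1/4)`` (aggregates widen more than they heighten).
    Returns the image and a truth record (centers nm, amplitudes, sigmas,
    member counts).
    """
    rp = rp or RenderParams()
    labels = traj.cluster_labels[frame]
    pos_um = traj.positions[frame]
    nlab = labels.max() + 1
    counts = np.bincount(labels, minlength=nlab).astype(float)
    cx = np.bincount(labels, weights=pos_um[:, 0], minlength=nlab) / counts
    cy = np.bincount(labels, weights=pos_um[:, 1], minlength=nlab) / counts
    centers_nm = np.column_stack([cx, cy]) * 1000.0
    amps = rp.bump_height * np.minimum(counts, rp.height_cap)
    sigmas = rp.bump_sigma * counts**0.25
    img = render_topography(centers_nm, amps, sigmas, rp, rng, frame_index=frame)
    truth = {
        "centers_nm": centers_nm,
        "amplitudes_nm": amps,
        "sigmas_nm": sigmas,
        "members": counts.astype(int),
    }
    return img, truth


def render_frame_series(
    rp: RenderParams | None = None,
    n_persistent: int = 20,
    n_spurious: int = 10,
    n_frames: int = 10,
    seed: int = 0,
) -> tuple[list[TopographyImage], dict[str, Any]]:
    """Consecutive drifting topographs of persistent bumps plus one-frame blobs.

    Persistent bumps keep their (field-relative) position in every frame while
    the whole field drifts by ``rp.drift_per_frame``; spurious blobs are
    injected into single frames (round-robin) to emulate scan artefacts.
    Bumps are placed with a margin covering the total drift and with a
    minimum spacing so ground-truth identity is unambiguous.  Returns frames
    plus a truth dict (persistent centers, spurious (frame, center) pairs,
    drift).
    """
    rp = rp or RenderParams()
    rng = np.random.default_rng(seed)
    drift = np.asarray(rp.drift_per_frame, float)
    field_nm = np.array([rp.topo_shape[1], rp.topo_shape[0]]) * rp.topo_pixel_size
    margin = 3.0 * rp.bump_sigma + float(np.abs(drift).max()) * n_frames + 2.0
    min_sep = 4.5 * rp.bump_sigma

    persistent = _place_points(rng, n_persistent, field_nm, margin, min_sep)
    spurious: list[tuple[int, np.ndarray]] = []
    for k in range(n_spurious):
        f = k % n_frames
        pt = _place_points(
            rng, 1, field_nm, margin, min_sep,
            avoid=np.vstack([persistent] + [s[1][None] for s in spurious])
            if len(spurious) else persistent,
        )[0]
        spurious.append((f, pt))

    frames = []
    for f in range(n_frames):
        centers = [persistent + f * drift]
        centers += [s[1][None] + f * drift for s in spurious if s[0] == f]
        centers = np.vstack(centers)
        frames.append(
            render_topography(
                centers, rp.bump_height, rp.bump_sigma, rp, rng, frame_index=f
            )
        )
    truth = {
        "persistent_centers_nm": persistent,
        "spurious": spurious,
        "drift_per_frame_nm": tuple(drift),
    }
    return frames, truth


def _place_points(rng, n, field_nm, margin, min_sep, avoid=None) -> np.ndarray:
    pts: list[np.ndarray] = []
    existing = [] if avoid is None else [np.asarray(avoid).reshape(-1, 2)]
    for _ in range(10000):
        if len(pts) == n:
            break
        cand = margin + rng.uniform(size=2) * (field_nm - 2 * margin)
        others = np.vstack(existing + [np.array(pts).reshape(-1, 2)]) if (existing or pts) else None
        if others is not None and len(others) and np.hypot(*(others - cand).T).min() < min_sep:
            continue
        pts.append(cand)
    if len(pts) < n:
        raise ParameterError("could not place bumps with requested spacing")
    return np.array(pts)


def render_spot_images(
    traj: SimTrajectory,
    rp: RenderParams | None = None,
    frame_indices: list[int] | None = None,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Render two-channel fluorescence images of trajectory frames.

    Returns an array of shape (T, 2, H, W) plus ground truth (per-frame
    per-channel particle positions in um).  Per-particle brightness jitter is
    fixed over time (molecular brightness); shot-like noise scales with the
    square root of the local intensity.
    """
    rp = rp or RenderParams()
    rng = np.random.default_rng(rp.seed)
    if frame_indices is None:
        frame_indices = list(range(len(traj.times)))
    box = traj.params.box if traj.params is not None else (
        float(traj.positions[..., 0].max()), float(traj.positions[..., 1].max()))
    shape = (
        int(round(box[1] / rp.fluo_pixel_size)),
        int(round(box[0] / rp.fluo_pixel_size)),
    )
    sigma_px = rp.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / rp.fluo_pixel_size
    amp = 1.0 + rp.amp_jitter * rng.uniform(-1.0, 1.0, size=traj.n_particles)

    stack = np.zeros((len(frame_indices), 2, *shape))
    truth: dict[str, Any] = {"frames": frame_indices, "positions_um": []}
    for k, f in enumerate(frame_indices):
        per_channel = []
        for ch in (0, 1):
            sel = traj.species == ch
            img = np.zeros(shape)
            centers_px = traj.positions[f][sel] / rp.fluo_pixel_size
            _add_gaussians(img, centers_px, amp[sel], sigma_px)
            if rp.noise_scale > 0:
                img += rng.normal(size=shape) * rp.noise_scale * np.sqrt(img + 0.05)
            stack[k, ch] = img
            per_channel.append(traj.positions[f][sel].copy())
        truth["positions_um"].append(per_channel)
    return stack, truth


def generate_force_curves(
    E_true: float,
    nu: float = 0.5,
    theta_deg: float = 17.5,
    kappa: float = 0.7453,
    noise_sd_frac: float = 0.0,
    n: int = 1,
    seed: int = 0,
    z0: float = 0.0,
    F0: float = 0.0,
    tilt: float = 0.0,
    z_range: tuple[float, float] = (-150.0, 100.0),
    n_points: int = 300,
    spring_constant: float = 0.1,
) -> list[ForceCurve]:
    """Forward-model approach curves with optional Gaussian force noise.

    ``noise_sd_frac`` scales the noise SD relative to the maximum force.
    Ground truth is recorded in each curve's meta.
    """
    rng = np.random.default_rng(seed)
    z = np.linspace(z_range[1], z_range[0], n_points)  # far -> deep
    clean = hertz_force(z, E_true, z0, F0, tilt, nu, theta_deg, kappa)
    sd = noise_sd_frac * np.abs(clean).max()
    curves = []
    for _ in range(n):
        F = clean + (rng.normal(0.0, sd, size=z.shape) if sd > 0 else 0.0)
        curves.append(
            ForceCurve(
                z.copy(), F, spring_constant,
                meta={"E_true_kPa": E_true, "z0_true_nm": z0, "noise_sd_nN": sd},
            )
        )
    return curves


def generate_hole_lattice(
    diameter: float = 5.0,
    pitch: float = 10.0,
    jitter: float = 0.0,
    transform: Transform2D | None = None,
    field_um: float = 50.0,
    pixel_size_a: float = 0.1,
    pixel_size_b: float = 0.1,
    radius_jitter: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, Transform2D, np.ndarray]:
    """Paired modality images of a regular hole lattice.

    Modality A (AFM/transmitted light) shows dark holes on a bright field at
    ``pixel_size_a``; modality B (FITC fluorescence) shows bright holes at
    ``pixel_size_b``, with hole centres mapped through ``transform`` (identity
    by default).  ``jitter`` displaces centres (um SD), ``radius_jitter``
    perturbs hole radii fractionally.  Returns (img_a, img_b, truth
    transform, centres in modality A um).
    """
    rng = np.random.default_rng(seed)
    if transform is None:
        transform = Transform2D(scale=1.0, rotation_deg=0.0, translation=(0.0, 0.0))
    margin = diameter
    coords = np.arange(margin, field_um - margin + 1e-9, pitch)
    gx, gy = np.meshgrid(coords, coords)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    if jitter > 0:
        centers = centers + rng.normal(0.0, jitter, size=centers.shape)
    radii = diameter / 2.0 * (1.0 + radius_jitter * rng.uniform(-1, 1, size=len(centers)))

    img_a = _disk_image(centers, radii, field_um, pixel_size_a, dark=True)
    centers_b = transform.apply(centers)
    img_b = _disk_image(centers_b, radii * transform.scale, field_um, pixel_size_b, dark=False)
    return img_a, img_b, transform, centers


def _disk_image(centers, radii, field_um, pixel_size, dark: bool) -> np.ndarray:
    n = int(round(field_um / pixel_size))
    xs = (np.arange(n) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, xs)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(centers)
    d, idx = tree.query(pts, k=1)
    # smooth edge one pixel wide for subpixel centroid fidelity
    signed = (d - radii[idx]) / pixel_size
    inside = 1.0 / (1.0 + np.exp(np.clip(signed / 0.3, -50, 50)))
    img = inside.reshape(n, n)
    return 1.0 - 0.9 * img if dark else 0.1 + 0.9 * img
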