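"""End-to-end study workflows combining simulation, rendering and analysis.

Each function runs one self-contained in-silico version of an experiment:
simulate membrane proteins under a fixation preset, render the observable
(AFM topograph or fluorescence channels), run the corresponding analysis, and
return condition-level statistics.  These are the building blocks used by the
pipeline runner, the examples and the acceptance checks.
"""

from __future__ import annotations

from typing import Any

import numpy as np

from . import mechanics, protrusions, spots, synthetic
from .protrusions import DetectParams, detect_protrusions, mann_whitney_u, match_across_frames
from .spots import (
    cross_channel_nn,
    detect_aggregation_onset,
    detect_spots,
    equalize_density,
    track_spot,
)
from .synthetic import (
    RenderParams,
    fluor_sim_params,
    render_cluster_topograph,
    render_frame_series,
    render_spot_images,
    simulate_fixation,
    topo_sim_params,
)

__all__ = [
    "topo_condition_study",
    "compare_topo_conditions",
    "fluor_cell_means",
    "compare_fluor_conditions",
    "topo_direction_pair",
    "fluor_direction_pair",
    "fixation_trace_onset",
    "persistence_study",
    "hertz_recovery_study",
]


def _detect_params_for(rp: RenderParams) -> DetectParams:
    # background disk ~3x the largest expected bump radius
    return DetectParams(
        min_prominence=3.0 * rp.roughness_rms,
        background_radius=9.0 * rp.bump_sigma,
        min_area=0.5 * 2.0 * np.pi * np.log(2.0) * rp.bump_sigma**2,
    )


def topo_condition_study(
    preset: str,
    n_images: int,
    seed: int = 0,
    rp: RenderParams | None = None,
    at_time: str = "end",
):
    """Per-image protrusion statistics for one fixation preset.

    Each image is an independent topography-scale simulation rendered at its
    final frame (``at_time='end'``) or at the pre-fixation frame
    (``at_time='pre'``), then analysed with the half-max detector.  Returns
    the per-image DataFrame and summary from ``summarize_condition``.
    """
    rp = rp or RenderParams()
    sets = []
    for k in range(n_images):
        sim = simulate_fixation(topo_sim_params(preset, seed=seed * 100003 + k))
        frame = sim.frame_at(sim.params.t_fix if at_time == "pre" else sim.times[-1])
        img, _ = render_cluster_topograph(
            sim, frame, rp, rng=np.random.default_rng(seed * 100003 + k + 1)
        )
        sets.append(detect_protrusions(img, _detect_params_for(rp)))
    return protrusions.summarize_condition(sets)


def compare_topo_conditions(
    preset_a: str,
    preset_b: str,
    n_images: int,
    seed: int = 0,
    rp: RenderParams | None = None,
) -> dict[str, Any]:
    """Mann-Whitney comparison of per-image mean protrusion areas."""
    df_a, sum_a = topo_condition_study(preset_a, n_images, seed=seed, rp=rp)
    df_b, sum_b = topo_condition_study(preset_b, n_images, seed=seed + 7919, rp=rp)
    a = df_a["mean_area_nm2"].dropna().to_numpy()
    b = df_b["mean_area_nm2"].dropna().to_numpy()
    u, p = mann_whitney_u(a, b)
    return {
        "conditions": {preset_a: sum_a, preset_b: sum_b},
        "mann_whitney": {"U": u, "p": p},
    }


def fluor_cell_means(
    preset: str,
    n_cells: int,
    seed: int = 0,
    rp: RenderParams | None = None,
    rendered: bool = True,
    at: str = "end",
) -> np.ndarray:
    """Per-cell mean cross-channel NN distance (um) under one preset.

    With ``rendered=True`` (the full pipeline) each cell's channels are
    rendered to images, spots detected, densities equalised, and the A->B
    nearest distances averaged; otherwise the simulated positions are used
    directly.  ``at`` selects the analysed frame: 'end' or 'pre'
    (just before fixative addition).
    """
    rp = rp or RenderParams()
    means = np.empty(n_cells)
    for k in range(n_cells):
        s = seed * 99991 + k
        p = fluor_sim_params(preset, seed=s, t_start=-1.0, record_interval=1.0)
        sim = simulate_fixation(p)
        frame = sim.frame_at(p.t_fix - 1.0 if at == "pre" else sim.times[-1])
        means[k] = _cell_mean_nn(sim, frame, rp, rendered, seed=s)
    return means


def _cell_mean_nn(sim, frame: int, rp: RenderParams, rendered: bool, seed: int) -> float:
    if rendered:
        stack, _ = render_spot_images(
            sim, rp=_with_seed(rp, seed), frame_indices=[frame]
        )
        a = detect_spots(stack[0, 0], rp.fluo_pixel_size, channel="A")
        b = detect_spots(stack[0, 1], rp.fluo_pixel_size, channel="B")
        if len(a) == 0 or len(b) == 0:
            return np.nan
        a, b = equalize_density(a, b)
        return cross_channel_nn(a, b).cell_mean
    pos = sim.positions[frame]
    a = spots.SpotField(pos[sim.species == 0], np.ones((sim.species == 0).sum()))
    b = spots.SpotField(pos[sim.species == 1], np.ones((sim.species == 1).sum()))
    return cross_channel_nn(a, b).cell_mean


def _with_seed(rp: RenderParams, seed: int) -> RenderParams:
    from dataclasses import replace

    return replace(rp, seed=seed)


def compare_fluor_conditions(
    presets: list[str],
    n_cells: int,
    reference: str = "living",
    seed: int = 0,
    rendered: bool = True,
) -> dict[str, Any]:
    """Student's t-test report of cell-mean NN distances across presets."""
    cell_means = {
        pr: fluor_cell_means(pr, n_cells, seed=seed + 31 * i, rendered=rendered)
        for i, pr in enumerate(presets)
    }
    return spots.condition_compare(cell_means, reference=reference)


def topo_direction_pair(
    seed: int = 0, preset: str = "ga", rp: RenderParams | None = None
) -> tuple[float, float]:
    """(median pre-fixation area, median post-fixation area) of one patch.

    One topography-scale simulation rendered just before fixative addition
    and at the end of the run; both frames pass through the same half-max
    detector.  Medians are over the detected protrusions of the frame.
    """
    rp = rp or RenderParams()
    sim = simulate_fixation(topo_sim_params(preset, seed=seed))
    dp = _detect_params_for(rp)
    out = []
    for f in (sim.frame_at(sim.params.t_fix), len(sim.times) - 1):
        img, _ = render_cluster_topograph(
            sim, f, rp, rng=np.random.default_rng(seed * 7 + f + 1)
        )
        areas = detect_protrusions(img, dp).areas
        out.append(float(np.median(areas)) if len(areas) else np.nan)
    return out[0], out[1]


def fluor_direction_pair(
    seed: int = 0, preset: str = "ga", rendered: bool = True,
    rp: RenderParams | None = None,
) -> tuple[float, float]:
    """(pre-fixation, post-fixation) mean cross-channel NN distance (um).

    One fluorescence-scale simulation, analysed 1 s before fixative addition
    and at the end of the run.
    """
    rp = rp or RenderParams()
    p = fluor_sim_params(preset, seed=seed, t_start=-1.0, record_interval=1.0)
    sim = simulate_fixation(p)
    pre = _cell_mean_nn(sim, sim.frame_at(p.t_fix - 1.0), rp, rendered, seed=seed * 3 + 1)
    post = _cell_mean_nn(sim, len(sim.times) - 1, rp, rendered, seed=seed * 3 + 2)
    return pre, post


def fixation_trace_onset(
    seed: int = 0,
    preset: str = "ga",
    rendered: bool = False,
    low_threshold: float = 0.2,
    hold: int = 3,
) -> tuple[spots.TimeLapseTrace, float | None]:
    """Track one A-spot through a fixation time-lapse and detect its onset.

    The tracked spot is a randomly chosen channel-A molecule among those that
    end up aggregated with at least one channel-B molecule — the same
    selection a microscopist makes when following a spot that visibly
    aggregates in the time-lapse.  Returns the trace and the detected
    aggregation-onset time (s after fixative addition), or None when the spot
    never settles.
    """
    p = fluor_sim_params(preset, seed=seed)
    sim = simulate_fixation(p)
    rng = np.random.default_rng(seed + 1)
    idx_a = np.nonzero(sim.species == 0)[0]
    final = sim.cluster_labels[-1]
    b_clusters = set(final[sim.species == 1])
    mixed = idx_a[np.isin(final[idx_a], list(b_clusters))]
    start = sim.positions[0][rng.choice(mixed if len(mixed) else idx_a)]

    if rendered:
        rp = RenderParams(seed=seed + 2)
        stack, _ = render_spot_images(sim, rp=rp)
        frames = [
            (
                detect_spots(stack[f, 0], rp.fluo_pixel_size, channel="A"),
                detect_spots(stack[f, 1], rp.fluo_pixel_size, channel="B"),
            )
            for f in range(stack.shape[0])
        ]
    else:
        frames = [
            (
                spots.SpotField(sim.positions[f][sim.species == 0],
                                np.ones((sim.species == 0).sum())),
                spots.SpotField(sim.positions[f][sim.species == 1],
                                np.ones((sim.species == 1).sum())),
            )
            for f in range(len(sim.times))
        ]
    trace = track_spot(
        frames, start, max_disp=1.0, times=sim.times, fixation_time=p.t_fix
    )
    onset = detect_aggregation_onset(trace, low_threshold=low_threshold, hold=hold)
    return trace, onset


def persistence_study(
    seed: int = 0,
    n_persistent: int = 20,
    n_spurious: int = 10,
    n_frames: int = 10,
    drift_nm: tuple[float, float] = (2.0, 0.0),
    max_disp: float = 10.0,
    k_min: int = 3,
    rp: RenderParams | None = None,
):
    """Render a drifting frame series and recover the persistent-bump count."""
    from dataclasses import replace

    rp = rp or RenderParams()
    rp = replace(rp, drift_per_frame=drift_nm)
    frames, truth = render_frame_series(
        rp, n_persistent=n_persistent, n_spurious=n_spurious,
        n_frames=n_frames, seed=seed,
    )
    dp = _detect_params_for(rp)
    sets = [detect_protrusions(f, dp) for f in frames]
    res = match_across_frames(sets, max_disp=max_disp, k_min=k_min, images=frames)
    return res, truth


def hertz_recovery_study(
    E_list=(27.0, 165.0, 449.0, 535.0),
    noise_sd_frac: float = 0.05,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict[str, Any]:
    """Parameter-recovery study of the pyramidal Hertz fit.

    For each true modulus, fit ``n_replicates`` noisy forward-model curves and
    report the mean recovered modulus and relative bias.
    """
    out: dict[str, Any] = {"E_true_kPa": list(E_list), "E_fit_mean_kPa": [],
                           "bias_frac": []}
    for i, E in enumerate(E_list):
        curves = synthetic.generate_force_curves(
            E, noise_sd_frac=noise_sd_frac, n=n_replicates, seed=seed + 17 * i
        )
        fits = [mechanics.fit_hertz_pyramid(c).youngs_modulus for c in curves]
        mean = float(np.mean(fits))
        out["E_fit_mean_kPa"].append(mean)
        out["bias_frac"].append(mean / E - 1.0)
    return out
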