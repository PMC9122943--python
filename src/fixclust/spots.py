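"""Two-channel fluorescence spot detection and distance analysis.

Diffraction-limited spots are detected with a scale-matched Laplacian-of-
Gaussian filter (the standard single-particle detector): the response is
computed at sigma = diameter / (2*sqrt(2)) and normalised so that an ideal
Gaussian spot of the matched diameter and unit peak amplitude scores a
quality of exactly 1.0.  Spots are local maxima above a quality threshold,
localised to subpixel precision by quadratic refinement.

Downstream statistics mirror a cross-channel colocalisation-by-distance
analysis: channel densities are equalised by quality rank, the distance from
each spot in channel A to the nearest spot in channel B is averaged per cell,
conditions are compared with Student's t-test, and single-spot time-lapse
traces yield the aggregation-onset time after fixative addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import ttest_ind

from .exceptions import ParameterError

__all__ = [
    "SpotField",
    "NNResult",
    "TimeLapseTrace",
    "detect_spots",
    "equalize_density",
    "cross_channel_nn",
    "condition_compare",
    "track_spot",
    "detect_aggregation_onset",
]


@dataclass
class SpotField:
    """Detected spots of one channel; coordinates in micrometres."""

    xy: np.ndarray  # (N, 2) positions, um
    quality: np.ndarray  # (N,) LoG quality, ideal matched spot = 1.0
    channel: str = ""
    pixel_size: float = 0.05  # um
    crop_polygon: np.ndarray | None = None
    image_ref: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, float).reshape(-1, 2)
        self.quality = np.asarray(self.quality, float).reshape(-1)
        if self.xy.shape[0] != self.quality.shape[0]:
            raise ParameterError("xy and quality must have equal length")
        if np.any(self.quality < 0):
            raise ParameterError("quality must be >= 0")

    def __len__(self) -> int:
        return len(self.xy)


@dataclass
class NNResult:
    """Cross-channel nearest distances (A -> nearest B) for one cell."""

    per_spot_distances: np.ndarray  # um
    cell_mean: float  # um
    n_spots: int


@dataclass
class TimeLapseTrace:
    """Distance of one tracked spot to its nearest other-channel spot over time."""

    times: np.ndarray  # s
    distances: np.ndarray  # um
    fixation_time: float = 0.0  # s; fixative added at t = fixation_time
    onset_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.distances = np.asarray(self.distances, float)
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.distances < 0):
            raise ParameterError("distances must be >= 0")


def _log_sigma(diameter: float) -> float:
    """LoG scale matched to a spot of the given diameter: sigma = d / (2*sqrt(2))."""
    return diameter / (2.0 * np.sqrt(2.0))


def detect_spots(
    image: np.ndarray,
    pixel_size: float,
    diameter: float = 0.5,
    quality_threshold: float = 0.2,
    crop_polygon: np.ndarray | None = None,
    channel: str = "",
) -> SpotField:
    """Detect spots by scale-normalised LoG filtering.

    ``diameter`` (um) is the expected spot size; the detection scale is
    sigma = diameter/(2*sqrt(2)).  Quality is the negative scale-normalised
    Laplacian response rescaled so an ideal matched Gaussian spot of unit peak
    amplitude scores 1.0 (a Gaussian of width sigma filtered at the same sigma
    has centre response amplitude/2, hence the factor 2).
    """
    image = np.asarray(image, float)
    if diameter <= 0:
        raise ParameterError("diameter must be > 0")
    if diameter / pixel_size < 2.0:
        raise ParameterError("spot diameter must span at least 2 pixels")
    sigma_px = _log_sigma(diameter) / pixel_size
    response = -ndimage.gaussian_laplace(image, sigma=sigma_px, mode="reflect")
    quality_map = 2.0 * sigma_px**2 * response

    is_max = quality_map >= ndimage.maximum_filter(quality_map, size=3, mode="reflect")
    is_max &= quality_map >= quality_threshold
    # suppress plateau duplicates: keep one pixel per connected maximum region
    labels, n = ndimage.label(is_max)
    xs, ys, qs = [], [], []
    for (r, c) in np.round(
        ndimage.center_of_mass(is_max, labels, range(1, n + 1))
    ).astype(int).reshape(-1, 2):
        q = float(quality_map[r, c])
        dr = dc = 0.0
        if 0 < c < quality_map.shape[1] - 1:
            denom = quality_map[r, c - 1] - 2 * q + quality_map[r, c + 1]
            if denom < 0:
                dc = 0.5 * (quality_map[r, c - 1] - quality_map[r, c + 1]) / denom
        if 0 < r < quality_map.shape[0] - 1:
            denom = quality_map[r - 1, c] - 2 * q + quality_map[r + 1, c]
            if denom < 0:
                dr = 0.5 * (quality_map[r - 1, c] - quality_map[r + 1, c]) / denom
        xs.append((c + dc) * pixel_size)
        ys.append((r + dr) * pixel_size)
        qs.append(q)
    xy = np.column_stack([xs, ys]) if xs else np.empty((0, 2))
    quality = np.asarray(qs)

    if crop_polygon is not None and len(xy):
        keep = np.array([_in_poly(pt, np.asarray(crop_polygon, float)) for pt in xy])
        xy, quality = xy[keep], quality[keep]
    return SpotField(
        xy=xy,
        quality=quality,
        channel=channel,
        pixel_size=pixel_size,
        crop_polygon=None if crop_polygon is None else np.asarray(crop_polygon, float),
    )


def _in_poly(pt: np.ndarray, poly: np.ndarray) -> bool:
    x, y = pt
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    cond = (y0 <= y) != (y1 <= y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xs = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
    return bool(np.sum(cond & (xs > x)) % 2)


def equalize_density(a: SpotField, b: SpotField) -> tuple[SpotField, SpotField]:
    """Trim the denser channel to the sparser channel's count by quality rank.

    Both fields must share the analysis region, so equal counts mean equal
    area per spot.  Never adds spots; the kept spots are the highest-quality
    ones of the denser channel.
    """
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("cannot equalize an empty channel")
    n = min(len(a), len(b))

    def trim(f: SpotField) -> SpotField:
        if len(f) <= n:
            return f
        keep = np.sort(np.argsort(f.quality, kind="stable")[::-1][:n])
        return SpotField(
            xy=f.xy[keep], quality=f.quality[keep], channel=f.channel,
            pixel_size=f.pixel_size, crop_polygon=f.crop_polygon,
            image_ref=dict(f.image_ref),
        )

    return trim(a), trim(b)


def cross_channel_nn(a: SpotField, b: SpotField) -> NNResult:
    """Distance from each A-spot centre to the nearest B-spot centre (um)."""
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both channels must contain spots")
    tree = cKDTree(b.xy)
    d, _ = tree.query(a.xy, k=1)
    return NNResult(
        per_spot_distances=d,
        cell_mean=float(d.mean()),
        n_spots=int(len(a)),
    )


def condition_compare(cell_means_by_condition: dict[str, np.ndarray], reference: str):
    """Two-sided equal-variance Student's t-test of each condition vs reference.

    ``cell_means_by_condition`` maps a condition name to its per-cell mean NN
    distances.  Returns a dict with mean +/- SEM per condition and (t, p) for
    each non-reference condition against the reference.
    """
    if reference not in cell_means_by_condition:
        raise ParameterError(f"reference condition {reference!r} missing")
    report: dict[str, Any] = {"reference": reference, "conditions": {}, "tests": {}}
    for name, vals in cell_means_by_condition.items():
        vals = np.asarray(vals, float)
        if vals.size < 2:
            raise ParameterError(f"condition {name!r} needs >= 2 cells")
        report["conditions"][name] = {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
            "n": int(vals.size),
        }
    ref = np.asarray(cell_means_by_condition[reference], float)
    for name, vals in cell_means_by_condition.items():
        if name == reference:
            continue
        t, p = ttest_ind(np.asarray(vals, float), ref, equal_var=True)
        report["tests"][name] = {"t": float(t), "p": float(p)}
    return report


def track_spot(
    frames: list[tuple[SpotField, SpotField]],
    start_xy: tuple[float, float],
    max_disp: float,
    times: np.ndarray | None = None,
    fixation_time: float = 0.0,
) -> TimeLapseTrace:
    """Track one channel-A spot through a time-lapse and record its nearest
    channel-B distance per frame.

    ``frames`` is a time-ordered list of (channel A, channel B) SpotFields.
    The spot is linked frame-to-frame to the nearest A-spot within
    ``max_disp``; the trace ends when the link is lost.
    """
    if len(frames) == 0:
        raise ParameterError("need at least one frame")
    a0 = frames[0][0]
    if len(a0) == 0:
        raise ParameterError("start spot not found in first frame")
    d0 = np.hypot(*(a0.xy - np.asarray(start_xy, float)).T)
    if d0.min() > max_disp:
        raise ParameterError("start spot not found in first frame")
    cur = a0.xy[int(np.argmin(d0))]

    if times is None:
        times = 2.0 * np.arange(len(frames))  # default 2 s frame interval
    times = np.asarray(times, float)

    ts, ds = [], []
    for f, (a, b) in enumerate(frames):
        if f > 0:
            if len(a) == 0:
                break
            dd = np.hypot(*(a.xy - cur).T)
            if dd.min() > max_disp:
                break
            cur = a.xy[int(np.argmin(dd))]
        if len(b) == 0:
            break
        ts.append(times[f])
        ds.append(float(np.hypot(*(b.xy - cur).T).min()))
    return TimeLapseTrace(
        times=np.asarray(ts), distances=np.asarray(ds), fixation_time=fixation_time
    )


def detect_aggregation_onset(
    trace: TimeLapseTrace,
    low_threshold: float = 0.2,
    hold: int = 3,
) -> float | None:
    """First time >= fixation at which the distance stays below threshold.

    Onset is the first time point at or after ``trace.fixation_time`` where
    the distance is below ``low_threshold`` for at least ``hold`` consecutive
    frames.  Returns None if no such run exists.  Sets ``trace.onset_time``.
    """
    if hold < 1:
        raise ParameterError("hold must be >= 1")
    t, d = trace.times, trace.distances
    idx = np.nonzero(t >= trace.fixation_time)[0]
    run = 0
    for i in idx:
        if d[i] < low_threshold:
            run += 1
            if run == hold:
                trace.onset_time = float(t[i - hold + 1])
                return trace.onset_time
        else:
            run = 0
    trace.onset_time = None
    return None
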