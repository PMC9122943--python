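"""AFM topograph loading, calibration and flattening.

Raw AFM height maps carry a tilted background (sample slope, piezo bow) and
per-scan-line offsets that must be removed before any feature on the few-nm
scale can be measured.  The chain implemented here mirrors the standard
scanning-probe processing sequence: a 2-D polynomial plane fit, per-line
polynomial levelling, and a small median filter, each with robust trimming so
that genuine protrusions do not drag the fitted baseline upward.

Heights are stored internally as float64 nanometres regardless of the source
bit depth; pixel size is isotropic and given in nm.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
from scipy import ndimage

from .exceptions import FormatError, InputError, ParameterError

__all__ = [
    "TopographyImage",
    "FlattenParams",
    "load_topography",
    "save_topography",
    "plane_fit_subtract",
    "line_level",
    "median_filter",
    "flatten",
]


@dataclass
class TopographyImage:
    """A calibrated 2-D height map.

    Attributes
    ----------
    heights:
        2-D float64 array of heights in nm, row = slow-scan axis.
    pixel_size:
        Isotropic sampling, nm per pixel.
    frame_index:
        Position of this frame in a time series (0 for single frames).
    meta:
        Free-form provenance record; processing steps append to
        ``meta["processing"]``.
    """

    heights: np.ndarray
    pixel_size: float
    frame_index: int = 0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.heights.ndim != 2:
            raise FormatError("heights must be a 2-D array")
        if not np.all(np.isfinite(self.heights)):
            bad = np.argwhere(~np.isfinite(self.heights))
            raise FormatError(
                f"non-finite heights at pixel (row, col) = {tuple(bad[0])}"
            )
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")

    @property
    def scan_size(self) -> tuple[float, float]:
        """(width, height) of the scanned field in nm."""
        nrow, ncol = self.heights.shape
        return (ncol * self.pixel_size, nrow * self.pixel_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def with_heights(self, heights: np.ndarray, step: str | None = None) -> "TopographyImage":
        meta = dict(self.meta)
        if step is not None:
            meta = {**meta, "processing": list(meta.get("processing", [])) + [step]}
        return replace(self, heights=np.asarray(heights, dtype=np.float64), meta=meta)


@dataclass
class FlattenParams:
    """Parameters of the flattening chain (plane fit -> line level -> median).

    ``tolerance`` is the fraction of pixels kept when re-fitting the
    polynomial baselines: after an initial fit, pixels are ranked by absolute
    residual and only the best ``tolerance`` fraction enters a single re-fit.
    This keeps protrusions out of the baseline.
    """

    plane_degree: int = 2
    line_degree: int = 3
    median_mask: int = 3
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.plane_degree < 0 or self.line_degree < 0:
            raise ParameterError("polynomial degrees must be >= 0")
        if self.median_mask < 1 or self.median_mask % 2 == 0:
            raise ParameterError("median_mask must be an odd integer >= 1")
        if not (0 < self.tolerance <= 1):
            raise ParameterError("tolerance must lie in (0, 1]")


def load_topography(
    path: str | Path,
    pixel_size: float,
    z_scale: float = 1.0,
    frame_index: int = 0,
) -> TopographyImage:
    """Load a height map from a grayscale TIFF or whitespace-delimited matrix.

    ``z_scale`` converts stored intensity units to nm (1.0 if the file is
    already in nm).
    """
    path = Path(path)
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be > 0")
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        try:
            raw = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - tifffile internals
            raise InputError(f"could not read TIFF {path}: {exc}") from exc
    else:
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                rows.append([float(tok) for tok in line.split()])
        if not rows:
            raise FormatError(f"{path}: empty matrix")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise FormatError(f"{path}: non-rectangular matrix")
        raw = np.array(rows, dtype=np.float64)
    raw = np.atleast_2d(np.asarray(raw, dtype=np.float64))
    if not np.all(np.isfinite(raw)):
        bad = np.argwhere(~np.isfinite(raw))[0]
        raise FormatError(f"{path}: NaN/inf at pixel (row, col) = {tuple(bad)}")
    return TopographyImage(
        heights=raw * z_scale,
        pixel_size=pixel_size,
        frame_index=frame_index,
        meta={"source": str(path), "z_scale": z_scale},
    )


def save_topography(img: TopographyImage, path: str | Path) -> Path:
    """Write a float32 TIFF plus a JSON sidecar with calibration/provenance."""
    path = Path(path)
    tifffile.imwrite(path, img.heights.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "pixel_size_nm": img.pixel_size,
                "frame_index": img.frame_index,
                "meta": {k: v for k, v in img.meta.items() if _jsonable(v)},
            },
            fh,
            indent=2,
        )
    return path


def _jsonable(v: Any) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _poly2d_design(shape: tuple[int, int], degree: int) -> np.ndarray:
    """Total-degree 2-D polynomial design matrix on coordinates scaled to [-1, 1]."""
    nrow, ncol = shape
    y = np.linspace(-1.0, 1.0, nrow) if nrow > 1 else np.zeros(1)
    x = np.linspace(-1.0, 1.0, ncol) if ncol > 1 else np.zeros(1)
    xx, yy = np.meshgrid(x, y)
    cols = [
        (xx**i * yy**j).ravel()
        for i, j in itertools.product(range(degree + 1), repeat=2)
        if i + j <= degree
    ]
    return np.column_stack(cols)


def _trimmed_lstsq(design: np.ndarray, values: np.ndarray, tolerance: float) -> np.ndarray:
    """Least-squares fit with one robust re-fit pass keeping the best fraction."""
    if design.shape[0] < design.shape[1]:
        raise ParameterError(
            f"degenerate fit: {design.shape[0]} samples for {design.shape[1]} terms"
        )
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    if tolerance < 1.0:
        resid = np.abs(values - design @ coef)
        keep = max(design.shape[1], int(round(tolerance * len(values))))
        idx = np.argsort(resid, kind="stable")[:keep]
        coef, *_ = np.linalg.lstsq(design[idx], values[idx], rcond=None)
    return coef


def plane_fit_subtract(
    img: TopographyImage, degree: int = 2, tolerance: float = 0.5
) -> TopographyImage:
    """Fit and subtract a 2-D polynomial background surface of total degree."""
    if degree < 0:
        raise ParameterError("degree must be >= 0")
    if not (0 < tolerance <= 1):
        raise ParameterError("tolerance must lie in (0, 1]")
    design = _poly2d_design(img.heights.shape, degree)
    coef = _trimmed_lstsq(design, img.heights.ravel(), tolerance)
    surface = (design @ coef).reshape(img.heights.shape)
    return img.with_heights(
        img.heights - surface, step=f"plane_fit(degree={degree}, tolerance={tolerance})"
    )


def line_level(
    img: TopographyImage,
    degree: int = 3,
    tolerance: float = 0.5,
    axis: int = 1,
) -> TopographyImage:
    """Subtract a per-scan-line polynomial baseline.

    ``axis=1`` levels along rows (the usual fast-scan direction); ``axis=0``
    levels along columns.
    """
    if degree < 0:
        raise ParameterError("degree must be >= 0")
    if not (0 < tolerance <= 1):
        raise ParameterError("tolerance must lie in (0, 1]")
    z = img.heights if axis == 1 else img.heights.T
    n = z.shape[1]
    if n < degree + 1:
        raise ParameterError(f"scan lines of {n} px cannot support degree {degree}")
    x = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    design = np.vander(x, degree + 1)
    out = np.empty_like(z)
    for r in range(z.shape[0]):
        coef = _trimmed_lstsq(design, z[r], tolerance)
        out[r] = z[r] - design @ coef
    if axis == 0:
        out = out.T
    return img.with_heights(
        out, step=f"line_level(degree={degree}, tolerance={tolerance}, axis={axis})"
    )


def median_filter(img: TopographyImage, mask_width: int = 3) -> TopographyImage:
    """Median-filter the height map with a square mask; edges are reflected."""
    if mask_width < 1 or mask_width % 2 == 0:
        raise ParameterError("mask_width must be an odd integer >= 1")
    out = ndimage.median_filter(img.heights, size=mask_width, mode="reflect")
    return img.with_heights(out, step=f"median_filter(mask_width={mask_width})")


def flatten(img: TopographyImage, params: FlattenParams | None = None) -> TopographyImage:
    """Full flattening chain: plane fit, per-line levelling, median filter."""
    p = params or FlattenParams()
    out = plane_fit_subtract(img, p.plane_degree, p.tolerance)
    out = line_level(out, p.line_degree, p.tolerance)
    out = median_filter(out, p.median_mask)
    return out
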