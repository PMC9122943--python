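"""AFM-fluorescence registration via membrane-hole fiducials.

The microporous support membrane carries a regular lattice of micrometre
holes visible in both modalities (dark in transmitted light / AFM height,
bright after FITC staining).  Hole centres are detected by thresholding and
circularity filtering; the rigid + scale (similarity) transform between the
two centre sets is estimated by coarse lattice alignment, mutual-nearest-
neighbour correspondence, and a closed-form least-squares (Umeyama) fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import SimilarityTransform, warp

from .exceptions import ParameterError

__all__ = [
    "HoleSet",
    "Transform2D",
    "detect_holes",
    "match_and_estimate",
    "apply_transform",
]


@dataclass
class HoleSet:
    """Detected hole centres of one modality (units of that modality, e.g. um)."""

    centers: np.ndarray  # (N, 2) (x, y)
    radius: float  # expected hole radius
    modality: str = ""

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.centers)


@dataclass
class Transform2D:
    """Similarity transform p' = s * R(phi) @ p + t, with fit RMSE."""

    scale: float
    rotation_deg: float
    translation: tuple[float, float]
    rmse: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        phi = np.deg2rad(self.rotation_deg)
        c, s = np.cos(phi), np.sin(phi)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.translation[0]],
                [self.scale * s, self.scale * c, self.translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, float).reshape(-1, 2)
        m = self.matrix
        return pts @ m[:2, :2].T + m[:2, 2]

    def inverse(self) -> "Transform2D":
        phi = np.deg2rad(self.rotation_deg)
        c, s = np.cos(phi), np.sin(phi)
        rinv = np.array([[c, s], [-s, c]]) / self.scale
        t = -rinv @ np.asarray(self.translation)
        return Transform2D(
            scale=1.0 / self.scale,
            rotation_deg=-self.rotation_deg,
            translation=(float(t[0]), float(t[1])),
        )


def detect_holes(
    image: np.ndarray,
    pixel_size: float,
    expected_diameter: float,
    dark_holes: bool = True,
    circularity_min: float = 0.8,
    modality: str = "",
) -> HoleSet:
    """Detect circular holes by Otsu thresholding and circularity filtering.

    ``dark_holes`` selects the polarity (True for transmitted-light/AFM where
    holes are dark, False for FITC-stained fluorescence where they are
    bright).  Components must have circularity 4*pi*A/P^2 >= 0.8 and a
    diameter within +/-30% of ``expected_diameter``.
    """
    image = np.asarray(image, float)
    if expected_diameter / pixel_size <= 4:
        raise ParameterError("expected_diameter must exceed 4 pixels")
    thr = threshold_otsu(image)
    mask = image < thr if dark_holes else image > thr
    centers = []
    for prop in regionprops(label(mask)):
        if prop.perimeter == 0:
            continue
        # border-clipped holes have biased centroids
        minr, minc, maxr, maxc = prop.bbox
        if minr == 0 or minc == 0 or maxr == image.shape[0] or maxc == image.shape[1]:
            continue
        circ = 4.0 * np.pi * prop.area / prop.perimeter**2
        diam = prop.equivalent_diameter_area * pixel_size
        if circ >= circularity_min and (
            0.7 * expected_diameter <= diam <= 1.3 * expected_diameter
        ):
            r, c = prop.centroid
            centers.append((c * pixel_size, r * pixel_size))
    centers = np.asarray(centers, float).reshape(-1, 2)
    return HoleSet(centers=centers, radius=expected_diameter / 2.0, modality=modality)


def _umeyama(src: np.ndarray, dst: np.ndarray) -> Transform2D:
    """Closed-form least-squares similarity transform mapping src -> dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    var_s = (xs**2).sum() / len(src)
    scale = float(np.trace(np.diag(D) @ S) / var_s) if var_s > 0 else 1.0
    t = mu_d - scale * R @ mu_s
    rot = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
    fit = Transform2D(scale=scale, rotation_deg=rot, translation=(float(t[0]), float(t[1])))
    fit.rmse = float(np.sqrt(np.mean(np.sum((fit.apply(src) - dst) ** 2, axis=1))))
    return fit


def _lattice_stats(pts: np.ndarray) -> tuple[float, float]:
    """(median NN spacing, principal lattice angle mod 90 deg) of a point set."""
    tree = cKDTree(pts)
    d, idx = tree.query(pts, k=2)
    vec = pts[idx[:, 1]] - pts
    ang = np.rad2deg(np.arctan2(vec[:, 1], vec[:, 0])) % 90.0
    # circular mean with period 90 degrees
    phase = np.deg2rad(ang * 4.0)
    mean_ang = np.rad2deg(np.arctan2(np.sin(phase).mean(), np.cos(phase).mean())) / 4.0
    return float(np.median(d[:, 1])), float(mean_ang % 90.0)


def match_and_estimate(a: HoleSet, b: HoleSet) -> Transform2D:
    """Estimate the similarity transform mapping set ``a`` onto set ``b``.

    Coarse alignment uses each set's principal lattice vector (NN spacing and
    direction); correspondences are mutual nearest neighbours under the
    coarse transform; the final transform is the closed-form least-squares
    similarity fit, refined with one re-matching pass.  The 90-degree lattice
    ambiguity is resolved by trying the four candidate rotations and keeping
    the one with most correspondences / lowest RMSE.
    """
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("need at least 2 holes per set")
    pa, pb = a.centers, b.centers
    if len(a) == 2 and len(b) == 2:
        cands = [_umeyama(pa, pb), _umeyama(pa, pb[::-1])]
        return min(cands, key=lambda t: t.rmse)

    pitch_a, ang_a = _lattice_stats(pa)
    pitch_b, ang_b = _lattice_stats(pb)
    scale0 = pitch_b / pitch_a
    candidates: list[tuple[int, Transform2D]] = []
    for k in range(-1, 3):
        rot0 = (ang_b - ang_a) + 90.0 * k
        coarse = Transform2D(scale=scale0, rotation_deg=rot0, translation=(0.0, 0.0))
        moved = coarse.apply(pa)
        shift = pb.mean(axis=0) - moved.mean(axis=0)
        moved = moved + shift
        pairs = _mutual_nn(moved, pb, max_dist=0.6 * pitch_b)
        if len(pairs) < 2:
            continue
        fit = _umeyama(pa[pairs[:, 0]], pb[pairs[:, 1]])
        pairs = _mutual_nn(fit.apply(pa), pb, max_dist=0.5 * pitch_b)
        if len(pairs) < 2:
            continue
        fit = _umeyama(pa[pairs[:, 0]], pb[pairs[:, 1]])
        candidates.append((len(pairs), fit))
    if not candidates:
        raise ParameterError("fewer than 2 hole correspondences found")
    n_best = max(n for n, _ in candidates)
    rmse_best = min(f.rmse for n, f in candidates if n == n_best)
    # a regular lattice is only identifiable modulo its 90-degree symmetry:
    # among near-equivalent candidates prefer the smallest rotation
    ties = [
        (n, f)
        for n, f in candidates
        if n == n_best and f.rmse <= rmse_best * 1.1 + 1e-12
    ]
    n_matched, best = min(ties, key=lambda nf: abs(((nf[1].rotation_deg + 180) % 360) - 180))
    best.meta["n_matches"] = int(n_matched)
    return best


def _mutual_nn(pa: np.ndarray, pb: np.ndarray, max_dist: float) -> np.ndarray:
    ta, tb = cKDTree(pa), cKDTree(pb)
    d_ab, j_ab = tb.query(pa, k=1)
    _, i_ba = ta.query(pb, k=1)
    pairs = [
        (i, j)
        for i, (j, d) in enumerate(zip(j_ab, d_ab))
        if d <= max_dist and i_ba[j] == i
    ]
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def apply_transform(
    img: np.ndarray,
    t: Transform2D,
    pixel_size_in: float = 1.0,
    pixel_size_out: float = 1.0,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Resample ``img`` into the target frame of ``t`` with bilinear sampling.

    ``t`` maps source coordinates (units of ``pixel_size_in``) to target
    coordinates (units of ``pixel_size_out``).  Out-of-bounds pixels are NaN.
    """
    img = np.asarray(img, float)
    if output_shape is None:
        output_shape = img.shape
    # pixel-space transform: target px -> source px (inverse map for warp)
    m = t.matrix.copy()
    scale_in = np.diag([pixel_size_in, pixel_size_in, 1.0])
    scale_out = np.diag([1.0 / pixel_size_out, 1.0 / pixel_size_out, 1.0])
    m_px = scale_out @ m @ scale_in
    tform = SimilarityTransform(matrix=m_px)
    return warp(
        img,
        inverse_map=tform.inverse,
        output_shape=output_shape,
        order=1,
        mode="constant",
        cval=np.nan,
        preserve_range=True,
    )
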