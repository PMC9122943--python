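"""Hertz-Sneddon force-curve analysis for a pyramidal indenter.

The approach segment of an AFM force-distance curve is modelled as a linear
(possibly tilted) baseline before contact and, past the contact point z0, a
quadratic indentation response

    F(z) = F0 + tilt*z + kappa * tan(theta) * E/(1-nu^2) * (z0 - z)^2,

where E is the Young's modulus, nu the Poisson ratio (0.5 for an
incompressible cell), theta the face half-angle of the pyramid and kappa a
dimensionless front factor (0.7453 for a regular three-sided pyramid, per
Bilodeau; 1/sqrt(2) recovers the four-sided convention).  The fitted E scales
inversely with kappa*tan(theta), so the geometric convention is explicit and
transparent.

Units: separation in nm, force in nN, E reported in kPa
(1 kPa = 1e-6 nN/nm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, FormatError, ParameterError

__all__ = [
    "ForceCurve",
    "HertzFit",
    "deflection_to_force",
    "separation_from_piezo",
    "load_force_curve",
    "hertz_force",
    "fit_hertz_pyramid",
    "modulus_map",
    "KPA_PER_NN_NM2",
]

# 1 nN/nm^2 = 1 GPa = 1e6 kPa
KPA_PER_NN_NM2 = 1.0e6


@dataclass
class ForceCurve:
    """Approach force-distance curve: separation (nm) decreasing into contact."""

    separation: np.ndarray
    force: np.ndarray
    spring_constant: float = 0.1  # N/m
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, float)
        self.force = np.asarray(self.force, float)
        if self.separation.shape != self.force.shape:
            raise FormatError("separation and force must have equal length")
        if self.separation.size < 20:
            raise FormatError("force curve needs at least 20 samples")
        if self.spring_constant <= 0:
            raise ParameterError("spring_constant must be > 0")


@dataclass
class HertzFit:
    """Fitted contact model parameters."""

    youngs_modulus: float  # kPa
    contact_point: float  # nm
    baseline: float  # nN
    baseline_tilt: float  # nN/nm
    poisson_ratio: float = 0.5
    half_angle: float = 17.5  # degrees
    front_factor: float = 0.7453
    rss: float = 0.0
    n_points: int = 0


def deflection_to_force(deflection: np.ndarray, spring_constant: float) -> np.ndarray:
    """Hooke's law: force (nN) = spring constant (N/m) x deflection (nm)."""
    deflection = np.asarray(deflection, float)
    if spring_constant <= 0:
        raise ParameterError("spring_constant must be > 0")
    return spring_constant * deflection


def separation_from_piezo(piezo: np.ndarray, deflection: np.ndarray) -> np.ndarray:
    """Tip-sample separation (nm) = piezo height - cantilever deflection."""
    piezo = np.asarray(piezo, float)
    deflection = np.asarray(deflection, float)
    if piezo.shape != deflection.shape:
        raise FormatError("piezo and deflection must have equal length")
    return piezo - deflection


def load_force_curve(
    path: str | Path,
    mode: str = "separation",
    spring_constant: float = 0.1,
) -> ForceCurve:
    """Read a two-column curve file.

    ``mode='separation'``: columns are (separation_nm, force_nN);
    ``mode='piezo'``: columns are (piezo_nm, deflection_nm), converted with
    the spring constant.
    """
    data = np.loadtxt(path, delimiter=None if str(path).endswith(".tsv") else None,
                      comments="#", ndmin=2)
    if data.shape[1] < 2:
        # retry comma-separated
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns")
    if mode == "separation":
        sep, force = data[:, 0], data[:, 1]
    elif mode == "piezo":
        sep = separation_from_piezo(data[:, 0], data[:, 1])
        force = deflection_to_force(data[:, 1], spring_constant)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return ForceCurve(sep, force, spring_constant, meta={"source": str(path)})


def _front_coeff(nu: float, theta_deg: float, kappa: float) -> float:
    """kappa*tan(theta)/(1-nu^2) in (nN/nm^2) per (nN/nm^2) of E."""
    return kappa * np.tan(np.deg2rad(theta_deg)) / (1.0 - nu**2)


def hertz_force(
    z: np.ndarray,
    E_kPa: float,
    z0: float,
    F0: float = 0.0,
    tilt: float = 0.0,
    nu: float = 0.5,
    theta_deg: float = 17.5,
    kappa: float = 0.7453,
) -> np.ndarray:
    """Forward model: baseline + pyramidal Hertz-Sneddon indentation force."""
    z = np.asarray(z, float)
    delta = np.clip(z0 - z, 0.0, None)  # indentation depth, nm
    coeff = _front_coeff(nu, theta_deg, kappa) * (E_kPa / KPA_PER_NN_NM2)
    return F0 + tilt * z + coeff * delta**2


def fit_hertz_pyramid(
    curve: ForceCurve,
    nu: float = 0.5,
    theta_deg: float = 17.5,
    kappa: float = 0.7453,
    fit_tilt: bool = True,
) -> HertzFit:
    """Fit (E, z0, F0, tilt) to an approach curve by nonlinear least squares.

    Initialisation: the baseline level and noise SD come from the 30% of
    samples farthest from the surface; z0 starts at the first point (scanning
    toward contact) exceeding baseline + 3 SD; E starts from the closed-form
    inversion at the deepest point.
    """
    if not (0 < theta_deg < 90):
        raise ParameterError("theta_deg must be in (0, 90)")
    if not (0 <= nu <= 0.5):
        raise ParameterError("poisson ratio must be in [0, 0.5]")
    order = np.argsort(curve.separation)[::-1]  # far -> deep
    z = curve.separation[order]
    F = curve.force[order]

    n_base = max(5, int(0.3 * z.size))
    base_level = float(np.median(F[:n_base]))
    base_sd = float(np.std(F[:n_base]))
    thresh = base_level + 3.0 * max(base_sd, 1e-12)
    above = np.nonzero(F > thresh)[0]
    above = above[above >= n_base // 2] if above.size else above
    if above.size == 0 or above[0] == 0:
        raise FitError("no contact region detected (force never exceeds baseline noise)")
    i0 = int(above[0])
    z0_init = float(z[i0])

    coeff_unit = _front_coeff(nu, theta_deg, kappa)
    delta_max = max(z0_init - z[-1], 1e-6)
    E_init = max((F[-1] - base_level) / (coeff_unit * delta_max**2), 1e-12) * KPA_PER_NN_NM2

    def residuals(params: np.ndarray) -> np.ndarray:
        E_kPa, z0, F0, tilt = params
        return hertz_force(z, E_kPa, z0, F0, tilt if fit_tilt else 0.0,
                           nu, theta_deg, kappa) - F

    x0 = np.array([E_init, z0_init, base_level, 0.0])
    scale = np.array([max(E_init, 1.0), max(abs(z0_init), np.ptp(z) / 10, 1.0),
                      max(abs(base_level), np.std(F), 1e-3), 1e-3])
    res = least_squares(
        residuals,
        x0,
        x_scale=scale,
        bounds=([1e-9, z.min(), -np.inf, -np.inf], [np.inf, z.max(), np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    E_kPa, z0, F0, tilt = res.x
    if not np.isfinite(E_kPa) or E_kPa <= 0:
        raise FitError("fit produced a non-positive Young's modulus")
    return HertzFit(
        youngs_modulus=float(E_kPa),
        contact_point=float(z0),
        baseline=float(F0),
        baseline_tilt=float(tilt) if fit_tilt else 0.0,
        poisson_ratio=nu,
        half_angle=theta_deg,
        front_factor=kappa,
        rss=float(np.sum(res.fun**2)),
        n_points=int(z.size),
    )


def modulus_map(
    curves,
    nu: float = 0.5,
    theta_deg: float = 17.5,
    kappa: float = 0.7453,
):
    """Fit every curve of a 2-D grid; failed fits are masked.

    ``curves`` is a nested sequence (rows of ForceCurve or None).  Returns
    (masked E map in kPa, summary dict with mean, SEM, n_valid, n_failed).
    """
    nrow = len(curves)
    ncol = len(curves[0])
    E = np.full((nrow, ncol), np.nan)
    n_failed = 0
    for i in range(nrow):
        for j in range(ncol):
            c = curves[i][j]
            if c is None:
                n_failed += 1
                continue
            try:
                E[i, j] = fit_hertz_pyramid(c, nu, theta_deg, kappa).youngs_modulus
            except (FitError, FormatError):
                n_failed += 1
    valid = np.isfinite(E)
    if not valid.any():
        raise FitError("all force-curve fits failed")
    vals = E[valid]
    summary = {
        "mean_kPa": float(vals.mean()),
        "sem_kPa": float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0,
        "n_valid": int(vals.size),
        "n_failed": int(n_failed),
    }
    return np.ma.masked_invalid(E), summary
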