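"""Patchy-vesicle geometry and the orientation-gated propulsion law.

The swimmer is a spherical vesicle of radius ``R`` whose membrane carries
a single highly permeable circular patch of radius ``r_patch``.  Enzymatic
reaction products leave the lumen preferentially through the patch, so
the product cloud — and with it the phoretic propulsion — is strongest
when the patch faces up-gradient.  The angle ``beta`` between the patch
axis (the orientation unit vector **n**) and the local chemical-gradient
direction gates the propulsion speed:

    V(beta) = V0 * (cos(beta/2)) ** p,       p = nint(2*pi/alpha)

where ``alpha`` is the sector angle of the patch.  The same functional
form describes the normalised product concentration just outside the
patch; :func:`product_distribution_numeric` provides an independent
numerical profile (a superposition of steady-diffusion point sources
covering the patch cap) against which the exponent can be fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, GeometryError, ParameterError


def patch_sector_angle(r_patch_nm: float, R_nm: float) -> float:
    """Sector angle alpha = 2*arcsin(r_patch/R) of the permeable cap, rad.

    The patch radius is read as the chord radius of the spherical cap, so
    ``r_patch -> R`` gives a hemispherical patch (alpha -> pi).
    """
    if not (0 < r_patch_nm < R_nm):
        raise GeometryError(
            f"patch radius must satisfy 0 < r_patch < R, got r={r_patch_nm}, R={R_nm}"
        )
    return 2.0 * math.asin(r_patch_nm / R_nm)


def patch_exponent(alpha_rad: float) -> int:
    """Gating exponent p = nint(2*pi/alpha); ties round half away from zero."""
    if not (0 < alpha_rad <= math.pi):
        raise ParameterError(f"alpha must lie in (0, pi], got {alpha_rad}")
    x = 2.0 * math.pi / alpha_rad
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SwimmerGeometry:
    """Vesicle radius, permeable-patch radius (nm) and derived sector angle."""

    R_nm: float = 50.0
    r_patch_nm: float = 15.0

    def __post_init__(self) -> None:
        patch_sector_angle(self.r_patch_nm, self.R_nm)  # validates

    @property
    def alpha_rad(self) -> float:
        return patch_sector_angle(self.r_patch_nm, self.R_nm)

    @property
    def exponent(self) -> int:
        return patch_exponent(self.alpha_rad)


@dataclass(frozen=True)
class PropulsionLaw:
    """Maximal propulsion speed V0 (μm/s) and the integer gating exponent."""

    V0_um_s: float
    exponent: int = 10
    amplitude_A: float = 1.0

    def __post_init__(self) -> None:
        if self.V0_um_s < 0:
            raise ParameterError(f"V0 must be non-negative, got {self.V0_um_s}")
        if not (isinstance(self.exponent, (int, np.integer)) and self.exponent >= 1):
            raise ParameterError(f"exponent must be an integer >= 1, got {self.exponent}")

    @classmethod
    def from_geometry(cls, geometry: SwimmerGeometry, V0_um_s: float) -> "PropulsionLaw":
        return cls(V0_um_s=V0_um_s, exponent=geometry.exponent)


def propulsion_speed(law: PropulsionLaw, beta_rad: float) -> float:
    """Gated speed V(beta) = V0 * cos(beta/2)**p for beta in [0, pi]."""
    if not (0.0 <= beta_rad <= math.pi):
        raise ParameterError(f"beta must lie in [0, pi], got {beta_rad}")
    return law.V0_um_s * math.cos(beta_rad / 2.0) ** law.exponent


def mean_gated_drift_factor(exponent: int) -> float:
    """Isotropic-orientation mean of cos(beta) * cos(beta/2)**p, exact.

    With x = cos(beta) uniform on [-1, 1] this is
    (1/2) ∫ x ((1+x)/2)^(p/2) dx = p / ((p/2 + 1) (p/2 + 2)) / 2 for even p;
    evaluated here for any integer p via the closed form
    2 p / ((p + 2) (p + 4)).  For p = 10 the value is 5/42: the steady-state
    chemotactic drift of an isotropically oriented ensemble is V0 * 5/42.
    """
    p = int(exponent)
    if p < 1:
        raise ParameterError("exponent must be >= 1")
    return 2.0 * p / ((p + 2.0) * (p + 4.0))


def _cap_sources(geometry: SwimmerGeometry, n_sources: int, rng_free: bool = True) -> np.ndarray:
    """Deterministic quasi-uniform points on the patch spherical cap (unit sphere).

    Fibonacci lattice in (cos(theta), azimuth) restricted to the cap of
    half-angle alpha/2 around the +z axis; returned scaled to radius R.
    """
    half = geometry.alpha_rad / 2.0
    cos_min = math.cos(half)
    i = np.arange(n_sources)
    # uniform in solid angle over the cap
    cos_t = 1.0 - (1.0 - cos_min) * (i + 0.5) / n_sources
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = golden * i
    pts = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return geometry.R_nm * pts


def product_distribution_numeric(
    geometry: SwimmerGeometry,
    n_sources: int = 2000,
    offset_nm: float | None = None,
    beta_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state product concentration just outside the vesicle vs. beta.

    The patch is tiled with ``n_sources`` point sources of equal strength;
    each contributes a free-space steady-diffusion kernel ∝ 1/distance.
    The field is evaluated on a shell at radius ``R + offset`` at polar
    angle beta from the patch axis, averaged over azimuth to suppress the
    residual anisotropy of the source lattice.

    The evaluation offset is the one free parameter of this simplified
    kernel: very close to the membrane the profile reduces to the sharp
    patch footprint, far away it flattens into a monopole.  The default,
    half the patch radius, is the distance over which the patch near-field
    smooths out; there the profile is well described by the analytic
    gating law with its geometric exponent.

    Returns ``(beta_grid, profile)`` with the profile normalised to a
    maximum of 1.  This is an approximation: no substrate depletion and
    no boundary condition on the vesicle surface are imposed.
    """
    if n_sources < 100:
        raise ParameterError(f"n_sources must be >= 100, got {n_sources}")
    if offset_nm is None:
        offset_nm = geometry.r_patch_nm / 2.0
    if not (offset_nm > 0):
        raise ParameterError(f"offset must be positive, got {offset_nm}")
    if beta_grid is None:
        beta_grid = np.linspace(0.0, math.pi, 181)
    beta_grid = np.asarray(beta_grid, dtype=float)

    sources = _cap_sources(geometry, n_sources)
    r_eval = geometry.R_nm + offset_nm
    # evaluation points in the xz-plane; average over a few azimuths to
    # suppress the residual azimuthal anisotropy of the source lattice
    profile = np.zeros_like(beta_grid)
    n_az = 8
    for k in range(n_az):
        az = 2.0 * math.pi * k / n_az
        ex = np.column_stack([
            r_eval * np.sin(beta_grid) * np.cos(az),
            r_eval * np.sin(beta_grid) * np.sin(az),
            r_eval * np.cos(beta_grid),
        ])
        d = np.linalg.norm(ex[:, None, :] - sources[None, :, :], axis=2)
        profile += (1.0 / d).sum(axis=1)
    profile /= profile.max()
    return beta_grid, profile


def _gating_model(beta: np.ndarray, A: float, p: float) -> np.ndarray:
    return A * np.cos(beta / 2.0) ** p


def fit_patch_exponent(
    beta_grid: np.ndarray, profile: np.ndarray
) -> tuple[float, float, int]:
    """Least-squares fit of A * cos(beta/2)**p to a normalised profile.

    Returns ``(A, p, nint(p))``.  Raises :class:`FitError` when the
    profile carries no usable angular structure (constant, or increasing
    with beta overall).
    """
    beta = np.asarray(beta_grid, dtype=float)
    prof = np.asarray(profile, dtype=float)
    if beta.size < 10 or (beta.max() - beta.min()) < 0.9 * math.pi:
        raise FitError("profile must have >= 10 points spanning (0, pi)")
    if np.allclose(prof, prof[0]):
        raise FitError("profile is constant; exponent is unidentifiable")
    if prof[-1] >= prof[0]:
        raise FitError("profile does not decay with beta; not a patch-source shape")
    try:
        popt, _ = curve_fit(
            _gating_model, beta, prof, p0=(prof.max(), 5.0),
            bounds=((0.0, 0.5), (np.inf, 200.0)), maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"exponent fit did not converge: {exc}") from exc
    A_hat, p_hat = float(popt[0]), float(popt[1])
    return A_hat, p_hat, int(math.floor(p_hat + 0.5))
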