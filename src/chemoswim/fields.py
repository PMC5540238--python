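"""Substrate concentration fields and ambient flow.

Three analytic substrate fields cover the experimental scenarios:

``linear``
    A constant gradient, the quasi-steady state reached a while after
    substrate addition, when ∇C is approximately constant across the
    field of view.
``diffusive_1d``
    Substrate released at time ``start_time`` from one side of the
    observation chamber held at concentration ``C0``; the half-space
    solution ``C(s, t) = C0 · erfc(s / (2 √(D_s (t − t0))))`` with ``s``
    the distance from the source plane along ``direction``.
``radial_disk``
    A disk source (an agarose plug soaked in substrate) of radius
    ``source_radius`` held at ``C0``; radial erfc approximation of the
    in-plane diffusion field.

Gradients are the exact spatial derivatives of the implemented forms.
Concentration is clamped to the source value behind the source and is
zero (with zero gradient) before ``start_time``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .errors import ParameterError

FIELD_NONE = 0
FIELD_LINEAR = 1
FIELD_DIFFUSIVE_1D = 2
FIELD_RADIAL_DISK = 3

_KIND_CODES = {
    "none": FIELD_NONE,
    "linear": FIELD_LINEAR,
    "diffusive_1d": FIELD_DIFFUSIVE_1D,
    "radial_disk": FIELD_RADIAL_DISK,
}

#: Glucose diffusivity in water at 37 °C, μm²/s (literature value).
GLUCOSE_DIFFUSIVITY_UM2_S = 600.0


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not (n > 0):
        raise ParameterError("direction vector must be non-zero")
    return v / n


@dataclass(frozen=True)
class SubstrateField:
    """Analytic substrate concentration field C(r, t) with exact gradient.

    Parameters
    ----------
    kind:
        One of ``none``, ``linear``, ``diffusive_1d``, ``radial_disk``.
    C0:
        Source concentration, mol/L.
    direction:
        Up-gradient unit direction for ``linear``; for ``diffusive_1d``
        the direction pointing *away* from the source plane (the
        gradient then points back toward the source).
    gradient_M_per_um:
        Constant gradient magnitude for ``linear``, mol/L per μm.
    source_position:
        Scalar coordinate of the source plane along ``direction``
        (``diffusive_1d``) or the 2-vector disk centre (``radial_disk``), μm.
    source_radius_um:
        Disk radius for ``radial_disk``, μm.
    D_s_um2_s:
        Substrate diffusivity, μm²/s.
    start_time_s:
        Moment the substrate is added.
    """

    kind: str = "none"
    C0: float = 0.0
    direction: tuple = (1.0, 0.0, 0.0)
    gradient_M_per_um: float = 0.0
    source_position: tuple | float = 0.0
    source_radius_um: float = 0.0
    D_s_um2_s: float = GLUCOSE_DIFFUSIVITY_UM2_S
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ParameterError(f"unknown field kind {self.kind!r}")
        if self.C0 < 0:
            raise ParameterError("C0 must be non-negative")
        if self.kind in ("diffusive_1d", "radial_disk") and not (self.D_s_um2_s > 0):
            raise ParameterError("substrate diffusivity must be positive")
        if self.kind != "none":
            _unit(self.direction)

    @property
    def code(self) -> int:
        return _KIND_CODES[self.kind]

    def pack(self) -> np.ndarray:
        """Flatten to the parameter vector consumed by the numba kernels."""
        fp = np.zeros(8)
        if self.kind == "linear":
            d = np.zeros(3)
            d[: len(self.direction)] = _unit(self.direction)
            fp[:5] = [self.C0, self.gradient_M_per_um, *d]
        elif self.kind == "diffusive_1d":
            d = np.zeros(3)
            d[: len(self.direction)] = _unit(self.direction)
            fp[:5] = [self.C0, float(self.source_position), *d]
            fp[5] = self.D_s_um2_s
            fp[6] = self.start_time_s
        elif self.kind == "radial_disk":
            sx, sy = np.asarray(self.source_position, dtype=float)[:2]
            fp[:4] = [self.C0, self.source_radius_um, sx, sy]
            fp[5] = self.D_s_um2_s
            fp[6] = self.start_time_s
        return fp


def evaluate_field(substrate: SubstrateField, position, time_s: float):
    """Concentration (mol/L) and gradient vector (mol/L/μm) at one point.

    ``position`` is a 3-vector in μm (2-vectors are zero-padded).
    """
    if time_s < 0:
        raise ParameterError("time must be non-negative")
    r = np.zeros(3)
    pos = np.asarray(position, dtype=float)
    r[: pos.size] = pos
    grad = np.zeros(3)

    if substrate.kind == "none":
        return 0.0, grad

    if substrate.kind == "linear":
        d = np.zeros(3)
        d[: len(substrate.direction)] = _unit(substrate.direction)
        C = substrate.C0 + substrate.gradient_M_per_um * float(r @ d)
        if C <= 0.0:
            return 0.0, grad
        return C, substrate.gradient_M_per_um * d

    if substrate.kind == "diffusive_1d":
        if time_s <= substrate.start_time_s:
            return 0.0, grad
        d = np.zeros(3)
        d[: len(substrate.direction)] = _unit(substrate.direction)
        s = float(r @ d) - float(substrate.source_position)
        if s <= 0.0:
            return substrate.C0, grad
        w = 2.0 * math.sqrt(substrate.D_s_um2_s * (time_s - substrate.start_time_s))
        xi = s / w
        C = substrate.C0 * float(erfc(xi))
        dCds = -substrate.C0 * 2.0 / math.sqrt(math.pi) * math.exp(-(xi**2)) / w
        return C, dCds * d

    # radial_disk
    if time_s <= substrate.start_time_s:
        return 0.0, grad
    sx, sy = np.asarray(substrate.source_position, dtype=float)[:2]
    dx, dy = r[0] - sx, r[1] - sy
    rho = math.hypot(dx, dy)
    if rho <= substrate.source_radius_um:
        return substrate.C0, grad
    w = 2.0 * math.sqrt(substrate.D_s_um2_s * (time_s - substrate.start_time_s))
    xi = (rho - substrate.source_radius_um) / w
    C = substrate.C0 * float(erfc(xi))
    dCdr = -substrate.C0 * 2.0 / math.sqrt(math.pi) * math.exp(-(xi**2)) / w
    grad[0] = dCdr * dx / rho
    grad[1] = dCdr * dy / rho
    return C, grad


@dataclass(frozen=True)
class FlowField:
    """Ambient flow: ``none`` or a uniform velocity vector in μm/s."""

    kind: str = "none"
    velocity_um_s: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "uniform"):
            raise ParameterError(f"unknown flow kind {self.kind!r}")
        v = np.asarray(self.velocity_um_s, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ParameterError("flow velocity components must be finite")

    def vector(self) -> np.ndarray:
        v = np.zeros(3)
        if self.kind == "uniform":
            vv = np.asarray(self.velocity_um_s, dtype=float)
            v[: vv.size] = vv
        return v
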