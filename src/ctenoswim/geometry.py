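"""Spheroidal body geometry, ctene placement and rotation kinematics.

The ctenophore body is modelled as a prolate spheroid with semi-major axis
``b = L_B/2`` along the aboral–oral symmetry axis and semi-minor axis
``a = d_B/2``.  Body frame convention: ``e1'`` points from the aboral pole
toward the mouth (oral positive), ``e2'`` lies in the tentacular plane and
``e3'`` completes the right-handed triad; the tentacular plane is the
``e1'–e2'`` plane and the sagittal plane the ``e1'–e3'`` plane.

Eight comb rows circumscribe the body: four "tentacular" rows adjacent to
the tentacular plane (azimuths ±eps_T and their 180° reflections) and four
"sagittal" rows adjacent to the sagittal plane (±eps_S and reflections).
Within a row, the most aboral ctene sits at a position angle ``kappa``
(measured about the centroid from the aboral pole) and successive ctenes are
spaced by a meridian arc length ``delta = s*l`` toward the oral end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "Morphometry",
    "BodyProperties",
    "CtenePlacement",
    "build_rotation_matrix",
    "euler_rate",
    "build_body",
    "place_ctenes",
    "quadrant_rows",
    "N_ROWS",
]

N_ROWS = 8

#: cos(theta) threshold below which Euler-angle rates are singular
GIMBAL_TOL = 1e-6


class GeometryError(ValueError):
    """Invalid morphometry or ctene layout (e.g. row overflowing the oral pole)."""


class GimbalLockError(ArithmeticError):
    """Pitch too close to ±90° for the yaw–pitch–roll rate map."""


@dataclass(frozen=True)
class Morphometry:
    """Body and comb-row measurements (SI units internally).

    Defaults are the study-population means for *Bolinopsis vitrea*:
    body length 7.8 mm, diameter 6.1 mm, ctene length 0.5 mm, normalized
    inter-ctene spacing s = delta/l = 0.8, 10 ctenes per sagittal row,
    7 per tentacular row, row azimuths 63.9° / 23° from the tentacular
    plane and first-ctene position angle 27°.
    """

    L_B: float = 7.8e-3   # body length (m)
    d_B: float = 6.1e-3   # body diameter in the tentacular plane (m)
    l: float = 0.5e-3     # ctene length (m)
    s: float = 0.8        # inter-ctene spacing ratio delta/l (-)
    n_S: int = 10         # ctenes per sagittal row
    n_T: int = 7          # ctenes per tentacular row
    eps_S: float = 63.9   # sagittal row azimuth from tentacular plane (deg)
    eps_T: float = 23.0   # tentacular row azimuth from tentacular plane (deg)
    kappa: float = 27.0   # position angle of the most aboral ctene (deg)

    def __post_init__(self) -> None:
        for name in ("L_B", "d_B", "l", "s"):
            if not (getattr(self, name) > 0 and math.isfinite(getattr(self, name))):
                raise GeometryError(f"{name} must be positive and finite")
        if self.n_S < 1 or self.n_T < 1:
            raise GeometryError("n_S and n_T must be >= 1")
        if not (0.0 < self.eps_T < self.eps_S < 90.0):
            raise GeometryError("require 0 < eps_T < eps_S < 90 degrees")
        if not (0.0 < self.kappa < 90.0):
            raise GeometryError("require 0 < kappa < 90 degrees")
        # The ctene arc must fit on the half-meridian; checked by placing.
        _meridian_alphas(self, max(self.n_S, self.n_T))

    @property
    def delta(self) -> float:
        """Meridian arc length between neighbouring ctenes (m)."""
        return self.s * self.l


@dataclass(frozen=True)
class BodyProperties:
    """Derived inertial and volumetric properties of the spheroidal body."""

    a: float            # semi-minor axis (m)
    b: float            # semi-major axis (m)
    V: float            # volume (m^3)
    m: float            # mass (kg), neutral buoyancy
    d_e: float          # equivalent-sphere diameter (m)
    I: np.ndarray = field(repr=False)  # 3x3 inertia matrix, body frame (kg m^2)

    @property
    def aspect_ratio(self) -> float:
        return self.b / self.a


@dataclass(frozen=True)
class CtenePlacement:
    """One ctene's placement on the body surface.

    ``lam`` is the angle of the local meridian tangent relative to the
    symmetry axis; the oscillation direction of the plate in the body frame
    is ``[cos lam, sin lam * cos eps, sin lam * sin eps]``.
    """

    row_id: int         # 0..7
    k: int              # index within row, 1 = most aboral
    r_prime: np.ndarray  # position relative to centroid, body frame (m)
    lam: float          # meridian tangent angle (rad)
    eps: float          # row azimuth from tentacular plane (rad)


def build_rotation_matrix(psi: float, theta: float, phi: float) -> np.ndarray:
    """Global→body rotation matrix for yaw ``psi``, pitch ``theta``, roll ``phi``.

    Successive rotations about e3' (yaw), e2' (pitch) and e1' (roll);
    a global vector x maps to the body frame via ``x' = R @ x``.
    """
    if not all(math.isfinite(v) for v in (psi, theta, phi)):
        raise ValueError("Euler angles must be finite")
    cps, sps = math.cos(psi), math.sin(psi)
    cth, sth = math.cos(theta), math.sin(theta)
    cph, sph = math.cos(phi), math.sin(phi)
    return np.array([
        [cth * cps, cth * sps, -sth],
        [sph * sth * cps - cph * sps, sph * sth * sps + cph * cps, sph * cth],
        [cph * sth * cps + sph * sps, cph * sth * sps - sph * cps, cph * cth],
    ])


def euler_rate(omega_body: np.ndarray, psi: float, theta: float, phi: float):
    """Rates (psi_dot, theta_dot, phi_dot) from the body-frame angular velocity.

    Standard yaw–pitch–roll kinematics; singular at |cos theta| -> 0.
    """
    cth = math.cos(theta)
    if abs(cth) <= GIMBAL_TOL:
        raise GimbalLockError(f"pitch {theta} rad too close to gimbal lock")
    wx, wy, wz = (float(c) for c in omega_body)
    sph, cph = math.sin(phi), math.cos(phi)
    tth = math.tan(theta)
    psi_dot = (wy * sph + wz * cph) / cth
    theta_dot = wy * cph - wz * sph
    phi_dot = wx + (wy * sph + wz * cph) * tth
    return psi_dot, theta_dot, phi_dot


def build_body(morph: Morphometry, rho_fluid: float = 1025.0) -> BodyProperties:
    """Spheroid volume, neutrally buoyant mass, equivalent diameter and inertia.

    The body is treated as a homogeneous solid spheroid of the fluid's
    density (ctenophores are near-neutrally buoyant); the inertia matrix is
    diagonal with the roll axis distinct from the (equal) pitch/yaw axes.
    """
    a = morph.d_B / 2.0
    b = morph.L_B / 2.0
    V = 4.0 / 3.0 * math.pi * a * a * b
    m = rho_fluid * V
    d_e = 2.0 * (a * a * b) ** (1.0 / 3.0)
    I1 = 0.4 * m * a * a                  # about the symmetry (roll) axis
    I2 = 0.2 * m * (a * a + b * b)        # pitch/yaw axes
    I = np.diag([I1, I2, I2])
    return BodyProperties(a=a, b=b, V=V, m=m, d_e=d_e, I=I)


def _meridian_arc_integrand(alpha: float, a: float, b: float) -> float:
    return math.sqrt((b * math.sin(alpha)) ** 2 + (a * math.cos(alpha)) ** 2)


def _alpha_from_centroid_angle(gamma: float, a: float, b: float) -> float:
    """Parametric polar angle alpha for a geometric (centroid) angle gamma.

    gamma is measured from the aboral pole direction about the centroid;
    the surface point is x' = -b cos(alpha), radial = a sin(alpha).
    """
    r = 1.0 / math.sqrt((math.cos(gamma) / b) ** 2 + (math.sin(gamma) / a) ** 2)
    return math.atan2(r * math.sin(gamma) / a, r * math.cos(gamma) / b)


def _meridian_alphas(morph: Morphometry, n: int) -> np.ndarray:
    """Parametric angles of n ctenes spaced by arc delta from kappa, oral-ward."""
    a, b = morph.d_B / 2.0, morph.L_B / 2.0
    alpha0 = _alpha_from_centroid_angle(math.radians(morph.kappa), a, b)
    delta = morph.delta

    def arc_from(alpha_lo: float, alpha_hi: float) -> float:
        return quad(_meridian_arc_integrand, alpha_lo, alpha_hi, args=(a, b))[0]

    alphas = [alpha0]
    for _ in range(n - 1):
        prev = alphas[-1]
        if arc_from(prev, math.pi) < delta * (1 - 1e-12):
            raise GeometryError(
                "ctene row overflows the oral pole: reduce n, s, l or kappa"
            )
        alphas.append(brentq(lambda x: arc_from(prev, x) - delta, prev, math.pi))
    return np.asarray(alphas)


def place_ctenes(morph: Morphometry) -> list[CtenePlacement]:
    """Place all 8 rows of ctenes on the spheroid surface.

    Rows 0–7 are ordered by body quadrant (one sagittal + one tentacular row
    per quadrant): quadrant 0 holds rows {0: sagittal +eps_S, 1: tentacular
    +eps_T}, quadrant 1 rows {2, 3} at −eps_T/−eps_S, quadrant 2 rows {4, 5}
    at 180°−eps_S / 180°−eps_T, quadrant 3 rows {6, 7} at 180°+eps_T /
    180°+eps_S.
    """
    a, b = morph.d_B / 2.0, morph.L_B / 2.0
    eS, eT = math.radians(morph.eps_S), math.radians(morph.eps_T)
    rows = [
        (eS, morph.n_S), (eT, morph.n_T),
        (-eT, morph.n_T), (-eS, morph.n_S),
        (math.pi - eS, morph.n_S), (math.pi - eT, morph.n_T),
        (math.pi + eT, morph.n_T), (math.pi + eS, morph.n_S),
    ]
    alphas_S = _meridian_alphas(morph, morph.n_S)
    alphas_T = _meridian_alphas(morph, morph.n_T)
    placements: list[CtenePlacement] = []
    for row_id, (eps, n) in enumerate(rows):
        alphas = alphas_S if n == morph.n_S else alphas_T
        for k, alpha in enumerate(alphas, start=1):
            sa, ca = math.sin(alpha), math.cos(alpha)
            r_prime = np.array([-b * ca, a * sa * math.cos(eps), a * sa * math.sin(eps)])
            lam = math.atan2(a * ca, b * sa)
            placements.append(
                CtenePlacement(row_id=row_id, k=k, r_prime=r_prime, lam=lam, eps=eps)
            )
    return placements


def quadrant_rows() -> list[tuple[int, int]]:
    """Row-id pairs sharing a body quadrant (controlled together in vivo)."""
    return [(0, 1), (2, 3), (4, 5), (6, 7)]
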