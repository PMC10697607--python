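"""Quasi-steady hydrodynamic forces and torques at intermediate Reynolds number.

Implements the blade-element force balance of the reduced-order swimmer:

* row propulsive force — the negative of the quasi-steady drag summed over
  the oscillating plates of a comb row, with the plate drag coefficient
  evaluated at the instantaneous plate Reynolds number;
* body drag — component-wise quadratic drag on the spheroid, with distinct
  longitudinal and transverse coefficients and areas (``pi a^2`` axial,
  ``pi a b`` lateral);
* acceleration-reaction (added-mass) force — ``-rho V diag(Cm) a'`` with
  Lamb's potential-flow coefficients for a prolate spheroid;
* opposing torque — ``-(rho/2)(d_e/2)^5 sgn(w_i) C_R w_i^2`` per body axis.

The coefficient correlations live behind :class:`CoefficientModel` so that
better-sourced correlations can replace the defaults without touching the
dynamics.  The defaults are engineering reconstructions built to satisfy
the known limits (Stokes law, sphere degeneracy, monotone decrease with Re);
see ``docs/methods.md`` for their provenance and validity bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .geometry import BodyProperties, CtenePlacement
from .kinematics import PlateState, plate_velocity_global

__all__ = [
    "FluidProperties",
    "CoefficientModel",
    "default_coefficients",
    "prolate_added_mass",
    "stokes_shape_factors",
    "stokes_torque_ratios",
    "row_force",
    "net_force",
    "propulsive_torque",
    "body_drag",
    "added_mass_force",
    "opposing_torque",
]


@dataclass(frozen=True)
class FluidProperties:
    """Seawater at the study temperature by default (21–23 °C)."""

    rho: float = 1025.0   # density (kg/m^3)
    nu: float = 1.05e-6   # kinematic viscosity (m^2/s)

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.nu <= 0:
            raise ValueError("fluid density and viscosity must be positive")

    @property
    def mu(self) -> float:
        return self.rho * self.nu


@dataclass(frozen=True)
class CoefficientModel:
    """Pluggable drag / added-mass / rotation-torque coefficient strategies.

    Each entry is a callable of the relevant Reynolds number (added-mass
    coefficients are Re-independent constants fixed by the aspect ratio).
    ``params`` carries the numeric constants the fast integrator kernel
    needs; custom models with ``params=None`` route the simulator through
    the reference (slow) force path.
    """

    name: str
    C_A: Callable[[float], float]
    C_B_par: Callable[[float], float]
    C_B_perp: Callable[[float], float]
    C_m_par: float
    C_m_perp: float
    C_R_par: Callable[[float], float]
    C_R_perp: Callable[[float], float]
    validity: str = "Re in ~[1, 1000]"
    params: dict | None = field(default=None, repr=False)


def prolate_added_mass(aspect_ratio: float) -> tuple[float, float]:
    """Lamb potential-flow added-mass coefficients (axial, transverse).

    For a sphere both equal 1/2; for a prolate spheroid the axial
    coefficient is smaller than the transverse one.
    """
    q = aspect_ratio
    if q < 1.0:
        raise ValueError("aspect ratio b/a must be >= 1 (prolate or sphere)")
    if q < 1.0 + 1e-9:
        return 0.5, 0.5
    e = math.sqrt(1.0 - 1.0 / (q * q))
    at = math.atanh(e)
    alpha0 = 2.0 * (1.0 - e * e) / e**3 * (at - e)
    beta0 = 1.0 / (e * e) - (1.0 - e * e) / e**3 * at
    return alpha0 / (2.0 - alpha0), beta0 / (2.0 - beta0)


def stokes_shape_factors(aspect_ratio: float) -> tuple[float, float]:
    """Oberbeck Stokes-drag correction factors (K_par, K_perp).

    Drag of a prolate spheroid in creeping flow is ``6 pi mu b K U`` with
    ``b`` the semi-major axis; both factors tend to 1 in the sphere limit.
    """
    q = aspect_ratio
    if q < 1.0 + 1e-9:
        return 1.0, 1.0
    e = math.sqrt(1.0 - 1.0 / (q * q))
    L = math.log((1.0 + e) / (1.0 - e))
    K_par = (8.0 / 3.0) * e**3 / (-2.0 * e + (1.0 + e * e) * L)
    K_perp = (16.0 / 3.0) * e**3 / (2.0 * e + (3.0 * e * e - 1.0) * L)
    return K_par, K_perp


def stokes_torque_ratios(aspect_ratio: float) -> tuple[float, float]:
    """Creeping-flow torque of a prolate spheroid over that of the
    equal-volume sphere, for rotation about the symmetry axis (par) and a
    transverse axis (perp); both tend to 1 in the sphere limit."""
    q = aspect_ratio
    if q < 1.0 + 1e-9:
        return 1.0, 1.0
    e = math.sqrt(1.0 - 1.0 / (q * q))
    L = math.log((1.0 + e) / (1.0 - e))
    # Chwang & Wu Stokes torques, normalized by 8 pi mu r_e^3 with
    # r_e^3 = a^2 b = b^3 (1 - e^2).
    T_par = (32.0 / 3.0) * e**3 * (1.0 - e * e) / (2.0 * e - (1.0 - e * e) * L)
    T_perp = (32.0 / 3.0) * e**3 * (2.0 - e * e) / (-2.0 * e + (1.0 + e * e) * L)
    norm = 8.0 * (1.0 - e * e)
    return T_par / norm, T_perp / norm


def _clamped(re: float, lo: float = 1e-2, hi: float = 1e4) -> float:
    return min(max(re, lo), hi)


def default_coefficients(body: BodyProperties | None = None,
                         C_inf: float = 1.95, alpha: float = 10.0) -> CoefficientModel:
    """Default intermediate-Re coefficient correlations for a prolate spheroid.

    * plate: ``C_A = C_inf + alpha/sqrt(Re_p)`` (normal flat plate,
      quasi-steady);
    * body drag: Oberbeck shape factors times the Schiller–Naumann
      finite-Re multiplier, exact in the Stokes and sphere limits;
    * added mass: Lamb's closed forms;
    * rotation: Dennis–Singh–Ingham rotating-sphere correlation
      ``6.45/sqrt(Re) + 32.1/Re`` scaled by the creeping-flow
      spheroid/sphere torque ratio.

    Reynolds numbers are clamped to [1e-2, 1e4] before evaluation.
    """
    if body is None:
        from .geometry import Morphometry, build_body
        body = build_body(Morphometry())
    q = body.aspect_ratio
    K_par, K_perp = stokes_shape_factors(q)
    Cm_par, Cm_perp = prolate_added_mass(q)
    R_par, R_perp = stokes_torque_ratios(q)
    # Stokes prefactors for Eq-8-style coefficients referenced to the
    # equivalent diameter Reynolds number and the axial/lateral areas.
    A_par = 12.0 * body.b * K_par * body.d_e / (body.a * body.a)
    A_perp = 12.0 * K_perp * body.d_e / body.a

    def C_A(re_p: float) -> float:
        return C_inf + alpha / math.sqrt(_clamped(re_p))

    def _sn(re: float) -> float:
        return 1.0 + 0.15 * _clamped(re) ** 0.687

    def C_B_par(re: float) -> float:
        return A_par / _clamped(re) * _sn(re)

    def C_B_perp(re: float) -> float:
        return A_perp / _clamped(re) * _sn(re)

    def _cr_sphere(re: float) -> float:
        re = _clamped(re)
        return 6.45 / math.sqrt(re) + 32.1 / re

    def C_R_par(re: float) -> float:
        return R_par * _cr_sphere(re)

    def C_R_perp(re: float) -> float:
        return R_perp * _cr_sphere(re)

    params = dict(
        CA_inf=C_inf, CA_alpha=alpha,
        A_par=A_par, A_perp=A_perp, sn_c1=0.15, sn_c2=0.687,
        Cm_par=Cm_par, Cm_perp=Cm_perp,
        CR_par=R_par, CR_perp=R_perp,
        re_lo=1e-2, re_hi=1e4,
    )
    return CoefficientModel(
        name="default-reconstruction",
        C_A=C_A, C_B_par=C_B_par, C_B_perp=C_B_perp,
        C_m_par=Cm_par, C_m_perp=Cm_perp,
        C_R_par=C_R_par, C_R_perp=C_R_perp,
        params=params,
    )


def _check_finite(*arrays) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite value in hydrodynamic input")


def ctene_force(placement: CtenePlacement, state: PlateState, body_vel: np.ndarray,
                R: np.ndarray, fluid: FluidProperties, coeffs: CoefficientModel) -> np.ndarray:
    """Propulsive force of a single ctene in the global frame.

    The force is the negative of the plate's quasi-steady drag: magnitude
    set by the squared relative speed |V_body + u| and the instantaneous
    flow-normal area ``w * y_A``, directed opposite the plate velocity u.
    Plates with zero tip speed contribute nothing.
    """
    _check_finite(body_vel)
    if state.x_A_dot == 0.0:
        return np.zeros(3)
    u = plate_velocity_global(state, R, placement)
    rel = np.asarray(body_vel, dtype=float) + u
    speed_plate = abs(state.x_A_dot)
    re_p = speed_plate * state.y_A / fluid.nu
    C_A = coeffs.C_A(re_p)
    mag = fluid.rho * state.w / 2.0 * state.y_A * C_A * float(rel @ rel)
    return -mag * u / speed_plate


def row_force(row: Sequence[CtenePlacement], states: Sequence[PlateState],
              body_vel: np.ndarray, R: np.ndarray,
              fluid: FluidProperties, coeffs: CoefficientModel) -> np.ndarray:
    """Propulsive force of one comb row (global frame): sum over its plates."""
    if len(row) != len(states):
        raise ValueError("one PlateState required per placement")
    F = np.zeros(3)
    for placement, state in zip(row, states):
        F += ctene_force(placement, state, body_vel, R, fluid, coeffs)
    return F


def net_force(row_forces: Sequence[np.ndarray]) -> np.ndarray:
    """Net propulsive force: vector sum over the comb rows."""
    return np.sum(np.asarray(row_forces, dtype=float), axis=0)


def propulsive_torque(placements: Sequence[CtenePlacement],
                      forces_global: Sequence[np.ndarray], R: np.ndarray) -> np.ndarray:
    """Net propulsive torque about the centroid, body frame.

    Each global ctene force is rotated into the body frame before crossing
    with the ctene position vector.
    """
    T = np.zeros(3)
    for placement, F in zip(placements, forces_global):
        T += np.cross(placement.r_prime, R @ np.asarray(F, dtype=float))
    return T


def body_drag(body_vel: np.ndarray, R: np.ndarray, body: BodyProperties,
              fluid: FluidProperties, coeffs: CoefficientModel) -> np.ndarray:
    """Quadratic spheroid drag (global frame), component-wise in the body frame.

    Longitudinal component uses area ``pi a^2`` and C_B_par, lateral
    components ``pi a b`` and C_B_perp; each component opposes its own
    body-frame velocity component (signed square law), so drag power is
    never positive.
    """
    v = np.asarray(body_vel, dtype=float)
    _check_finite(v)
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        return np.zeros(3)
    re = speed * body.d_e / fluid.nu
    vb = R @ v
    areas = np.array([math.pi * body.a**2, math.pi * body.a * body.b,
                      math.pi * body.a * body.b])
    cs = np.array([coeffs.C_B_par(re), coeffs.C_B_perp(re), coeffs.C_B_perp(re)])
    Fb = -0.5 * fluid.rho * areas * cs * np.abs(vb) * vb
    return R.T @ Fb


def added_mass_force(body_acc: np.ndarray, R: np.ndarray, body: BodyProperties,
                     fluid: FluidProperties, coeffs: CoefficientModel) -> np.ndarray:
    """Acceleration-reaction force (global frame): ``-rho V diag(Cm) a'``."""
    acc = np.asarray(body_acc, dtype=float)
    _check_finite(acc)
    ab = R @ acc
    cm = np.array([coeffs.C_m_par, coeffs.C_m_perp, coeffs.C_m_perp])
    return R.T @ (-fluid.rho * body.V * cm * ab)


def opposing_torque(omega_body: np.ndarray, body: BodyProperties,
                    fluid: FluidProperties, coeffs: CoefficientModel) -> np.ndarray:
    """Resistive torque on the rotating spheroid (body frame).

    Signed square law per body axis with the rotation-torque coefficients
    evaluated at the per-axis rotational Reynolds number
    ``|w_i| (d_e/2)^2 / nu``.
    """
    w = np.asarray(omega_body, dtype=float)
    _check_finite(w)
    r_e = body.d_e / 2.0
    T = np.zeros(3)
    for i, (wi, cr) in enumerate(zip(
            w, (coeffs.C_R_par, coeffs.C_R_perp, coeffs.C_R_perp))):
        if wi == 0.0:
            continue
        re_rot = abs(wi) * r_e * r_e / fluid.nu
        T[i] = -0.5 * fluid.rho * r_e**5 * math.copysign(cr(re_rot) * wi * wi, wi)
    return T
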