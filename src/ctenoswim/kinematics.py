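"""Prescribed oscillating-plate (ctene) kinematics.

Each ctene is an oscillating flat plate of time-varying length whose tip
traces a closed ellipse once per beat cycle.  The ellipse is centred at
``(0, l*(1 - Sa/2))`` with horizontal semi-axis ``a_x = l*sin(Phi/2)`` and
vertical semi-axis ``a_y = l*Sa/2``, so the plate reaches full extension
``y_A = l`` at mid power stroke, the swept amplitude is ``Phi``, and the
enclosed tip-path area over its practical maximum (the half-ellipse of axes
``a_x`` × ``l/2`` inscribed in the reach half-circle) equals the spatial
asymmetry ``Sa`` exactly.

Temporal asymmetry: the ellipse parameter angle advances at a constant rate
within each half-cycle — the upper (power, extended) half is traversed in
``t_p = (1-Ta)/(2f)`` and the lower (recovery, contracted) half in
``t_r = (1+Ta)/(2f)``.

Sign convention: the tangential coordinate ``x_A`` is positive oral-ward
along the local meridian tangent.  With ``direction=+1`` (forward swimming)
the power stroke sweeps the tip aboral-ward (``x_A`` decreasing), producing
oral-ward thrust; ``direction=-1`` mirrors the path horizontally.

Metachrony: plate ``k`` (1 = most aboral) is dephased by ``(k-1)*P_L`` beat
cycles, keyed so the metachronal wave travels opposite to the power stroke
(antiplectic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BeatParams", "PlateState", "tip_state", "phase_offset", "plate_velocity_global"]


@dataclass(frozen=True)
class BeatParams:
    """Five-parameter beat-cycle control set plus stroke direction.

    Defaults are the representative values for *B. vitrea*: stroke amplitude
    112°, phase lag 13.2% of the period, temporal and spatial asymmetry 0.3.
    """

    f: float = 30.0       # beat frequency (Hz)
    Phi: float = 112.0    # stroke amplitude (deg)
    Ta: float = 0.3       # temporal asymmetry (t_r - t_p)/(t_r + t_p)
    Sa: float = 0.3       # spatial asymmetry A_e/A_o
    P_L: float = 0.132    # phase lag, fraction of the period
    direction: int = 1    # +1 forward power stroke (aboral sweep), -1 reversed

    def __post_init__(self) -> None:
        if self.f < 0 or not math.isfinite(self.f):
            raise ValueError("f must be >= 0 and finite")
        if not (0.0 < self.Phi < 180.0):
            raise ValueError("Phi must be in (0, 180) degrees")
        if not (-1.0 < self.Ta < 1.0):
            raise ValueError("Ta must be in (-1, 1)")
        if not (0.0 < self.Sa <= 1.0):
            raise ValueError("Sa must be in (0, 1]")
        if not (0.0 <= self.P_L < 1.0):
            raise ValueError("P_L must be in [0, 1)")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")

    @property
    def T(self) -> float:
        """Beat period (s); inf for an inactive row."""
        return 1.0 / self.f if self.f > 0 else math.inf

    @property
    def t_p(self) -> float:
        """Power-stroke duration (s)."""
        return (1.0 - self.Ta) / (2.0 * self.f) if self.f > 0 else math.inf

    @property
    def t_r(self) -> float:
        """Recovery-stroke duration (s)."""
        return (1.0 + self.Ta) / (2.0 * self.f) if self.f > 0 else math.inf

    @property
    def tau(self) -> float:
        """Phase-lag time between adjacent ctenes (s)."""
        return self.P_L / self.f if self.f > 0 else 0.0


@dataclass(frozen=True)
class PlateState:
    """Instantaneous plate tip state in the local stroke plane."""

    x_A: float       # tip tangential coordinate (m), oral-ward positive
    y_A: float       # instantaneous plate length (m)
    x_A_dot: float   # tangential tip speed (m/s)
    y_A_dot: float   # plate length rate (m/s)
    w: float         # plate width (m), 0.5*l


def _phase_to_eta(cycle_frac: np.ndarray, Ta: float):
    """Ellipse parameter angle eta and its rate (per cycle) from cycle fraction.

    Upper half (power) eta in [0, pi) during the first (1-Ta)/2 of the
    cycle; lower half (recovery) during the rest.
    """
    fp = (1.0 - Ta) / 2.0
    fr = (1.0 + Ta) / 2.0
    power = cycle_frac < fp
    eta = np.where(
        power,
        math.pi * cycle_frac / fp,
        math.pi + math.pi * (cycle_frac - fp) / fr,
    )
    deta_dfrac = np.where(power, math.pi / fp, math.pi / fr)
    return eta, deta_dfrac


def tip_state(t, params: BeatParams, l: float, phase_offset: float = 0.0):
    """Plate tip state at time(s) ``t`` for a ctene of length ``l``.

    ``phase_offset`` (seconds) is the metachronal dephasing returned by
    :func:`phase_offset`; the wave is keyed antiplectic, so the effective
    time is ``t - direction*phase_offset``.  For ``f = 0`` the plate is
    static at full extension (inactive row).  Accepts scalar or array ``t``;
    returns a :class:`PlateState` with matching scalar/array fields.
    """
    if l <= 0:
        raise ValueError("ctene length l must be positive")
    t = np.asarray(t, dtype=float)
    w = 0.5 * l
    if params.f == 0:
        z = np.zeros_like(t)
        return PlateState(x_A=z + 0.0, y_A=z + l, x_A_dot=z, y_A_dot=z, w=w)

    a_x = l * math.sin(math.radians(params.Phi) / 2.0)
    a_y = l * params.Sa / 2.0
    c_y = l * (1.0 - params.Sa / 2.0)

    t_eff = t - params.direction * phase_offset
    cycle_frac = np.mod(t_eff * params.f, 1.0)
    eta, deta_dfrac = _phase_to_eta(cycle_frac, params.Ta)
    eta_dot = deta_dfrac * params.f

    x = params.direction * a_x * np.cos(eta)
    y = c_y + a_y * np.sin(eta)
    x_dot = -params.direction * a_x * np.sin(eta) * eta_dot
    y_dot = a_y * np.cos(eta) * eta_dot
    if t.ndim == 0:
        return PlateState(float(x), float(y), float(x_dot), float(y_dot), w)
    return PlateState(x, y, x_dot, y_dot, w)


def phase_offset(k: int, params: BeatParams) -> float:
    """Metachronal dephasing time ``(k-1)*P_L/f`` of the k-th ctene (k >= 1)."""
    if k < 1:
        raise ValueError("ctene index k is 1-based")
    if params.f == 0:
        return 0.0
    return (k - 1) * params.P_L / params.f


def plate_velocity_global(state: PlateState, R: np.ndarray, placement) -> np.ndarray:
    """Plate velocity in the global frame.

    The plate oscillates along the local meridian tangent; its body-frame
    unit direction is ``[cos lam, sin lam cos eps, sin lam sin eps]`` and the
    global velocity is ``R.T @ (x_A_dot * direction_vector)``.
    """
    lam, eps = placement.lam, placement.eps
    d = np.array([
        math.cos(lam),
        math.sin(lam) * math.cos(eps),
        math.sin(lam) * math.sin(eps),
    ])
    return R.T @ (state.x_A_dot * d)
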