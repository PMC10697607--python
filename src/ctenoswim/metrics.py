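"""Maneuverability and agility metrics, trajectory canonicalization and
motor-volume (reachable-space) estimation.

Maneuverability is the mean radius of curvature of the swimming trajectory
normalized by body length (R/L̄; smaller = tighter turns), agility the mean
translational speed in body lengths per second (V̄).  Radii are computed
from smoothed position derivatives as ``R = |v|^3 / |v x a|``; positions
are smoothed by a moving average spanning one beat period to remove
intra-beat wobble, the analysis window excludes the first two beat cycles
(startup transient), and per-sample R/L is clamped at 10, the conventional
"straight swimming" cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .geometry import build_rotation_matrix

__all__ = [
    "ManeuverMetrics",
    "MotorVolumeGrid",
    "mean_speed",
    "curvature_radius",
    "mean_curvature_ratio",
    "maneuver_metrics",
    "build_map",
    "canonicalize",
    "canonicalize_landmarks",
    "motor_volume",
    "reynolds",
]

RL_CLAMP = 10.0


@dataclass(frozen=True)
class ManeuverMetrics:
    """Mean-speed / mean-curvature summary of one maneuver."""

    V_bar: float          # mean speed (body lengths / s)
    RL_bar: float         # mean normalized radius of curvature (-)
    straight_flag: bool   # RL_bar clamped at the straight-swimming cutoff
    window: tuple[float, float]   # analyzed time interval (s)


@dataclass(frozen=True)
class MotorVolumeGrid:
    """Voxelized occupancy of the space swept by the body."""

    voxel: float              # voxel edge length (m)
    origin: np.ndarray        # grid corner (m)
    shape: tuple[int, int, int]
    occupied: np.ndarray      # flat indices of occupied voxels
    volume: float             # occupied voxel count * voxel^3 (m^3)


def _window_slice(t: np.ndarray, window: tuple[float, float] | None):
    if window is None:
        return slice(None)
    lo, hi = window
    i0 = int(np.searchsorted(t, lo, side="left"))
    i1 = int(np.searchsorted(t, hi, side="right"))
    return slice(i0, i1)


def _smooth_positions(X: np.ndarray, dt: float, beat_period: float | None):
    if beat_period is None or beat_period <= 0 or dt <= 0:
        return X
    win = max(1, int(round(beat_period / dt)))
    if win < 2:
        return X
    return uniform_filter1d(X, size=win, axis=0, mode="nearest")


def mean_speed(traj, L: float, window: tuple[float, float] | None = None) -> float:
    """Mean speed over the window, body lengths per second.

    Path length is accumulated from sample-to-sample chords.
    """
    sl = _window_slice(traj.t, window)
    t = traj.t[sl]
    X = traj.X[sl]
    if len(t) < 2:
        raise ValueError("need at least 2 samples for a speed estimate")
    path = float(np.sum(np.linalg.norm(np.diff(X, axis=0), axis=1)))
    elapsed = float(t[-1] - t[0])
    if elapsed <= 0:
        raise ValueError("degenerate time window")
    return path / elapsed / L


def _rl_samples(traj, L: float, window, beat_period, clamp: float):
    sl = _window_slice(traj.t, window)
    t = traj.t[sl]
    if len(t) < 3:
        raise ValueError("need at least 3 samples for a curvature estimate")
    X = _smooth_positions(traj.X, traj.dt, beat_period)[sl]
    v = np.gradient(X, t, axis=0)
    a = np.gradient(v, t, axis=0)
    speed = np.linalg.norm(v, axis=1)
    cross = np.linalg.norm(np.cross(v, a), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = speed**3 / cross
    rl = R / L
    if len(rl) > 8:  # drop one-sided-difference edge samples
        rl = rl[2:-2]
    rl[~np.isfinite(rl)] = clamp
    return np.minimum(rl, clamp)


def mean_curvature_ratio(traj, L: float, window=None, beat_period=None,
                         clamp: float = RL_CLAMP) -> float:
    """Mean of the per-sample clamped R/L over the window."""
    return float(np.mean(_rl_samples(traj, L, window, beat_period, clamp)))


def curvature_radius(traj, L: float, clamp: float = RL_CLAMP,
                     window=None, beat_period=None) -> ManeuverMetrics:
    """Normalized mean radius of curvature with the straight-swimming clamp."""
    rl = mean_curvature_ratio(traj, L, window, beat_period, clamp)
    t = traj.t[_window_slice(traj.t, window)]
    straight = rl >= clamp * (1.0 - 1e-9)
    v = mean_speed(traj, L, window)
    return ManeuverMetrics(V_bar=v, RL_bar=min(rl, clamp),
                           straight_flag=bool(straight),
                           window=(float(t[0]), float(t[-1])))


def maneuver_metrics(traj, L: float, beat_period: float | None = None,
                     window: tuple[float, float] | None = None,
                     skip_cycles: float = 2.0) -> ManeuverMetrics:
    """V̄ and R/L̄ of a trajectory.

    If no explicit window is given, the first ``skip_cycles`` beat periods
    are excluded as startup transient.
    """
    if window is None:
        t0 = float(traj.t[0])
        if beat_period is not None and beat_period > 0:
            t0 += skip_cycles * beat_period
        window = (t0, float(traj.t[-1]))
    return curvature_radius(traj, L, window=window, beat_period=beat_period)


def build_map(results) -> "pandas.DataFrame":  # noqa: F821
    """Assemble a Maneuverability–Agility table.

    ``results`` is an iterable of ``(program, ManeuverMetrics)`` or of dicts
    already carrying mode/f_out/f_in.  Returns a DataFrame with one row per
    maneuver and columns mode, f_out, f_in, direction, V_bar, RL_bar,
    straight.
    """
    import pandas as pd
    rows = []
    for item in results:
        if isinstance(item, dict):
            rows.append(item)
            continue
        program, mm = item
        freqs = sorted(set(f for f in program.freqs if f > 0), reverse=True)
        f_out = freqs[0] if freqs else 0.0
        f_in = freqs[1] if len(freqs) > 1 else 0.0
        rows.append(dict(mode=program.mode_label, f_out=f_out, f_in=f_in,
                         direction=program.direction, V_bar=mm.V_bar,
                         RL_bar=mm.RL_bar, straight=mm.straight_flag))
    if not rows:
        raise ValueError("no results to tabulate")
    return pd.DataFrame(rows)


def _pose_from_landmarks(apical, bulb1, bulb2):
    """Rigid pose (origin, global->body rotation) from the three landmarks."""
    apical = np.asarray(apical, float)
    mid = 0.5 * (np.asarray(bulb1, float) + np.asarray(bulb2, float))
    xhat = mid - apical
    nx = np.linalg.norm(xhat)
    baxis = np.asarray(bulb1, float) - np.asarray(bulb2, float)
    if nx < 1e-12 or np.linalg.norm(baxis) < 1e-12:
        raise ValueError("degenerate landmark configuration")
    xhat = xhat / nx
    yhat = baxis - (baxis @ xhat) * xhat
    ny = np.linalg.norm(yhat)
    if ny < 1e-9 * np.linalg.norm(baxis):
        raise ValueError("landmarks nearly collinear: tentacular axis "
                         "parallel to the body axis")
    yhat = yhat / ny
    zhat = np.cross(xhat, yhat)
    R = np.vstack([xhat, yhat, zhat])  # rows: body axes in global coords
    return mid, R


def canonicalize(traj):
    """Rigidly move a trajectory to the canonical start pose.

    At the first sample the body centroid sits at the origin, the oral axis
    points along +x and the tentacular plane coincides with the x–y plane.
    Positive x is forward swimming.  Idempotent for already-canonical input.
    """
    from .dynamics import Trajectory
    psi0, th0, ph0 = traj.angles[0]
    R0 = build_rotation_matrix(psi0, th0, ph0)
    X0 = traj.X[0]
    Xc = (traj.X - X0) @ R0.T
    Vc = traj.V @ R0.T
    angles = np.empty_like(traj.angles)
    for i in range(len(traj.t)):
        Ri = build_rotation_matrix(*traj.angles[i]) @ R0.T
        sth = float(np.clip(-Ri[0, 2], -1.0, 1.0))
        angles[i] = (math.atan2(Ri[0, 1], Ri[0, 0]), math.asin(sth),
                     math.atan2(Ri[1, 2], Ri[2, 2]))
    return Trajectory(t=traj.t.copy(), X=Xc, V=Vc, angles=angles,
                      omega=traj.omega.copy(), dt=traj.dt,
                      meta={**traj.meta, "canonical": True})


def canonicalize_landmarks(track):
    """Canonicalize a landmark track; returns the bulb-midpoint trajectory.

    The initial pose is derived from the apical organ and the two
    tentacular bulbs; the returned Trajectory follows the bulb midpoint,
    with orientation angles derived from the per-frame landmark pose.
    """
    from .dynamics import Trajectory
    origin, R0 = _pose_from_landmarks(track.apical[0], track.bulb1[0],
                                      track.bulb2[0])
    n = len(track.t)
    X = np.empty((n, 3))
    angles = np.empty((n, 3))
    for i in range(n):
        mid_i, Ri = _pose_from_landmarks(track.apical[i], track.bulb1[i],
                                         track.bulb2[i])
        X[i] = R0 @ (mid_i - origin)
        Rrel = Ri @ R0.T
        sth = float(np.clip(-Rrel[0, 2], -1.0, 1.0))
        angles[i] = (math.atan2(Rrel[0, 1], Rrel[0, 0]), math.asin(sth),
                     math.atan2(Rrel[1, 2], Rrel[2, 2]))
    t = np.asarray(track.t, float)
    dt = float(t[1] - t[0]) if n > 1 else 0.0
    V = np.gradient(X, t, axis=0) if n > 2 else np.zeros_like(X)
    return Trajectory(t=t, X=X, V=V, angles=angles, omega=np.zeros((n, 3)),
                      dt=dt, meta={"source": "landmarks", "canonical": True})


def motor_volume(trajs, bodies, voxel: float,
                 pose_stride: int = 1) -> MotorVolumeGrid:
    """Voxelized union of the body spheroid over all trajectory samples.

    ``bodies`` is one BodyProperties per trajectory (or a single one shared
    by all).  A warning is emitted when the voxel is coarser than half the
    semi-minor axis.
    """
    import warnings
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    if not isinstance(bodies, (list, tuple)):
        bodies = [bodies] * len(trajs)
    if len(bodies) != len(trajs):
        raise ValueError("need one body per trajectory")
    if any(voxel > bd.a / 2 for bd in bodies):
        warnings.warn("voxel coarser than a/2; volume estimate will be crude")

    bmax = max(bd.b for bd in bodies)
    lo = np.min([traj.X.min(axis=0) for traj in trajs], axis=0) - bmax - voxel
    hi = np.max([traj.X.max(axis=0) for traj in trajs], axis=0) + bmax + voxel
    shape = tuple(int(math.ceil((hi[i] - lo[i]) / voxel)) for i in range(3))
    occ = np.zeros(shape, dtype=bool)
    axes = [lo[i] + (np.arange(shape[i]) + 0.5) * voxel for i in range(3)]

    for traj, bd in zip(trajs, bodies):
        for i in range(0, len(traj.t), pose_stride):
            c = traj.X[i]
            R = build_rotation_matrix(*traj.angles[i])
            i0 = [np.searchsorted(axes[j], c[j] - bd.b) for j in range(3)]
            i1 = [np.searchsorted(axes[j], c[j] + bd.b) for j in range(3)]
            sub = np.meshgrid(*(axes[j][i0[j]:i1[j]] for j in range(3)),
                              indexing="ij")
            q = np.stack([s - c[j] for j, s in enumerate(sub)], axis=-1)
            qb = q @ R.T  # body-frame coordinates
            inside = ((qb[..., 0] / bd.b) ** 2
                      + (qb[..., 1] ** 2 + qb[..., 2] ** 2) / bd.a**2) <= 1.0
            occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= inside
    count = int(occ.sum())
    return MotorVolumeGrid(voxel=voxel, origin=lo, shape=shape,
                           occupied=np.flatnonzero(occ),
                           volume=count * voxel**3)


def reynolds(U: float, L: float, f: float, l: float, nu: float):
    """Body and appendage Reynolds numbers: ``U L / nu`` and ``2 pi f l^2 / nu``."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    return U * L / nu, 2.0 * math.pi * f * l * l / nu
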