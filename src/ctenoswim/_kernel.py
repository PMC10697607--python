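"""Fixed-step RK4 integrator core for the self-propelled spheroid.

The state is ``[X(3), V(3), R(9 row-major), omega_body(3)]``.  Orientation
is integrated as the full rotation matrix via ``Rdot = -[omega']_x R``
(re-orthonormalized every step) rather than as Euler angles: turning
maneuvers routinely pitch the body axis through ±90 deg, where the
yaw–pitch–roll rate map is singular.  Euler angles are extracted only for
output.

All beat-cycle, placement and coefficient constants arrive as plain float
arrays so the hot loop can be jitted.  If numba is unavailable the same
code runs as pure Python (slowly).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# indices into the scalar-parameter vector
(P_RHO, P_NU, P_W, P_AX, P_AY, P_CY, P_TA, P_DIR,
 P_A, P_B, P_M, P_VOL, P_DE, P_I1, P_I2,
 P_CA_INF, P_CA_ALPHA, P_A_PAR, P_A_PERP, P_SN1, P_SN2,
 P_CM_PAR, P_CM_PERP, P_CR_PAR, P_CR_PERP, P_RE_LO, P_RE_HI) = range(27)

N_PARAMS = 27


@njit(cache=True)
def _rhs(t, y, rp, dvec, fr, ph0, p, dy):
    """Time derivative of the 18-component state, written into ``dy``."""
    # unpack
    vx, vy, vz = y[3], y[4], y[5]
    R00, R01, R02 = y[6], y[7], y[8]
    R10, R11, R12 = y[9], y[10], y[11]
    R20, R21, R22 = y[12], y[13], y[14]
    wx, wy, wz = y[15], y[16], y[17]

    rho = p[P_RHO]
    nu = p[P_NU]
    re_lo, re_hi = p[P_RE_LO], p[P_RE_HI]

    # body-frame velocity
    vb0 = R00 * vx + R01 * vy + R02 * vz
    vb1 = R10 * vx + R11 * vy + R12 * vz
    vb2 = R20 * vx + R21 * vy + R22 * vz

    # --- propulsive force and torque (body frame) ---
    a_x, a_y, c_y = p[P_AX], p[P_AY], p[P_CY]
    Ta, dirn = p[P_TA], p[P_DIR]
    fp = (1.0 - Ta) / 2.0
    half = rho * p[P_W] / 2.0

    Fb0 = Fb1 = Fb2 = 0.0
    Tb0 = Tb1 = Tb2 = 0.0
    n_c = fr.shape[0]
    for i in range(n_c):
        f = fr[i]
        if f <= 0.0:
            continue
        cyc = ph0[i] + f * t
        frac = cyc - np.floor(cyc)
        if frac < fp:
            eta = np.pi * frac / fp
            eta_dot = np.pi * f / fp
        else:
            eta = np.pi + np.pi * (frac - fp) / (1.0 - fp)
            eta_dot = np.pi * f / (1.0 - fp)
        se = np.sin(eta)
        xdot = -dirn * a_x * se * eta_dot
        if xdot == 0.0:
            continue
        yA = c_y + a_y * se
        sp = abs(xdot)
        re_p = sp * yA / nu
        if re_p < re_lo:
            re_p = re_lo
        elif re_p > re_hi:
            re_p = re_hi
        CA = p[P_CA_INF] + p[P_CA_ALPHA] / np.sqrt(re_p)
        d0, d1, d2 = dvec[i, 0], dvec[i, 1], dvec[i, 2]
        r0 = vb0 + xdot * d0
        r1 = vb1 + xdot * d1
        r2 = vb2 + xdot * d2
        rel2 = r0 * r0 + r1 * r1 + r2 * r2
        s = 1.0 if xdot > 0.0 else -1.0
        mag = half * yA * CA * rel2 * s
        fc0 = -mag * d0
        fc1 = -mag * d1
        fc2 = -mag * d2
        Fb0 += fc0
        Fb1 += fc1
        Fb2 += fc2
        Tb0 += rp[i, 1] * fc2 - rp[i, 2] * fc1
        Tb1 += rp[i, 2] * fc0 - rp[i, 0] * fc2
        Tb2 += rp[i, 0] * fc1 - rp[i, 1] * fc0

    # --- body drag (body frame) ---
    speed = np.sqrt(vx * vx + vy * vy + vz * vz)
    if speed > 0.0:
        re_b = speed * p[P_DE] / nu
        if re_b < re_lo:
            re_b = re_lo
        elif re_b > re_hi:
            re_b = re_hi
        sn = 1.0 + p[P_SN1] * re_b ** p[P_SN2]
        cb_par = p[P_A_PAR] / re_b * sn
        cb_perp = p[P_A_PERP] / re_b * sn
        area_par = np.pi * p[P_A] * p[P_A]
        area_perp = np.pi * p[P_A] * p[P_B]
        Fb0 += -0.5 * rho * area_par * cb_par * abs(vb0) * vb0
        Fb1 += -0.5 * rho * area_perp * cb_perp * abs(vb1) * vb1
        Fb2 += -0.5 * rho * area_perp * cb_perp * abs(vb2) * vb2

    # total force in the global frame
    Fg0 = R00 * Fb0 + R10 * Fb1 + R20 * Fb2
    Fg1 = R01 * Fb0 + R11 * Fb1 + R21 * Fb2
    Fg2 = R02 * Fb0 + R12 * Fb1 + R22 * Fb2

    # --- effective mass matrix (added mass on the left-hand side) ---
    # M = m I + rho V R^T diag(Cm) R  (symmetric)
    m = p[P_M]
    cpar = rho * p[P_VOL] * p[P_CM_PAR]
    cperp = rho * p[P_VOL] * p[P_CM_PERP]
    M00 = m + cpar * R00 * R00 + cperp * (R10 * R10 + R20 * R20)
    M11 = m + cpar * R01 * R01 + cperp * (R11 * R11 + R21 * R21)
    M22 = m + cpar * R02 * R02 + cperp * (R12 * R12 + R22 * R22)
    M01 = cpar * R00 * R01 + cperp * (R10 * R11 + R20 * R21)
    M02 = cpar * R00 * R02 + cperp * (R10 * R12 + R20 * R22)
    M12 = cpar * R01 * R02 + cperp * (R11 * R12 + R21 * R22)
    # Cramer solve M acc = Fg
    det = (M00 * (M11 * M22 - M12 * M12)
           - M01 * (M01 * M22 - M12 * M02)
           + M02 * (M01 * M12 - M11 * M02))
    a0 = (Fg0 * (M11 * M22 - M12 * M12)
          - M01 * (Fg1 * M22 - M12 * Fg2)
          + M02 * (Fg1 * M12 - M11 * Fg2)) / det
    a1 = (M00 * (Fg1 * M22 - M12 * Fg2)
          - Fg0 * (M01 * M22 - M12 * M02)
          + M02 * (M01 * Fg2 - Fg1 * M02)) / det
    a2 = (M00 * (M11 * Fg2 - Fg1 * M12)
          - M01 * (M01 * Fg2 - Fg1 * M02)
          + Fg0 * (M01 * M12 - M11 * M02)) / det

    # --- opposing torque (body frame) ---
    r_e = p[P_DE] / 2.0
    re_fac = r_e * r_e / nu
    tq = 0.5 * rho * r_e ** 5
    for comp in range(3):
        wi = y[15 + comp]
        if wi == 0.0:
            continue
        re_r = abs(wi) * re_fac
        if re_r < re_lo:
            re_r = re_lo
        elif re_r > re_hi:
            re_r = re_hi
        cr0 = 6.45 / np.sqrt(re_r) + 32.1 / re_r
        cr = cr0 * (p[P_CR_PAR] if comp == 0 else p[P_CR_PERP])
        topp = -tq * cr * wi * abs(wi)
        if comp == 0:
            Tb0 += topp
        elif comp == 1:
            Tb1 += topp
        else:
            Tb2 += topp

    # --- rotational dynamics: I w' = T - w x (I w) ---
    I1, I2 = p[P_I1], p[P_I2]
    gx = wy * (I2 * wz) - wz * (I2 * wy)   # = 0 for I2 == I3
    gy = wz * (I1 * wx) - wx * (I2 * wz)
    gz = wx * (I2 * wy) - wy * (I1 * wx)
    dwx = (Tb0 - gx) / I1
    dwy = (Tb1 - gy) / I2
    dwz = (Tb2 - gz) / I2

    # --- kinematics ---
    dy[0], dy[1], dy[2] = vx, vy, vz
    dy[3], dy[4], dy[5] = a0, a1, a2
    # Rdot = -[w']_x R
    dy[6] = -(wy * R20 - wz * R10)
    dy[7] = -(wy * R21 - wz * R11)
    dy[8] = -(wy * R22 - wz * R12)
    dy[9] = -(wz * R00 - wx * R20)
    dy[10] = -(wz * R01 - wx * R21)
    dy[11] = -(wz * R02 - wx * R22)
    dy[12] = -(wx * R10 - wy * R00)
    dy[13] = -(wx * R11 - wy * R01)
    dy[14] = -(wx * R12 - wy * R02)
    dy[15], dy[16], dy[17] = dwx, dwy, dwz


@njit(cache=True)
def _orthonormalize(y):
    """Gram–Schmidt on the rows of the stored rotation matrix."""
    n0 = np.sqrt(y[6] ** 2 + y[7] ** 2 + y[8] ** 2)
    y[6] /= n0
    y[7] /= n0
    y[8] /= n0
    d = y[9] * y[6] + y[10] * y[7] + y[11] * y[8]
    y[9] -= d * y[6]
    y[10] -= d * y[7]
    y[11] -= d * y[8]
    n1 = np.sqrt(y[9] ** 2 + y[10] ** 2 + y[11] ** 2)
    y[9] /= n1
    y[10] /= n1
    y[11] /= n1
    y[12] = y[7] * y[11] - y[8] * y[10]
    y[13] = y[8] * y[9] - y[6] * y[11]
    y[14] = y[6] * y[10] - y[7] * y[9]


@njit(cache=True)
def simulate_chunk(y0, t0, dt, n_steps, stride, rp, dvec, fr, ph0, p):
    """Integrate ``n_steps`` RK4 steps from (t0, y0).

    Returns ``(samples, y_end)`` where samples has one row per ``stride``
    steps with columns ``[t, X(3), V(3), psi, theta, phi, omega(3)]``.
    The initial state is not sampled (the caller owns it).
    """
    y = y0.copy()
    k1 = np.empty(18)
    k2 = np.empty(18)
    k3 = np.empty(18)
    k4 = np.empty(18)
    ytmp = np.empty(18)
    n_samp = n_steps // stride
    out = np.empty((n_samp, 13))
    isamp = 0
    t = t0
    for step in range(n_steps):
        _rhs(t, y, rp, dvec, fr, ph0, p, k1)
        for j in range(18):
            ytmp[j] = y[j] + 0.5 * dt * k1[j]
        _rhs(t + 0.5 * dt, ytmp, rp, dvec, fr, ph0, p, k2)
        for j in range(18):
            ytmp[j] = y[j] + 0.5 * dt * k2[j]
        _rhs(t + 0.5 * dt, ytmp, rp, dvec, fr, ph0, p, k3)
        for j in range(18):
            ytmp[j] = y[j] + dt * k3[j]
        _rhs(t + dt, ytmp, rp, dvec, fr, ph0, p, k4)
        for j in range(18):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        _orthonormalize(y)
        t = t0 + (step + 1) * dt
        if (step + 1) % stride == 0:
            out[isamp, 0] = t
            for j in range(6):
                out[isamp, 1 + j] = y[j]
            # Euler angles from R (output only; gimbal ambiguity harmless)
            sth = -y[8]
            if sth > 1.0:
                sth = 1.0
            elif sth < -1.0:
                sth = -1.0
            out[isamp, 7] = np.arctan2(y[7], y[6])        # psi
            out[isamp, 8] = np.arcsin(sth)                # theta
            out[isamp, 9] = np.arctan2(y[11], y[14])      # phi
            out[isamp, 10] = y[15]
            out[isamp, 11] = y[16]
            out[isamp, 12] = y[17]
            isamp += 1
    return out, y


def rhs_reference(t, y, rp, dvec, fr, ph0, p):
    """Pure-Python wrapper around the jitted RHS (for oracle tests)."""
    dy = np.empty(18)
    _rhs(t, np.asarray(y, dtype=float), rp, dvec, fr, ph0, p, dy)
    return dy
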