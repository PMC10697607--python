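"""Self-propelled body dynamics and appendage control strategies.

Translates the observed ctene-row control strategies into per-row beat
frequency programs and integrates the coupled translational/rotational
rigid-body equations.  Rows are controlled in quadrant pairs for the
natural turning modes (each body quadrant holds one sagittal and one
tentacular row sharing a frequency):

* mode 1 — one quadrant pair beats at ``f_out``, the diagonally opposite
  pair at ``f_in``, the remaining four rows are inactive;
* mode 2 — the four rows on one side of the sagittal (or tentacular)
  plane beat at ``f_out``, the other four at ``f_in``;
* mode 3 — six rows at ``f_out``, one quadrant pair at ``f_in``;
* mode 4 — all eight rows at the same frequency (straight swimming).

``enumerate_subsets`` drops the quadrant pairing to explore hypothetical
independent row control (all 255 non-empty row subsets).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .geometry import (Morphometry, BodyProperties, build_body, place_ctenes,
                       quadrant_rows, N_ROWS)
from .hydro import FluidProperties, CoefficientModel, default_coefficients
from .kinematics import BeatParams

__all__ = [
    "RowFrequencyProgram",
    "BodyState",
    "Trajectory",
    "assign_mode",
    "enumerate_sweep",
    "enumerate_subsets",
    "simulate",
    "replay",
    "SWEEP_CONFIGURATIONS",
]

SWEEP_CONFIGURATIONS = ("mode1", "mode2_sagittal", "mode2_tentacular", "mode3")

#: integrator steps per beat period of the fastest active row
STEPS_PER_PERIOD = 200
#: sample every this many integrator steps
SAMPLE_STRIDE = 5
#: trailing window (s) over which the running mean R/L is monitored
STEADY_WINDOW = 2.0
#: relative change between consecutive beat-cycle checks that counts as steady
STEADY_RTOL = 0.01
#: running mean R/L beyond which the run is considered straight swimming
STRAIGHT_RL = 10.0
#: hard cap on simulated time under the steady-state halting policy (s)
MAX_DURATION = 10.0


class IntegrationError(RuntimeError):
    """Solver produced a non-finite state."""


@dataclass(frozen=True)
class RowFrequencyProgram:
    """Constant per-row beat frequencies plus the global stroke direction."""

    freqs: tuple[float, ...]
    direction: int = 1
    mode_label: str = "custom"

    def __post_init__(self) -> None:
        if len(self.freqs) != N_ROWS:
            raise ValueError(f"need {N_ROWS} row frequencies")
        if any(f < 0 or not math.isfinite(f) for f in self.freqs):
            raise ValueError("row frequencies must be >= 0 and finite")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")

    @property
    def f_max(self) -> float:
        return max(self.freqs)

    @property
    def active_rows(self) -> tuple[int, ...]:
        return tuple(i for i, f in enumerate(self.freqs) if f > 0)


@dataclass(frozen=True)
class BodyState:
    """Instantaneous rigid-body state (global-frame position/velocity)."""

    X: np.ndarray
    V: np.ndarray
    angles: np.ndarray       # yaw, pitch, roll (rad)
    omega_body: np.ndarray   # body-frame angular velocity (rad/s)
    t: float


@dataclass
class Trajectory:
    """Uniformly sampled body-state time series."""

    t: np.ndarray
    X: np.ndarray        # (n, 3) position (m)
    V: np.ndarray        # (n, 3) velocity (m/s)
    angles: np.ndarray   # (n, 3) yaw/pitch/roll (rad)
    omega: np.ndarray    # (n, 3) body-frame angular velocity (rad/s)
    dt: float            # sample interval (s)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> BodyState:
        return BodyState(self.X[i], self.V[i], self.angles[i], self.omega[i],
                         float(self.t[i]))

    def to_frame(self):
        """Trajectory as a pandas DataFrame (SI units)."""
        import pandas as pd
        return pd.DataFrame({
            "t": self.t,
            "x": self.X[:, 0], "y": self.X[:, 1], "z": self.X[:, 2],
            "vx": self.V[:, 0], "vy": self.V[:, 1], "vz": self.V[:, 2],
            "psi": self.angles[:, 0], "theta": self.angles[:, 1],
            "phi": self.angles[:, 2],
            "wx": self.omega[:, 0], "wy": self.omega[:, 1],
            "wz": self.omega[:, 2],
        })


def assign_mode(mode: str, f_out: float, f_in: float = 0.0,
                direction: int = 1, quadrant: int = 0) -> RowFrequencyProgram:
    """Per-row frequency program for one of the natural control strategies.

    ``quadrant`` orients the maneuver: for mode 1 it selects the
    ``f_out`` quadrant pair (the diagonally opposite pair gets ``f_in``);
    for mode 2 it selects which side of the splitting plane is fast; for
    mode 3 it selects the slow pair.
    """
    if mode not in SWEEP_CONFIGURATIONS + ("mode4",):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "mode4":
        f_in = f_out
    else:
        if not (f_out > f_in >= 0.0):
            raise ValueError("turning modes require f_out > f_in >= 0")
    quads = quadrant_rows()
    if not 0 <= quadrant < len(quads):
        raise ValueError("quadrant must be 0..3")
    freqs = [0.0] * N_ROWS
    if mode == "mode1":
        # diagonally opposite quadrant: 0<->3, 1<->2
        opposite = 3 - quadrant
        for r in quads[quadrant]:
            freqs[r] = f_out
        for r in quads[opposite]:
            freqs[r] = f_in
    elif mode == "mode2_sagittal":
        # sides of the sagittal plane: quadrants {0,1} (+y) vs {2,3} (-y)
        fast = (0, 1) if quadrant in (0, 1) else (2, 3)
        for q in range(4):
            for r in quads[q]:
                freqs[r] = f_out if q in fast else f_in
    elif mode == "mode2_tentacular":
        # sides of the tentacular plane: quadrants {0,2} (+z) vs {1,3} (-z)
        fast = (0, 2) if quadrant in (0, 2) else (1, 3)
        for q in range(4):
            for r in quads[q]:
                freqs[r] = f_out if q in fast else f_in
    elif mode == "mode3":
        for q in range(4):
            for r in quads[q]:
                freqs[r] = f_in if q == quadrant else f_out
    else:  # mode4
        freqs = [f_out] * N_ROWS
    return RowFrequencyProgram(tuple(freqs), direction=direction, mode_label=mode)


def enumerate_sweep() -> list[tuple[str, float, float]]:
    """The full frequency-sweep grid: 4 turning configurations x 153 pairs.

    ``f_out`` runs 2–34 Hz and ``f_in`` 0–(f_out - 2) Hz, both in 2-Hz
    steps, giving 153 pairs per configuration and 612 runs total.
    """
    pairs = [(float(fo), float(fi))
             for fo in range(2, 36, 2)
             for fi in range(0, fo, 2)]
    return [(cfg, fo, fi) for cfg in SWEEP_CONFIGURATIONS for fo, fi in pairs]


def enumerate_subsets(f: float = 30.0, direction: int = 1) -> list[RowFrequencyProgram]:
    """All 255 non-empty row subsets beating at ``f`` (independent control)."""
    if f <= 0:
        raise ValueError("f must be positive")
    programs = []
    for n_cr in range(1, N_ROWS + 1):
        for subset in itertools.combinations(range(N_ROWS), n_cr):
            freqs = tuple(f if r in subset else 0.0 for r in range(N_ROWS))
            programs.append(RowFrequencyProgram(freqs, direction=direction,
                                                mode_label="subset"))
    return programs


def _build_arrays(program_freqs, morph: Morphometry, beat: BeatParams,
                  body: BodyProperties, fluid: FluidProperties,
                  coeffs: CoefficientModel, direction: int):
    """Pack placements, per-ctene phases and constants for the kernel."""
    placements = place_ctenes(morph)
    n = len(placements)
    rp = np.empty((n, 3))
    dvec = np.empty((n, 3))
    fr = np.empty(n)
    ph0 = np.empty(n)
    for i, pl in enumerate(placements):
        rp[i] = pl.r_prime
        dvec[i] = (math.cos(pl.lam),
                   math.sin(pl.lam) * math.cos(pl.eps),
                   math.sin(pl.lam) * math.sin(pl.eps))
        fr[i] = program_freqs[pl.row_id]
        # antiplectic keying: plate k delayed by direction*(k-1)*P_L cycles
        ph0[i] = -direction * (pl.k - 1) * beat.P_L

    cp = coeffs.params
    if cp is None:
        raise ValueError(
            "simulate() needs a CoefficientModel with kernel params; "
            "use default_coefficients(...) or supply params")
    p = np.zeros(_kernel.N_PARAMS)
    p[_kernel.P_RHO] = fluid.rho
    p[_kernel.P_NU] = fluid.nu
    p[_kernel.P_W] = 0.5 * morph.l
    p[_kernel.P_AX] = morph.l * math.sin(math.radians(beat.Phi) / 2.0)
    p[_kernel.P_AY] = morph.l * beat.Sa / 2.0
    p[_kernel.P_CY] = morph.l * (1.0 - beat.Sa / 2.0)
    p[_kernel.P_TA] = beat.Ta
    p[_kernel.P_DIR] = float(direction)
    p[_kernel.P_A] = body.a
    p[_kernel.P_B] = body.b
    p[_kernel.P_M] = body.m
    p[_kernel.P_VOL] = body.V
    p[_kernel.P_DE] = body.d_e
    p[_kernel.P_I1] = body.I[0, 0]
    p[_kernel.P_I2] = body.I[1, 1]
    p[_kernel.P_CA_INF] = cp["CA_inf"]
    p[_kernel.P_CA_ALPHA] = cp["CA_alpha"]
    p[_kernel.P_A_PAR] = cp["A_par"]
    p[_kernel.P_A_PERP] = cp["A_perp"]
    p[_kernel.P_SN1] = cp["sn_c1"]
    p[_kernel.P_SN2] = cp["sn_c2"]
    p[_kernel.P_CM_PAR] = cp["Cm_par"]
    p[_kernel.P_CM_PERP] = cp["Cm_perp"]
    p[_kernel.P_CR_PAR] = cp["CR_par"]
    p[_kernel.P_CR_PERP] = cp["CR_perp"]
    p[_kernel.P_RE_LO] = cp["re_lo"]
    p[_kernel.P_RE_HI] = cp["re_hi"]
    return rp, dvec, fr, ph0, p


def _initial_state() -> np.ndarray:
    y0 = np.zeros(18)
    y0[6] = y0[10] = y0[14] = 1.0  # R = identity
    return y0


def _samples_to_traj(rows: list[np.ndarray], dt_s: float, meta: dict) -> Trajectory:
    arr = np.vstack(rows)
    return Trajectory(
        t=arr[:, 0], X=arr[:, 1:4], V=arr[:, 4:7],
        angles=arr[:, 7:10], omega=arr[:, 10:13], dt=dt_s, meta=meta,
    )


def _static_trajectory(duration: float, meta: dict) -> Trajectory:
    t = np.linspace(0.0, duration, 11)
    z = np.zeros((len(t), 3))
    return Trajectory(t=t, X=z.copy(), V=z.copy(), angles=z.copy(),
                      omega=z.copy(), dt=float(t[1] - t[0]), meta=meta)


def _initial_row(y0: np.ndarray) -> np.ndarray:
    row = np.zeros((1, 13))
    row[0, 1:7] = y0[:6]
    row[0, 7:10] = 0.0
    row[0, 10:13] = y0[15:18]
    return row


def simulate(program: RowFrequencyProgram,
             morph: Morphometry | None = None,
             beat: BeatParams | None = None,
             fluid: FluidProperties | None = None,
             coeffs: CoefficientModel | None = None,
             duration: float | None = None,
             halting: str = "duration",
             dt: float | None = None,
             sample_stride: int = SAMPLE_STRIDE) -> Trajectory:
    """Integrate the rigid-body equations from rest at the origin.

    The body starts axis-aligned (oral axis along +x).  With
    ``halting="duration"`` the run spans exactly ``duration`` seconds.  With
    ``halting="steady"`` the run continues until the trailing-2-s running
    mean of R/L changes by <1% between consecutive beat cycles (steady
    turn) or exceeds 10 (straight swimming), capped at 10 s.

    The fixed RK4 step defaults to ``1/(STEPS_PER_PERIOD * f_max)``.
    """
    morph = morph or Morphometry()
    beat = beat or BeatParams()
    fluid = fluid or FluidProperties()
    body = build_body(morph, fluid.rho)
    coeffs = coeffs or default_coefficients(body)
    if halting not in ("duration", "steady"):
        raise ValueError("halting must be 'duration' or 'steady'")
    if halting == "duration":
        if duration is None or duration <= 0:
            raise ValueError("duration must be positive")

    meta = dict(mode=program.mode_label, freqs=program.freqs,
                direction=program.direction, coeffs=coeffs.name,
                halting=halting)
    f_max = program.f_max
    if f_max == 0.0:
        return _static_trajectory(duration or 1.0, meta)

    beat_dir = BeatParams(f=beat.f, Phi=beat.Phi, Ta=beat.Ta, Sa=beat.Sa,
                          P_L=beat.P_L, direction=program.direction)
    rp, dvec, fr, ph0, p = _build_arrays(
        program.freqs, morph, beat_dir, body, fluid, coeffs, program.direction)

    dt = dt or 1.0 / (STEPS_PER_PERIOD * f_max)
    dt_s = dt * sample_stride
    meta["dt"] = dt
    y = _initial_state()
    rows = [_initial_row(y)]

    if halting == "duration":
        n_steps = int(round(duration / dt))
        out, y = _kernel.simulate_chunk(y, 0.0, dt, n_steps, sample_stride,
                                        rp, dvec, fr, ph0, p)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state; meta={meta}")
        rows.append(out)
        return _samples_to_traj(rows, dt_s, meta)

    # steady-state halting: advance one beat cycle at a time
    from .metrics import mean_curvature_ratio
    T_beat = 1.0 / f_max
    steps_per_cycle = STEPS_PER_PERIOD
    t = 0.0
    prev_rl = None
    L = morph.L_B
    while t < MAX_DURATION - 0.5 * dt:
        out, y = _kernel.simulate_chunk(y, t, dt, steps_per_cycle,
                                        sample_stride, rp, dvec, fr, ph0, p)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state; meta={meta}")
        rows.append(out)
        t += steps_per_cycle * dt
        if t + 1e-9 < STEADY_WINDOW + 2.0 * T_beat:
            continue
        traj = _samples_to_traj(rows, dt_s, meta)
        rl = mean_curvature_ratio(traj, L, window=(t - STEADY_WINDOW, t),
                                  beat_period=T_beat)
        if rl >= STRAIGHT_RL:
            meta["halt"] = "straight"
            break
        if prev_rl is not None and abs(rl - prev_rl) <= STEADY_RTOL * prev_rl:
            meta["halt"] = "steady"
            break
        prev_rl = rl
    else:
        meta["halt"] = "max_duration"
    return _samples_to_traj(rows, dt_s, meta)


def replay(schedule_t: np.ndarray, schedule_f: np.ndarray,
           direction: int = 1,
           morph: Morphometry | None = None,
           beat: BeatParams | None = None,
           fluid: FluidProperties | None = None,
           coeffs: CoefficientModel | None = None,
           sample_stride: int = SAMPLE_STRIDE) -> Trajectory:
    """Replay a per-row time-varying frequency schedule.

    ``schedule_t`` holds the start time of each segment (first entry 0) and
    ``schedule_f`` is ``(n_segments, 8)`` row frequencies, held
    stepwise-constant within a segment (the last segment ends one segment
    length after its start, or at the next breakpoint).  Per-row beat phase
    is continuous across segment boundaries.
    """
    schedule_t = np.asarray(schedule_t, dtype=float)
    schedule_f = np.asarray(schedule_f, dtype=float)
    if schedule_f.ndim != 2 or schedule_f.shape[1] != N_ROWS:
        raise ValueError(f"schedule must have {N_ROWS} frequency columns")
    if len(schedule_t) != len(schedule_f):
        raise ValueError("schedule times and frequencies disagree in length")
    if np.any(schedule_f < 0) or not np.all(np.isfinite(schedule_f)):
        raise ValueError("frequencies must be >= 0 and finite")
    if schedule_t[0] != 0.0 or np.any(np.diff(schedule_t) <= 0):
        raise ValueError("schedule times must start at 0 and increase")

    morph = morph or Morphometry()
    beat = beat or BeatParams()
    fluid = fluid or FluidProperties()
    body = build_body(morph, fluid.rho)
    coeffs = coeffs or default_coefficients(body)
    beat_dir = BeatParams(f=beat.f, Phi=beat.Phi, Ta=beat.Ta, Sa=beat.Sa,
                          P_L=beat.P_L, direction=direction)

    f_max = float(schedule_f.max())
    meta = dict(mode="replay", direction=direction, coeffs=coeffs.name)
    if f_max == 0.0:
        return _static_trajectory(float(schedule_t[-1]) or 1.0, meta)
    dt = 1.0 / (STEPS_PER_PERIOD * f_max)
    dt_s = dt * sample_stride
    meta["dt"] = dt

    ends = np.append(schedule_t[1:],
                     schedule_t[-1] + (np.diff(schedule_t)[-1]
                                       if len(schedule_t) > 1 else 1.0))
    y = _initial_state()
    rows = [_initial_row(y)]
    row_phase = np.zeros(N_ROWS)  # accumulated beat phase per row (cycles)
    placements = place_ctenes(morph)
    t = 0.0
    for seg in range(len(schedule_t)):
        seg_dur = float(ends[seg] - schedule_t[seg])
        n_steps = max(1, int(round(seg_dur / dt)))
        freqs = tuple(schedule_f[seg])
        rp, dvec, fr, ph0, p = _build_arrays(
            freqs, morph, beat_dir, body, fluid, coeffs, direction)
        # continuity: fold accumulated phase in, and reference time to 0
        for i, pl in enumerate(placements):
            ph0[i] += row_phase[pl.row_id] - fr[i] * t
        out, y = _kernel.simulate_chunk(y, t, dt, n_steps, sample_stride,
                                        rp, dvec, fr, ph0, p)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state in replay segment {seg}")
        rows.append(out)
        row_phase += np.asarray(freqs) * (n_steps * dt)
        t += n_steps * dt
    return _samples_to_traj(rows, dt_s, meta)
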