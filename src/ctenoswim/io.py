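"""Configuration parsing, landmark/trajectory readers and analytic fixtures.

Run configuration is YAML with nested blocks (morphometry, beat, fluid,
control, simulation, output).  Lengths in the morphometry block are given
in millimetres at the configuration boundary and converted to SI
internally; angles are degrees.  Unknown keys are rejected with the full
key path.

Landmark tracks are comma-separated tables with named columns
``t, apical_x..z, bulb1_x..z, bulb2_x..z`` (a leading ``# units: mm``
comment switches coordinate units).
"""

from __future__ import annotations

import hashlib
import io as _io
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .geometry import Morphometry
from .hydro import FluidProperties
from .kinematics import BeatParams

__all__ = [
    "RunConfig",
    "LandmarkTrack",
    "read_config",
    "write_config",
    "read_landmarks",
    "write_landmarks",
    "make_fixture",
    "write_trajectory",
    "read_trajectory",
]

_MORPH_KEYS = {"L_B", "d_B", "l", "s", "n_S", "n_T", "eps_S", "eps_T", "kappa"}
_BEAT_KEYS = {"f", "Phi", "Ta", "Sa", "P_L"}
_FLUID_KEYS = {"rho", "nu"}
_CONTROL_KEYS = {"mode", "f_out", "f_in", "direction", "quadrant", "rows",
                 "schedule_path"}
_SIM_KEYS = {"duration", "halting", "dt", "sample_stride"}
_OUTPUT_KEYS = {"path", "stride"}
_MM = 1e-3


@dataclass
class LandmarkTrack:
    """Per-frame 3D coordinates of the three tracked landmarks (SI units)."""

    t: np.ndarray
    apical: np.ndarray   # (n, 3) apical organ
    bulb1: np.ndarray    # (n, 3) tentacular bulb 1
    bulb2: np.ndarray    # (n, 3) tentacular bulb 2

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("landmark time must be strictly increasing")
        for name in ("apical", "bulb1", "bulb2"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (len(self.t), 3):
                raise ValueError(f"{name} must be (n, 3)")
            setattr(self, name, arr)
        tri = np.linalg.norm(
            np.cross(self.bulb1 - self.apical, self.bulb2 - self.apical),
            axis=1)
        if np.any(tri < 1e-18):
            raise ValueError("degenerate landmark triangle in at least one frame")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class RunConfig:
    """Validated run configuration (SI units)."""

    morphometry: Morphometry = field(default_factory=Morphometry)
    beat: BeatParams = field(default_factory=BeatParams)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    control: dict = field(default_factory=lambda: {
        "mode": "mode4", "f_out": 20.0, "f_in": 20.0,
        "direction": 1, "quadrant": 0})
    simulation: dict = field(default_factory=lambda: {
        "duration": 1.0, "halting": "duration"})
    output: dict = field(default_factory=dict)

    def fingerprint(self) -> str:
        """Stable content hash of the configuration."""
        payload = dict(
            morphometry=asdict(self.morphometry),
            beat=asdict(self.beat),
            fluid=asdict(self.fluid),
            control=dict(sorted(self.control.items())),
            simulation=dict(sorted(self.simulation.items())),
        )
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _reject_unknown(block: dict, allowed: set, path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config block "
                         f"'{path}'")


def _parse_config_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    _reject_unknown(raw, {"morphometry", "beat", "fluid", "control",
                          "simulation", "output"}, "<root>")
    morph_raw = dict(raw.get("morphometry") or {})
    _reject_unknown(morph_raw, _MORPH_KEYS, "morphometry")
    for key in ("L_B", "d_B", "l"):
        if key in morph_raw:
            morph_raw[key] = float(morph_raw[key]) * _MM  # mm -> m
    if "n_T" in morph_raw:
        morph_raw["n_T"] = int(round(morph_raw["n_T"]))
    if "n_S" in morph_raw:
        morph_raw["n_S"] = int(round(morph_raw["n_S"]))
    morph = Morphometry(**morph_raw)

    beat_raw = dict(raw.get("beat") or {})
    _reject_unknown(beat_raw, _BEAT_KEYS, "beat")
    beat = BeatParams(**beat_raw)

    fluid_raw = dict(raw.get("fluid") or {})
    _reject_unknown(fluid_raw, _FLUID_KEYS, "fluid")
    fluid = FluidProperties(**fluid_raw)

    control = dict(raw.get("control") or {})
    _reject_unknown(control, _CONTROL_KEYS, "control")
    if not control:
        control = {"mode": "mode4", "f_out": 20.0, "f_in": 20.0,
                   "direction": 1, "quadrant": 0}
    control.setdefault("direction", 1)
    control.setdefault("quadrant", 0)
    control.setdefault("f_in", 0.0)

    sim = dict(raw.get("simulation") or {})
    _reject_unknown(sim, _SIM_KEYS, "simulation")
    sim.setdefault("duration", 1.0)
    sim.setdefault("halting", "duration")
    if sim["halting"] not in ("duration", "steady"):
        raise ValueError("simulation.halting must be 'duration' or 'steady'")

    output = dict(raw.get("output") or {})
    _reject_unknown(output, _OUTPUT_KEYS, "output")
    return RunConfig(morphometry=morph, beat=beat, fluid=fluid,
                     control=control, simulation=sim, output=output)


def read_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return _parse_config_dict(raw)


def write_config(cfg: RunConfig, path) -> None:
    """Write a RunConfig back to YAML (mm/degree units in morphometry)."""
    morph = asdict(cfg.morphometry)
    for key in ("L_B", "d_B", "l"):
        morph[key] = morph[key] / _MM
    payload = dict(
        morphometry=morph,
        beat=asdict(cfg.beat),
        fluid=asdict(cfg.fluid),
        control=cfg.control,
        simulation=cfg.simulation,
        output=cfg.output,
    )
    payload["beat"].pop("direction", None)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


_LM_COLS = ["t"] + [f"{p}_{ax}" for p in ("apical", "bulb1", "bulb2")
                    for ax in "xyz"]


def read_landmarks(path) -> LandmarkTrack:
    """Read a landmark CSV (columns t, apical_x..z, bulb1_x..z, bulb2_x..z)."""
    units = "m"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "mm" in first:
                units = "mm"
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    missing = [c for c in _LM_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"landmark table missing columns {missing}")
    scale = _MM if units == "mm" else 1.0
    return LandmarkTrack(
        t=df["t"].to_numpy(),
        apical=df[["apical_x", "apical_y", "apical_z"]].to_numpy() * scale,
        bulb1=df[["bulb1_x", "bulb1_y", "bulb1_z"]].to_numpy() * scale,
        bulb2=df[["bulb2_x", "bulb2_y", "bulb2_z"]].to_numpy() * scale,
    )


def write_landmarks(track: LandmarkTrack, path) -> None:
    df = pd.DataFrame(
        np.column_stack([track.t, track.apical, track.bulb1, track.bulb2]),
        columns=_LM_COLS)
    df.to_csv(path, index=False, float_format="%.9g")


def write_trajectory(traj, path, fingerprint: str | None = None) -> None:
    """Write a trajectory as CSV with a metadata comment header."""
    df = traj.to_frame()
    with open(path, "w") as fh:
        meta = dict(traj.meta)
        if fingerprint:
            meta["config"] = fingerprint
        fh.write(f"# ctenoswim trajectory; meta: {meta}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_trajectory(path):
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    from .dynamics import Trajectory
    df = pd.read_csv(path, comment="#")
    t = df["t"].to_numpy()
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return Trajectory(
        t=t,
        X=df[["x", "y", "z"]].to_numpy(),
        V=df[["vx", "vy", "vz"]].to_numpy(),
        angles=df[["psi", "theta", "phi"]].to_numpy(),
        omega=df[["wx", "wy", "wz"]].to_numpy(),
        dt=dt, meta={"source": str(path)},
    )


def make_fixture(kind: str, n: int = 200, **params):
    """Analytic trajectories/landmark tracks with known metrics.

    Kinds: ``line`` (speed v, direction), ``circle`` (radius rho, angular
    rate Omega), ``helix`` (radius r, pitch p, angular rate Omega) and
    ``landmark_pose`` (rigid landmark triangle moved through a prescribed
    pose history; params: yaw/pitch/roll (rad), offset (m), speed (m/s)).
    """
    from .dynamics import Trajectory
    if n < 3:
        raise ValueError("need n >= 3 samples")
    duration = float(params.pop("duration", 2.0))
    t = np.linspace(0.0, duration, n)
    dt = float(t[1] - t[0])
    zeros = np.zeros((n, 3))

    if kind == "line":
        v = float(params.pop("v", 0.01))
        d = np.asarray(params.pop("direction", (1.0, 0.0, 0.0)), float)
        d = d / np.linalg.norm(d)
        X = np.outer(v * t, d)
        V = np.tile(v * d, (n, 1))
        return Trajectory(t=t, X=X, V=V, angles=zeros.copy(),
                          omega=zeros.copy(), dt=dt, meta={"fixture": kind})
    if kind == "circle":
        rho = float(params.pop("rho", 5e-3))
        Om = float(params.pop("Omega", 2.0))
        X = np.column_stack([rho * np.cos(Om * t), rho * np.sin(Om * t),
                             np.zeros(n)])
        V = np.column_stack([-rho * Om * np.sin(Om * t),
                             rho * Om * np.cos(Om * t), np.zeros(n)])
        return Trajectory(t=t, X=X, V=V, angles=zeros.copy(),
                          omega=zeros.copy(), dt=dt, meta={"fixture": kind})
    if kind == "helix":
        r = float(params.pop("r", 5e-3))
        p = float(params.pop("p", 4e-3))
        Om = float(params.pop("Omega", 2.0))
        X = np.column_stack([p * Om * t / (2 * math.pi),
                             r * np.cos(Om * t), r * np.sin(Om * t)])
        V = np.column_stack([np.full(n, p * Om / (2 * math.pi)),
                             -r * Om * np.sin(Om * t), r * Om * np.cos(Om * t)])
        return Trajectory(t=t, X=X, V=V, angles=zeros.copy(),
                          omega=zeros.copy(), dt=dt, meta={"fixture": kind})
    if kind == "landmark_pose":
        from .geometry import build_rotation_matrix
        yaw = float(params.pop("yaw", 0.0))
        pitch = float(params.pop("pitch", 0.0))
        roll = float(params.pop("roll", 0.0))
        offset = np.asarray(params.pop("offset", (0.0, 0.0, 0.0)), float)
        speed = float(params.pop("speed", 0.005))
        # body-frame landmark triangle (apical at the aboral pole, bulbs
        # symmetric in the tentacular plane)
        apical_b = np.array([-3.9e-3, 0.0, 0.0])
        bulb1_b = np.array([0.0, 2.0e-3, 0.0])
        bulb2_b = np.array([0.0, -2.0e-3, 0.0])
        R = build_rotation_matrix(yaw, pitch, roll)   # global -> body
        heading = R.T @ np.array([1.0, 0.0, 0.0])
        centers = offset + np.outer(speed * t, heading)
        return LandmarkTrack(
            t=t,
            apical=centers + apical_b @ R,
            bulb1=centers + bulb1_b @ R,
            bulb2=centers + bulb2_b @ R,
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
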