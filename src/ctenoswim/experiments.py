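"""Canned simulation protocols: motor-volume runs, the frequency sweep and
the independent-row-subset experiment.

These reproduce the study conditions: Table-2 mean morphometry, the
representative beat kinematics (Phi = 112 deg, P_L = 13.2%, Ta = Sa = 0.3),
seawater properties, start from rest with the oral axis along +x.

* ``motor_volume_run`` — one-second simulation of a turning mode with the
  active rows at ``f_out`` and a full frequency differential by default.
* ``run_sweep`` — the 612-run grid over the four turning configurations
  with steady-state / straight-swimming halting.
* ``run_subsets`` — one-second simulations of all 255 non-empty row subsets
  at 30 Hz (hypothetical independent row control).
* ``top_speed`` — straight swimming (mode 4) long enough to reach the
  drag–thrust plateau; speed over the trailing two seconds.
"""

from __future__ import annotations

import numpy as np

from .dynamics import (RowFrequencyProgram, assign_mode, enumerate_sweep,
                       enumerate_subsets, simulate, SWEEP_CONFIGURATIONS)
from .geometry import Morphometry
from .hydro import FluidProperties, default_coefficients
from .kinematics import BeatParams
from .metrics import maneuver_metrics, build_map, ManeuverMetrics

__all__ = ["motor_volume_run", "top_speed", "run_sweep", "run_subsets",
           "sweep_extremes", "subset_extremes"]


def _defaults(morph, beat, fluid):
    return (morph or Morphometry(), beat or BeatParams(),
            fluid or FluidProperties())


def motor_volume_run(mode: str, direction: int = 1, f_out: float = 30.0,
                     f_in: float = 0.0, duration: float = 1.0,
                     morph=None, beat=None, fluid=None,
                     quadrant: int = 0):
    """One motor-volume protocol run; returns (trajectory, metrics)."""
    morph, beat, fluid = _defaults(morph, beat, fluid)
    program = assign_mode(mode, f_out=f_out, f_in=f_in, direction=direction,
                          quadrant=quadrant)
    traj = simulate(program, morph=morph, beat=beat, fluid=fluid,
                    duration=duration, halting="duration")
    mm = maneuver_metrics(traj, morph.L_B, beat_period=1.0 / f_out)
    return traj, mm


def top_speed(f: float = 34.0, duration: float = 6.0, window: float = 2.0,
              morph=None, beat=None, fluid=None) -> float:
    """Plateau mean speed (BL/s) of straight swimming at frequency ``f``.

    Simulates mode 4 from rest for ``duration`` seconds (several drag-thrust
    relaxation times) and averages speed over the trailing ``window``.
    """
    morph, beat, fluid = _defaults(morph, beat, fluid)
    program = assign_mode("mode4", f_out=f)
    traj = simulate(program, morph=morph, beat=beat, fluid=fluid,
                    duration=duration, halting="duration")
    from .metrics import mean_speed
    return mean_speed(traj, morph.L_B, window=(duration - window, duration))


def run_sweep(morph=None, beat=None, fluid=None, direction: int = 1,
              progress: bool = False):
    """The full 612-run frequency sweep; returns a MAP DataFrame.

    Each run uses the steady-state halting policy; V̄ and R/L̄ are reported
    over the trailing two-second window at halt.
    """
    from .dynamics import STEADY_WINDOW
    from .metrics import curvature_radius
    morph, beat, fluid = _defaults(morph, beat, fluid)
    grid = enumerate_sweep()
    iterator = grid
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(grid, desc="sweep")
        except ImportError:
            pass
    rows = []
    for cfg, f_out, f_in in iterator:
        program = assign_mode(cfg, f_out=f_out, f_in=f_in, direction=direction)
        traj = simulate(program, morph=morph, beat=beat, fluid=fluid,
                        halting="steady")
        t_end = float(traj.t[-1])
        mm = curvature_radius(traj, morph.L_B,
                              window=(t_end - STEADY_WINDOW, t_end),
                              beat_period=1.0 / f_out)
        rows.append(dict(mode=cfg, f_out=f_out, f_in=f_in,
                         direction=direction, V_bar=mm.V_bar,
                         RL_bar=mm.RL_bar, straight=mm.straight_flag,
                         halt=traj.meta.get("halt", ""), t_end=t_end))
    return build_map(rows)


def run_subsets(direction: int = 1, f: float = 30.0, duration: float = 1.0,
                morph=None, beat=None, fluid=None, progress: bool = False):
    """All 255 row subsets at ``f`` Hz for ``duration`` s; MAP DataFrame."""
    morph, beat, fluid = _defaults(morph, beat, fluid)
    programs = enumerate_subsets(f=f, direction=direction)
    iterator = programs
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(programs, desc=f"subsets dir={direction}")
        except ImportError:
            pass
    rows = []
    for program in iterator:
        traj = simulate(program, morph=morph, beat=beat, fluid=fluid,
                        duration=duration, halting="duration")
        mm = maneuver_metrics(traj, morph.L_B, beat_period=1.0 / f)
        rows.append(dict(mode="subset", f_out=f, f_in=0.0,
                         direction=direction,
                         rows="".join(str(r) for r in program.active_rows),
                         n_cr=len(program.active_rows),
                         V_bar=mm.V_bar, RL_bar=mm.RL_bar,
                         straight=mm.straight_flag))
    return build_map(rows)


def sweep_extremes(map_df):
    """(min R/L̄, speed of the fastest sub-body-length-turn run)."""
    min_rl = float(map_df["RL_bar"].min())
    tight = map_df[map_df["RL_bar"] < 1.0]
    max_v_tight = float(tight["V_bar"].max()) if len(tight) else float("nan")
    return min_rl, max_v_tight


def subset_extremes(map_df):
    """(max V̄, min R/L̄) over a subset-experiment MAP."""
    return float(map_df["V_bar"].max()), float(map_df["RL_bar"].min())
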