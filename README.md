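# ctenoswim

A reduced-order 3D simulator of ctenophore metachronal swimming, for
biomechanists and bioinspired-robotics researchers studying maneuverability
and agility in drag-based paddling at intermediate Reynolds number
(Re ~ 1–1000).

Ctenophores (comb jellies) swim with eight rows of millimetre-scale paddles
(ctenes) beating in antiplectic metachronal waves. By driving the rows in
quadrant pairs at different frequencies they yaw and pitch about almost any
axis, and they reverse direction simply by reversing the power stroke.
`ctenoswim` models the animal as a self-propelled, neutrally buoyant
prolate spheroid whose motion obeys the Newton–Euler balance

    F_net + F_D + F_AR = m Ẍ
    T′_net + T′_op = I ω̇′ + ω′ × (I ω′)

where the net propulsive force is the negative of the quasi-steady drag of
each oscillating-plate ctene, `F_net = −Σ (ρw/2) y_A C_A |Ẋ + u|² û`,
summed over 68 ctenes placed on the body surface; `F_D` is anisotropic
quadratic body drag, `F_AR` the added-mass (acceleration-reaction) force and
`T′_op` a signed-quadratic resistive torque. Each ctene tip follows an
elliptical path with tunable stroke amplitude Φ, frequency f, phase lag
P_L, temporal asymmetry Ta and spatial asymmetry Sa. From simulated
trajectories the package computes the maneuverability metric R/L̄ (mean
radius of curvature in body lengths — smaller is tighter) and the agility
metric V̄ (mean speed in body lengths per second), assembles
maneuverability–agility plots (MAPs) over frequency sweeps, and estimates
motor volumes (reachable space) by voxelizing the swept body. See
`docs/methods.md` for the full model description and its limits.

## Worked example

Simulate turning mode 1 — one quadrant pair of adjacent rows beating at
30 Hz, all other rows inactive — for one second from rest, and measure the
turn:

```python
import ctenoswim as cs

morph = cs.Morphometry()                      # 7.8 mm body, 68 ctenes
program = cs.assign_mode("mode1", f_out=30.0, f_in=0.0)
traj = cs.simulate(program, morph=morph, duration=1.0)

from ctenoswim.metrics import maneuver_metrics
mm = maneuver_metrics(traj, morph.L_B, beat_period=1/30)
print(f"R/L = {mm.RL_bar:.3f}, V = {mm.V_bar:.3f} BL/s")
```

This prints

```
R/L = 0.369, V = 0.603 BL/s
```

i.e. the two active rows drive a turn with a mean radius of about 0.37 body
lengths while the animal advances at 0.60 body lengths per second. Changing
`f_out=30, f_in=0` to mode 3 (`six rows vs. two`) trades maneuverability
for agility (R/L = 1.37, V = 1.14 BL/s), and `direction=-1` swims backward
with sharper turns — the ctenes sit closer to the aboral pole, so the same
thrust produces more torque when reversed.

The same experiments are available from the shell:

```sh
ctenoswim sweep --dry-run          # enumerate the 612-run frequency sweep
ctenoswim sweep --out map.csv      # run it and write the MAP table
ctenoswim subsets --out mv.csv     # 255 independent-row-subset runs
ctenoswim simulate --out traj.csv  # one configured run (YAML config)
ctenoswim metrics traj.csv         # V̄ and R/L̄ of a trajectory file
```

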