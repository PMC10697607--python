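# Model and methods

`ctenoswim` simulates a lobate ctenophore (*Bolinopsis vitrea*–like body
plan) as a self-propelled rigid spheroid driven by eight rows of
metachronally beating paddles (ctenes), in the intermediate-Reynolds-number
regime (Re ~ 1–1000) where both viscosity and inertia matter. It is a
reduced-order, quasi-steady blade-element model: each ctene is an
oscillating flat plate whose drag, summed over all plates, propels and
torques the body; the surrounding flow is otherwise unresolved.

## Body and appendage geometry

The body is a prolate spheroid with semi-major axis `b = L_B/2` along the
aboral–oral symmetry axis (`e1'`, oral positive) and semi-minor axis
`a = d_B/2`. The body is neutrally buoyant (`m = ρV`) and its inertia is
that of a homogeneous solid spheroid; rotational added inertia is not
modelled. Two orthogonal symmetry planes organize the anatomy: the
tentacular plane (`e1'–e2'`) and the sagittal plane (`e1'–e3'`).

Eight comb rows circumscribe the body at fixed azimuths from the tentacular
plane: four tentacular rows at ±ε_T and their 180° reflections (n_T ctenes
each) and four sagittal rows at ±ε_S and reflections (n_S each). Within a
row the most aboral ctene sits at position angle κ (about the centroid,
from the aboral pole) and successive ctenes follow at meridian arc
increments δ = s·l toward the mouth; the constructor rejects layouts that
overflow the oral pole. Each placement carries the local meridian tangent
angle λ, which orients the plate's stroke plane. Because κ + (n−1)δ spans
less than the half-meridian, ctenes cluster aborally — the geometric origin
of the sharper backward turns the simulator reproduces.

Defaults are the study-population means: L_B = 7.8 mm, d_B = 6.1 mm,
l = 0.5 mm, s = 0.8, n_S = 10, n_T = 7 (nearest integer to the sample mean
7.1), ε_S = 63.9°, ε_T = 23°, κ = 27°. The column `s` is interpreted as the
normalized spacing δ/l. Configuration accepts mm and degrees; SI and
radians are used internally.

## Beat-cycle kinematics

Each ctene tip traces a closed ellipse once per period T = 1/f, centred at
(0, l(1 − Sa/2)) in local stroke coordinates (x tangential, oral-ward
positive; y radial plate length), with semi-axes a_x = l·sin(Φ/2) and
a_y = l·Sa/2. The top of the ellipse touches y = l (full extension at
mid power stroke) and the enclosed area over the practical maximum — the
ellipse of semi-axes a_x × l/2 inscribed in the reach half-circle — equals
the spatial asymmetry Sa exactly. The ellipse parameter advances at a
constant rate within each half-cycle: the extended (power) half takes
t_p = (1−Ta)/(2f), the contracted (recovery) half t_r = (1+Ta)/(2f). This
is the simplest parametrization satisfying all of the defining constraints
(amplitude Φ, full extension, area ratio Sa, duration ratio Ta); other
tip-path shapes satisfy them too, so quantitative force levels inherit
this reconstruction uncertainty.

With `direction = +1` the power stroke sweeps the tip aboral-ward, thrusting
the body mouth-first (forward); `direction = −1` mirrors the path and
reverses swimming. Plate k (1 = most aboral) is dephased by (k−1)·P_L
cycles, keyed so the metachronal wave runs opposite the power stroke
(antiplectic). Cycle-averaged row forces are nearly insensitive to the sign
of this keying. Defaults: Φ = 112°, P_L = 13.2 %, Ta = 0.3, Sa = 0.3,
representative of the studied animals.

## Forces and torques

Row propulsive force: the negative of the quasi-steady plate drag summed
over the row,

    F_row = −(ρ w / 2) Σ_k y_A C_A |Ẋ + u_k|² û_k ,

with plate width w = 0.5·l, instantaneous length y_A, plate velocity u_k
(tangent to the body surface, magnitude |ẋ_A|), body velocity Ẋ, and the
plate drag coefficient C_A evaluated at the instantaneous plate Reynolds
number Re_p = |ẋ_A|·y_A/ν. Stationary plates (f = 0, or stroke
turnarounds) contribute nothing — inactive rows are hydrodynamically
absent. Net force sums the eight rows; propulsive torque crosses each
ctene's body-frame position with its body-frame force.

Resistive terms: component-wise quadratic body drag in the body frame with
areas πa² (axial) and πab (lateral); acceleration-reaction force
−ρV·diag(C_m∥, C_m⊥, C_m⊥) on the body-frame acceleration, moved to the
left-hand side as an orientation-dependent effective mass matrix; and a
signed-quadratic opposing torque −(ρ/2)(d_e/2)⁵ C_R ω_i|ω_i| per body axis,
with d_e the equal-volume sphere diameter.

### Coefficient correlations

The exact correlations this class of model was originally run with are
not published in full detail, so `ctenoswim` ships reconstructions behind a
strategy interface (`CoefficientModel`) and treats them as the dominant
source of quantitative uncertainty:

* **Plate drag** — `C_A(Re_p) = 1.95 + 10/√Re_p`: a normal flat plate's
  high-Re limit plus a viscous correction, appropriate for Re_p ~ 1–1000.
* **Body drag** — Oberbeck's creeping-flow shape factors for a prolate
  spheroid (axial/transverse) combined with the Schiller–Naumann finite-Re
  multiplier `(1 + 0.15 Re^0.687)`, referenced to the equivalent-diameter
  Reynolds number. Exact in the Stokes limit and degenerating to the
  standard sphere law at a = b; strictly decreasing in Re.
* **Added mass** — Lamb's potential-flow coefficients; at the default
  aspect ratio b/a = 1.28, C_m∥ = 0.37 and C_m⊥ = 0.58 (sphere: 0.5).
* **Rotation torque** — the Dennis–Singh–Ingham rotating-sphere correlation
  `C = 6.45/√Re_r + 32.1/Re_r` (Re_r = ω(d_e/2)²/ν), scaled by the
  creeping-flow spheroid/sphere torque ratios for spin vs. tumble.

All Reynolds numbers are clamped to [1e-2, 1e4] before evaluation. Any
correlation can be swapped without touching the dynamics; the fast
integrator kernel consumes the numeric constants of the default family.

## Integration and control programs

Translational and rotational dynamics (Newton–Euler with the gyroscopic
term; added mass on the left-hand side) are integrated with a fixed-step
classical RK4 at dt = 1/(200·f_max), where f_max is the fastest active
row's frequency. Orientation is advanced as the full rotation matrix
(Ṙ = −[ω′]×R, re-orthonormalized every step) rather than Euler angles:
turning maneuvers routinely pitch the body axis through ±90°, where the
yaw–pitch–roll rate map is singular. Euler angles appear only in output.
Simulations start from rest at the origin, oral axis along +x. Halving dt
changes final displacement by <0.1 %. The model contains no randomness;
identical configurations produce byte-identical output.

Row control follows the observed strategies, with rows driven in quadrant
pairs (one sagittal + one tentacular row per body quadrant): mode 1 (one
quadrant pair at f_out, the diagonal pair at f_in, rest inactive), mode 2
(four rows on one side of the sagittal or tentacular plane vs. the other
four), mode 3 (six rows vs. one pair), mode 4 (all eight; straight
swimming). The frequency sweep covers f_out = 2–34 Hz and f_in = 0 to
f_out − 2 Hz in 2-Hz steps for the four turning configurations (612 runs);
the independent-row experiment drops quadrant pairing and runs all 255
non-empty row subsets at 30 Hz. A replay mode drives per-row
stepwise-constant frequency schedules with phase continuity across
segments.

Sweep runs halt when the trailing 2-s mean of R/L̄ changes by <1 % between
consecutive beat cycles (steady turn), or exceeds 10 (straight swimming),
with a 10-s cap; metrics are then reported over the trailing 2-s window.
The motor-volume protocol instead uses fixed 1-s runs at f_out = 30 Hz from
rest. Top speed is measured over the trailing 2 s of a 6-s mode-4 run —
several drag–thrust relaxation times.

## Metrics

Maneuverability R/L̄: positions are smoothed with a moving average spanning
one beat period (removing intra-beat wobble), differentiated centrally, and
the per-sample radius R = |v|³/|v×a| is normalized by body length, clamped
at 10 and averaged; estimates recover line/circle/helix closed forms within
1 % at 50–1000 samples/s (the first/last two samples, biased by one-sided
differences, are dropped). Unless a window is supplied the first two beat
cycles are excluded as startup transient. Agility V̄ is chord-summed path
length over elapsed time in body lengths/s. Motor volume is the voxelized
union of the oriented body spheroid along canonicalized trajectories
(start at origin, oral axis +x, tentacular plane = x–y); landmark tracks
(apical organ + two tentacular bulbs) are canonicalized from the initial
landmark pose, following the bulb midpoint.

## What the simulator does and does not show

All structural and symmetry properties hold exactly or to numerical
precision: mode-4 actuation yields a torque-free straight trajectory;
reflecting a control pattern through a symmetry plane mirrors the
trajectory; R/L̄ and V̄ increase from mode 1 to mode 3; backward turns are
sharper than forward ones (aboral ctene bias); maneuverability improves
monotonically with the frequency differential for modes 1 and 2 at every
f_out. Mode-1 agility also lands on the reported value (V̄ = 0.60 BL/s).

Quantitatively, the default correlations yield sustained turn rates about
half, and top speed about 60 %, of the reference simulated values
(e.g. top speed 1.46 vs. 2.49 BL/s at 34 Hz; mode-1 R/L̄ 0.37 vs. 0.20):
absolute force and torque levels are controlled by the unpublished
correlation details and tip-path shape, and should be treated as
order-of-magnitude faithful, with trends and symmetries reliable. Two
further caveats: (i) a stationary plate produces exactly zero force, so
fully inactive rows exert no passive drag — at maximum frequency
differential this removes the inner-row braking torque and, for the
six-row mode 3, lets the body weathervane toward straight swimming at high
speed, breaking the otherwise monotone Δf trend at f_in = 0; (ii) no
hydrodynamic interactions between plates or between plates and body are
modelled, so metachronal efficiency enhancement is absent by construction.
Ctene flexibility, irregular beating, per-row power-stroke reversal within
a maneuver, and external flows are out of scope.
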