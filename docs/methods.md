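# Model and methods

## The model

`quadturn` simulates a mouse-scale quadruped walking in the horizontal
plane. The trunk is a uniform rigid rod (length *L* = 10 cm, mass
*m* = 25 g) carried parallel to the ground at nominal height *H* = 3 cm,
with three planar degrees of freedom: COM position (x, y), and yaw θ.
Limbs attach to a rectangular frame of half-width *h* = 1 cm — forelimbs
at the front corners (*L*/2, ±*h*), hindlimbs level with the COM at
(0, ±*h*) — and these attachment points double as the touchdown targets
of the swing limbs. Limb kinematics are not modelled: a swing paw
teleports to its target at touchdown and a stance paw stays fixed in
ground coordinates until liftoff. All units are CGS (cm, g, s, dyn) with
g = 1000 cm/s².

**Horizontal dynamics.** Each stance paw generates a propulsion force of
fixed magnitude *F₀* directed along the paw's displacement toward its
*nominal* target — the baseline straight-walking attachment, without any
turning modification — in body coordinates. A paw that has drifted
backward during stance therefore pushes the body forward; a paw planted
lateral of its nominal target pushes the body toward the opposite side.
Viscous friction −λ**v**c (λ = 100 g/s) and the matching yaw friction
torque λIω/m dissipate energy; I = mL²/12 is the rod's yaw moment of
inertia. During two-limb support the body additionally feels the
effective inverted-pendulum force **F**p = mg z/H, perpendicular to the
support line and pointing from the line toward the COM, where z is the
signed perpendicular COM offset.

**Vertical loads.** With three or four limbs grounded, the vertical limb
loads balance gravity (ΣG = mg) and produce zero pitch/roll torque about
the COM. Three non-collinear contacts determine the loads uniquely
(barycentric coordinates × mg); four contacts are resolved by the
minimum-norm solution of the three balance constraints (minimising ΣG²,
i.e. the most even distribution), obtained in closed form from the KKT
conditions. With two limbs grounded the total load is
mg cos φ − m v_p²/H with cos φ = h_c/√(z² + h_c²), split between the
paws by the zero-pitch lever rule G₂s₂ = G₃s₃. The COM height h_c is a
separate state variable: during two-limb support it follows
dh_c/dt = −(z/h_c)v_p (preserving the pendulum arm √(z² + h_c²)) and it
returns to H whenever three-or-more-limb support resumes. A computed
negative load is never clipped: it is the sensory signal that the limb
cannot stay grounded.

**Rhythm generation.** Each limb has a two-state rhythm generator driven
purely by sensory feedback. Stance → swing when the limb unloads (G ≤ 0)
or when its displacement from the touchdown reference in body
coordinates exceeds the limit D (= L/2 = 5 cm; the displacement is the
planar norm, so mediolateral drift counts). Swing → stance when the
total vertical load decreases between consecutive steps by more than
εG = 10⁻⁶ mg; the limb that has been swinging the longest is grounded
(ties broken LF, RF, LH, RH). The one-step backward difference includes
the discontinuous drop when a support limb lifts: losing a support limb
is itself the strongest loss-of-balance signal, so the replacement limb
grounds within the same integration step. A consequence of this
serialization is that phases in which *both* limbs of one body side are
simultaneously airborne have zero duration; see Limitations.

## Turning strategies

Handedness below is described for a left turn; a right turn mirrors it.

* **Body bending** (geometric). The trunk is treated as two uniform
  segments hinged at the centre; the shoulder girdle rotates by δ/2 and
  the hip girdle by δ/2 the opposite way, and the attachment coordinates
  are re-centred on the mass centroid of the bent two-segment body
  (offset (L/4)·sin(δ/2) from the hinge). The rotation sense plants the
  forepaws *outside* the nominal straight-walking track: with propulsion
  directed along displacement toward the (unbent) nominal targets, that
  placement produces the inward steering components that curve the path
  — the same placement-opposite-the-turn principle the lateral shift
  uses. The rod's mass distribution (hence I) is unchanged.
* **Lateral force** (dynamic). An extra force of magnitude f_lat,
  perpendicular to the body axis and pointing toward the turn centre, is
  applied to each *grounded forelimb* (hindlimbs receive none). It is
  added on top of the displacement-directed propulsion, so the axial
  propulsion component is preserved and the total vector magnitude
  grows.
* **Lateral shift** (kinematic). Touchdown targets of the inner limbs
  move to lateral offset h − s and of the outer limbs to h + s. Because
  propulsion is referenced to the unshifted targets, planting the paws
  opposite the turn yields a net inward propulsion component.
* **Axial shift** (stride control, combinable with any strategy). Every
  touchdown target moves posteriorly by a along the body's longitudinal
  axis, and the forelimb displacement limit is reduced to D − a to
  preserve fore–hind timing. Magnitudes must satisfy s < h and a < D.

Pairs of strategies combine through a relative weight s ∈ [0, 1] and an
overall magnitude t ∈ [0, 1]: the first member has magnitude
t·s·Max₁ and the second t·(1−s)·Max₂ (maxima 2 rad, 500 dyn, 1 cm).

## Numerical integration

Fixed-step hybrid integration at dt = 0.5 ms. The viscous terms are
integrated exactly — velocities and yaw rate are updated as
v ← v·e^(−λdt/m) + (F/λ)(1 − e^(−λdt/m)) with the non-viscous force held
constant over the step — so with F₀ = 0 the decay matches the
closed-form exponential to machine precision; positions update
semi-implicitly from the new velocities. Discrete events (liftoffs, then
at most one touchdown) are processed at step boundaries in a fixed
order, which keeps runs exactly deterministic; there is no randomness
anywhere in the model. Halving dt changes stabilized curvatures by less
than 2 % (tested). Linear solves are 3×3/closed-form; degeneracies
(collinear triples, coincident contacts) are flagged, not inverted.

## Initialization and measurement protocol

A perfectly symmetric start (all paws on their nominal targets, zero
velocity) lies on a fixed point inside the left-right-symmetric invariant
subspace of the dynamics: the limb pairs then satisfy identical
transition conditions forever and no alternating gait can form. Runs
therefore start mid-stride: all four paws grounded, displaced backward
from their nominal targets by staggered amounts (lateral-sequence order
LH > LF > RH > RF, stagger scale 2 cm, touchdown references at the
nominal targets) with an initial forward speed F₀/λ. The feedback locks
this seed into a steady walk within a few strides.

Each run then follows a three-phase protocol:

1. **Warmup** with zero asymmetry until the stride cycle is periodic
   (stride period and stride length both change < 1 % over three
   consecutive left-forelimb stride cycles; timeout 10 s → `no_gait`).
2. **Ramp**: all strategy magnitudes grow linearly over 5 stride periods.
3. **Measurement**: COM positions at left-forelimb touchdowns are
   collected; the first 10 post-ramp strides are discarded as transient
   and the next 10 are kept.

The stabilized curvature κ\* is the median signed Menger curvature over
the kept stride triples (κ = 1/R of the circumcircle of three
consecutive LF-touchdown COM positions; counter-clockwise = left =
positive). Mean speed is chord path length over elapsed time in the
measurement window. An LF re-touchdown arriving sooner than 20 % of the
running stride interval replaces the previous stride point (the paw
bounced or stutter-stepped rather than started a new stride).

**Duty factors** are the fraction of the measurement window each limb
spends in stance, reconstructed from the event log; over whole cycles
this equals the cycle-averaged stance/stride ratio and it stays well
defined when turning produces very short stances. Inner/outer ratios are
resolved from the *commanded* turn direction, which is well defined even
near κ ≈ 0.

**Stability classification.** A run is unstable if it terminates
abnormally — `support_lost` (≤ 1 stance limbs), `height_collapse`
(h_c < H/2), `com_escape` (no admissible load configuration for longer
than one stride period), `no_gait` (warmup failure),
`insufficient_strides` — or if the kept stride curvatures fail to
converge: standard deviation above max(0.2·|median|, 0.005 cm⁻¹). The
absolute floor keeps the relative test meaningful near zero curvature
and doubles as the package's curvature measurement resolution. This
five-way taxonomy is a reconstruction; all thresholds are exposed.

## Sweep studies

Heatmaps sweep propulsion F₀ × strategy intensity at fixed axial shift;
every cell is an independent, deterministic run summarised by (measured
mean speed, κ\*, stable flag, failure mode). Envelope curves bin stable
cells by measured speed (an output, not F₀) and keep the per-bin maximum
curvature toward the commanded turn.

Desk-scale study grids: 16 propulsion values (150–1500 dyn, walking
speeds ≈ 4–45 cm/s), 10 intensities per strategy (δ ≤ 1 rad,
f_lat ≤ 500 dyn, s ≤ 0.9 cm), axial shifts 0–1.5 cm (step 0.25) for
bending/lateral force and 0–1 cm (step 0.2) for lateral shift; the
combined bending+lateral-force sweep uses 11 relative weights × 8
overall magnitudes × 10 propulsion values × 4 axial shifts. These sizes
keep a full study at a few thousand runs.

Derived statistics:

* **Axial-shift saturation** (bending, lateral force): the smallest
  shift whose envelope *maximum* is not exceeded by any larger shift's
  maximum beyond 5 % relative / 0.005 cm⁻¹ absolute. The envelope
  maximum is used because individual velocity bins of a desk-scale sweep
  are populated by few cells and fluctuate too much for bin-wise
  comparison; 2 cm/s bins are used here for the same reason.
* **Axial-shift peak** (lateral shift): the shift whose envelope attains
  the highest global maximum.
* **Speed crossovers**: per-strategy speed-optimized envelopes (maximum
  over intensities *and* axial shifts per 1 cm/s bin) are compared
  bin-wise, with differences below the 0.005 cm⁻¹ curvature resolution
  treated as ties.

## What the simulations do and do not show

The model reproduces, from feedback alone: a stable lateral-sequence
walk (duty factor ≈ 0.75, left/right duty ratios within 0.2 %) over
≈ 5–48 cm/s; the destabilizing effect of every asymmetry without stride
control; the stabilizing role of the axial shift with saturation near
1 cm for bending and lateral force and a peak near 0.4 cm for lateral
shift; the inner-forelimb duty-factor bias of turning (fore inner/outer
ratio > 1, growing with curvature) with strategy-specific hindlimb
behaviour (decreasing under bending, overtaking the forelimb asymmetry
under sharp lateral shift); the synergy of combining bending with
lateral force (mixed weights reach curvatures ≈ 0.4–0.5 cm⁻¹,
exceeding both pure strategies); and lateral-force dominance at
intermediate speeds (≈ 7–17 cm/s) with lateral-shift dominance at high
speeds (≈ 17–42 cm/s).

Known limitations:

* **Low-speed strategy ordering.** In this reconstruction the
  lateral-force and lateral-shift strategies sustain sharper stable
  turns (κ ≈ 0.24–0.32 cm⁻¹) than body bending (κ ≈ 0.14–0.15 cm⁻¹)
  in the 4–7 cm/s range, so bending is not the dominant low-speed
  strategy here. This ordering is sensitive to the instability
  criterion and grid placement near the walking floor (~5 cm/s), where
  stable turning orbits form isolated islands in parameter space.
* **Inner-side swing overlap.** Because a replacement limb grounds in
  the same integration step a support limb lifts, intervals in which
  the inner fore- and hindlimb swing simultaneously (support borne by
  the outer limbs only) have zero duration by construction. The
  alternative — restricting the touchdown trigger to within-configuration
  load decline — produces such intervals but destroys walking below
  ≈ 23 cm/s, so it was rejected.
* The planar approximation excludes roll, pitch, aerial phases and
  elastic trunk deformation; limbs teleport, so swing mechanics and
  swing-phase energetics are absent; the minimum-norm four-limb load
  rule is a regularising assumption, not a biological claim.
* Walking fails below ≈ 5 cm/s (quasi-periodic then falling gaits), so
  the model cannot probe slower locomotion.
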