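# quadturn

A planar neuromechanical simulator of quadrupedal (mouse-scale) walking
and turning, for researchers studying how sensory feedback, support
geometry and mechanical asymmetries shape locomotion.

The body is a uniform rigid rod (L = 10 cm, m = 25 g) moving in the
horizontal plane with three degrees of freedom (x, y, yaw θ). There is
no internal oscillator: each limb's two-state rhythm generator switches
on proprioceptive feedback alone — a limb lifts when it unloads
(G ≤ 0) or reaches its displacement limit D, and a swing limb grounds
when the total vertical load starts to fall (dG_tot/dt < 0). The
horizontal dynamics are

    m dv/dt = Σᵢ Fᵢ − λv + F_p,      I dω/dt = Σᵢ (rᵢ − r_c) × Fᵢ − λIω/m,

with per-limb propulsion of fixed magnitude F₀ directed along the paw's
displacement toward its nominal target, viscous friction λv, and the
inverted-pendulum force F_p = mgz/H during two-limb support. Vertical
limb loads come from force/torque balance: unique for three stance
limbs, minimum-norm (most even) for four, and the tilt relation
G₂+G₃ = mg·cosφ − mv_p²/H with lever rule G₂s₂ = G₃s₃ for two.

Turning is produced by three controlled asymmetries — body bending δ
(counter-rotating shoulder/hip girdles), a lateral steering force f_lat
on the grounded forelimbs, and a lateral shift s of touchdown targets
(inner side h−s, outer h+s) — optionally combined, plus an axial
(posterior) shift of all touchdown targets that acts as stride control.
Turning sharpness is measured stride-wise as the signed Menger curvature
κ = 1/R of the COM positions at three consecutive left-forelimb
touchdowns, and limb coordination by inner/outer duty-factor ratios.
See `docs/methods.md` for the full model description.

## Worked example

```python
from quadturn import SimConfig, simulate, summarize, make_strategy

# walk straight at ~15 cm/s, then ramp in a lateral-force left turn
strategy = make_strategy("lateral_force", 250.0, a_shift=1.0, turn="left")
result = simulate(SimConfig(F0=500.0, strategy=strategy))
summary = summarize(result)
print(f"status={result.status} stability={summary.stability}")
print(f"kappa*={summary.kappa_star:.3f} 1/cm  radius={1/summary.kappa_star:.1f} cm")
print(f"speed={summary.mean_speed:.1f} cm/s  "
      f"fore inner/outer={summary.fore_ratio:.2f}  hind={summary.hind_ratio:.2f}")
```

prints

```
status=completed stability=stable
kappa*=0.106 1/cm  radius=9.4 cm
speed=14.2 cm/s  fore inner/outer=1.22  hind=0.98
```

i.e. a stable left turn of ~9 cm radius at 14.2 cm/s, with the inner
forelimb spending 22 % more of the stride in stance than the outer one.
The same objects expose the trajectory (`result.traj`), the
liftoff/touchdown event log (`result.events`) and the per-stride
curvature records.

A command-line layer mirrors the library:

```bash
quadturn simulate run.yaml --outdir out/     # trajectory/events CSV + summary JSON
quadturn sweep   sweep.yaml --outdir sweep/  # F0 x intensity x axial-shift heatmap
quadturn plot    sweep/heatmap.csv           # PNG render
```

Sweep drivers in `quadturn.experiments` build the stability/curvature
heatmaps, the max-curvature-vs-velocity envelopes per axial shift, the
speed-optimized strategy comparison, and the brute-force pairwise
strategy combinations.

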