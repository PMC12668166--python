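# helicrawl

Modelling toolkit for **helical surface-crawling endovascular millirobots**:
soft, hollow, magnetically actuated helices that navigate 1–4 mm blood
vessels by hugging the wall while blood flows through their open core, and
that deposit a drug-transfer coating onto the endothelium by gentle
mechanical rubbing. The package is aimed at robotics and interventional
researchers who need the desk-scale physics of such a device — sizing,
safety, stability, localization and delivery — as tested, reusable code.

It covers, end to end:

* **Helix kinematics** — as-fabricated geometry from `Dr`, `L/Dr = 3.3`,
  `L/λ = 4.8`, and deformation under radial confinement by conservation of
  the helical filament arc length `S = N·sqrt((πD)² + λ²)`, so the turn
  count adapts as `N' = sqrt(S² − L'²)/(πD')`.
* **Sizing rules** — Rule 1 (wall contact): `Dr ≥ 1.1·Dmax`; Rule 2
  (deformation ceiling): `ε ≤ 35%` ⇔ `Dr ≤ Dmin/0.65`; catalog selection
  with a flagged marginal band.
* **Mechanics** — radial force `F = c0·(T/T_ref)^3.05·ε`, contact pressure
  against the 0.75 kPa design bound and the ~12.4 kPa endothelial
  tolerance, hysteresis recovery margin, and power-law exponent recovery
  from force–thickness data.
* **Hemodynamics & propulsion** — open-core flow velocity, Poiseuille wall
  shear, annulus drag, static (`μs·F_radial ≥ F_drag`) and kinetic
  (`F_prop ≥ μk·F_radial + F_drag`) stability thresholds, dipole-magnet
  fields, torque/pull, corkscrew speed `λ·fm·(1 − slip)` with step-out.
* **Digital-twin localization** — similarity-calibrated single-view 2D
  detections mapped to 3D via centerline milestones spaced a quarter robot
  length, with continuity gating and dropout coasting.
* **Coating delivery** — Weibull release law fit through two measured
  points, filter-based fragment accounting, and multi-pass deposition
  uniformity.
* **Synthetic phantoms** — straight/tapered/sinusoidal/bifurcated/wrapped
  vessel generators, steady and pulsatile waveforms, noisy projection
  streams with ground truth; all seed-deterministic.

See `docs/methods.md` for the models, assumptions and calibration choices.

## Worked example

```python
from helicrawl import RobotSpec, compressed_state
from helicrawl.phantoms import PhantomSpec, make_phantom
from helicrawl.pipeline import run_sizing_report

# A 3.6 mm helix squeezed to 0.65·Dr while stretching to 7.0·Dr:
spec = RobotSpec(dr=3.6)
state = compressed_state(spec, 0.65 * spec.dr, 7.0 * spec.dr)
print(f"turns under compression: {state.turns:.2f} (nominal {spec.n_turns})")

# Size a robot for a tapered segment narrowing from 3.2 to 2.3 mm:
vessel = make_phantom(PhantomSpec(kind="tapered", diameter=3.2,
                                  diameter_end=2.3, length=60.0))
report = run_sizing_report(vessel)
print(f"chosen size: {report.result.chosen_dr} mm, marginal={report.result.marginal}")
lo, hi = report.result.strain_range
print(f"strain range: {lo:.3f}..{hi:.3f}, design-compliant={report.design_compliant}")
```

prints

```
turns under compression: 6.74 (nominal 4.8)
chosen size: 3.6 mm, marginal=True
strain range: 0.111..0.361, design-compliant=True
```

The compressed helix forms new conformal turns (4.8 → 6.74) because its
filament cannot stretch. The 3.6 mm robot is the smallest catalog size
keeping wall contact over the 3.2 mm end (Rule 1 threshold 3.52 mm); at the
2.3 mm end it sits 1.7% past the exact Rule-2 threshold, inside the 2%
measurement-tolerance band, so the selection is accepted but flagged
`marginal`. Strain stays between 11.1% and 36.1%, and the radial contact
pressure remains inside the 0.75 kPa design bound throughout.

The same report is available from the shell:

```sh
$ helicrawl synth phantom --kind tapered --diameter 3.2 --diameter-end 2.3 \
    --length 60 --out vessel.csv
$ helicrawl size --vessel vessel.csv
chosen size      : 3.6 mm  (Rule 2 marginal)
bias diameter    : 3.240 mm at eps_bias=10%
strain range     : 0.111 .. 0.361
design pressure  : within 0.75 kPa bound
endothelial safe : yes (under 12.4 kPa)
```

Other subcommands: `stability` (flow-rate scan), `track` (2D detections →
3D track against a vessel twin), `demo-track` (synthetic tracking demo with
error statistics), `deliver` (deposition + release curves), `synth …`
(phantom/waveform/dataset generators) and `accept`.

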