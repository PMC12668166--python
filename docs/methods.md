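# Methods

`helicrawl` models a soft, hollow, magnetically actuated helical millirobot
that navigates blood vessels of roughly 1–4 mm lumen diameter by surface
crawling: the helix hugs the vessel wall, blood flows through its open core,
and a rotating external magnet drives corkscrew propulsion. This note
documents the models, their assumptions, the defaults and where they come
from, and what the synthetic phantoms do and do not capture.

## Helix geometry and compression kinematics

A robot size is fixed by its as-fabricated outer diameter `Dr` plus two
dimensionless ratios: length ratio `L/Dr = 3.3` (kept above the 3.0
anti-tumbling floor for stable torque transfer) and turn count
`L/λ = 4.8`. Secondary dimensions default to calibrated proxies — blade
width `b = 0.7·λ`, groove `β = λ − b`, wall thickness `T = 0.08·Dr` — all
overridable per spec, since only the high-`b/β`, thin-wall design intent is
fixed, not the exact coefficients.

Deformation under radial confinement is governed by a single conservation
law: the helical filament is treated as inextensible, with arc length
`S = N·sqrt((π·D)² + λ²)` evaluated on a cylinder of the robot's **outer**
diameter. Compressing to diameter `D'` while elongating to length `L'`
redistributes the filament into new conformal turns

    N' = sqrt(S² − L'²) / (π·D').

The outer-cylinder convention is a deliberate choice: it reproduces the
observed adaptation of the turn count from 4.8 to ≈6.74 when a 3.6 mm
helix is compressed to `0.65·Dr` and stretched to `7.0·Dr` to better than
1%; a wall-centerline variant is available behind a flag for sensitivity
work. Compressive strain is always `ε = (Dr − D)/Dr`, referenced to the
as-fabricated diameter, never to the preloaded one.

## Sizing rules

For a target segment with lumen extremes `Dmin`/`Dmax`:

* **Rule 1** (continuous wall contact / hysteresis offset): `Dr ≥ 1.1·Dmax`.
  The printed multiplier 1.1 is used as normative even though exact
  10%-strain algebra would give `1/0.9 ≈ 1.111`.
* **Rule 2** (deformation ceiling): `ε ≤ 35%`, equivalently
  `Dr ≤ Dmin/0.65`. The 35% cap is the 42% conformal deformation limit
  observed in tapered-cone runs minus a 7% safety margin.

Rule 2 carries a configurable 2% relative "marginal" band. The canonical
worked segment (`Dmax = 3.2`, `Dmin = 2.3` mm) selects the 3.6 mm robot, but
exact arithmetic puts 3.6 mm 1.7% past the Rule-2 threshold (3.538 mm);
measured lumen diameters are not better than a few percent, so this case is
accepted and explicitly flagged `marginal` rather than silently passed or
rejected. Lumens are treated as circular; elliptical cross-sections must be
supplied as equivalent circular diameters.

## Radial force, pressure and hysteresis

    F_radial = F_intrinsic + F_extrinsic
    F_intrinsic = c0 · (T/T_ref)^3.05 · ε

The intrinsic term is linear in strain and scales with wall thickness as
`T^3.05` (the same near-cubic law as the effective elastic modulus; the two
exponents are kept as separate parameters defaulting to 3.05). The absolute
coefficient `c0` is not derivable from published constants, so the default
is a conservative upper-bound calibration: `c0` is set so that the deepest
design strain (ε = 0.40) over the nominal blade contact area
(`b·S ≈ 96.3 mm²` for the 3.6 mm robot) produces exactly the 0.75 kPa
design pressure ceiling. Any strain inside the operating envelope then sits
at or below that ceiling, more than an order of magnitude below the
≈12.4 kPa endothelial damage threshold; both verdicts are reported
separately. Contact pressure uses the convenient identity
1 mN/mm² = 1 kPa.

First-cycle hysteresis is reduced to a single recovery ceiling `r = 0.94`:
after one load cycle the helix recovers to `r·Dr`, so a bias strain
`εbias` guarantees full recovery across a diameter variation of
`(r − (1 − εbias))·100` percent of `Dr` — 24% at 30% bias, 4% at the 10%
minimum bias. Stored elastic energy follows from integrating the linear
force law, hence `U ∝ ε²`. No viscoelastic creep is modelled.

The `T^3.05` law is validated by simulation: the synthetic force–thickness
generator draws `c·t^e·exp(N(0, σ))` and the log–log least-squares fit
(`scipy.stats.linregress`) recovers the exponent unbiasedly; the test suite
checks the single-fit tolerance (±0.05 at σ = 2%, n = 50) and a
200-replicate bias bound.

## Flow, drag and stability

Flow through the open core uses an axisymmetric occupancy model: the
wall-hugging helix leaves a core of diameter `Dv·(1 − 2·f)` with
`f = 0.19` by default, back-calculated from measured flow-rate/velocity
pairs (which imply `f ≈ 0.18–0.21`; the parameter is per-geometry
configurable because it is genuinely not constant across compressions).
Core shear stress is the Poiseuille estimate `τ = 4μQ/(πR³)`, flagged when
the Reynolds number leaves the laminar regime.

Drag on the robot is decomposed into two configurable terms:

* inertial: `Cd·½ρ·v∞²·A_annulus`, with `v∞` the **upstream superficial
  velocity** (Q over the full lumen) and `A_annulus` the blocked annulus —
  the standard bluff-body convention of using the approach velocity;
* viscous: the Poiseuille pressure drop across the open core over the robot
  length, acting on the annulus.

With `Cd = 1` this form makes friction (∝ ε) grow faster with compression
than drag does, so the observed static ordering — a 35%-strain deployment
endures more steady flow than a 10% one — emerges without coefficient
tuning.

Stability balances:

* static: largest `Q` with `μs·F_radial ≥ F_drag(Q)` (peak-of-cycle drag
  for pulsatile waveforms), solved with `brentq` and cross-checked against
  a grid-search oracle;
* kinetic: largest `Q` with `F_prop ≥ μk·F_radial + F_drag(Q)`.

The available propulsive force is capped twice: by the actuation limit
(default 12 mN, chosen so the steady-flow kinetic ordering between 10% and
35% strain and the pulsatile-compliance reversal both match bench
behaviour) and by traction, `F_prop ≤ μs·F_radial`, because a screw cannot
push harder than its grip. The traction cap makes kinetic ≤ static provable
at any setting. Friction coefficients are not published; defaults are
μs = 0.30, μk = 0.25 with an explicit calibration hook. Under pulsatile
flow with nonzero vessel compliance, the kinetic balance first relieves the
strain by `compliance·(peak/mean − 1)` — cyclic dilation at peak flow cuts
friction exactly when drag peaks, which is why the deeply compressed robot
can beat its own steady-flow threshold. Absolute thresholds from the
default calibration land a factor ~3–4 above the bench pump limits, since
the absolute force scale is a design-bound calibration, not a measured
friction fit; only orderings are asserted. An optional tilt term adds the
submerged weight component (composite density 3.3 g/cm³ from the 4:1
NdFeB:PDMS mass ratio) for upstream climbs, making the navigable flow rate
non-increasing in inclination.

Magnetic actuation uses the point-dipole field (`|B| ≤ 145 mT` envelope
check), torque `m×B`, and gradient pull `F_i = Σ_j m_j ∂B_j/∂x_i`. The
robot's dipole moment defaults to a 50 kA/m composite magnetization times
the material volume. Corkscrew speed is `λ·fm·(1 − slip)`; rotation is
synchronous while magnetic torque covers the friction torque
(`μk·F_radial·Dr/2`) and slip ramps linearly past step-out — the simplest
model consistent with the ≈76% slip implied by a measured 5.9 mm/s at
10 Hz on a 2.475 mm pitch.

## Milestone localization against a vessel digital twin

Single-view fluoroscopy yields only in-plane positions. The digital twin
supplies the third coordinate: virtual milestones are placed at uniform arc
length along the centerline, spaced a quarter of the **deployed** robot
length (≈3 mm for a 12 mm robot; always configurable, and gaps shrink
uniformly when the vessel length is not an exact multiple so they stay
equal). Image-to-world mapping is a least-squares similarity transform
(scale/rotation/translation, via `skimage.transform.SimilarityTransform`)
fitted to fiducial pairs with residual RMS reported; the projection model is
orthographic along a configurable axis (fixed C-arm pose; no perspective
model in v1).

Each detection keeps its calibrated in-plane coordinates and takes its
depth from the milestone chain. Default mode interpolates depth linearly
between the two bracketing milestones (projecting the point onto each
in-plane milestone segment and taking the closest); `snap` mode quantizes
the depth to the single nearest milestone for strict closest-milestone
fidelity, while the arc-length estimate stays continuous in both modes so
the continuity gate is not defeated by quantization. The gate restricts
candidates to `|Δs| ≤ v_max·Δt` with `v_max` defaulting to the no-slip
corkscrew bound, which resolves projection-overlapping limbs and keeps the
inferred arc length monotone for a monotonically advancing robot. Dropout
gaps are bridged by constant-velocity coasting at the nominal frame
interval (rows flagged `interpolated`) up to a configurable horizon; longer
gaps split the track. Per-sample compute latency is recorded; it measures
only this pipeline stage, not any rendering or acquisition delay. On a
noiseless synthetic stream the depth error is bounded by half the local
inter-milestone chord by construction.

## Coating release, fragments and deposition

Release of the transfer-coating payload follows a two-parameter Weibull
law `F(t) = 1 − exp(−(t/τ)^k)` calibrated in closed form through two
(time, fraction) points; the serum reference points (50% at 3 h, 90% at
12 h) give `k ≈ 0.866`, `τ ≈ 4.58 h`. A first-order law is kept as an
option but cannot honour both points (50% at 3 h forces 93.7% at 12 h).
The formulation itself (3.7 wt% PMMA in ATBC) is metadata only; no
rheology or vessel-wall absorption model is included.

Fragment accounting converts filter measurements into a sub-pore-size
fraction: `100 − (trapped% − nonspecific%)`, e.g. 2.1% trapped with 0.6%
nonspecific adsorption gives 98.5% of circulating fragments below the
10 µm pore.

Deposition along a traversed segment assumes the per-mm transfer is
proportional to the load remaining on the robot, giving exponential
depletion along the travel direction; the cell-exact update
`m·(1 − exp(−rate·Δs))` conserves mass to machine precision. Successive
passes alternate direction (forward-and-backward traversals), which is the
mechanism that flattens the profile: the coefficient of variation strictly
decreases from 1 to 3 to 5 passes.

## Synthetic phantoms and what they do not show

The generator family covers the bench geometries: straight vessels at
0–90° inclination (optionally tapered, e.g. 3.2→2.3 mm), a cone tapering
3.6→1.8 mm, a sinusoidal path, a 90° Y-bifurcation, and a helical path
wrapped around an arm-scale cylinder (45 mm wrap radius). Lumens are
axisymmetric with radius varying only along arc length; centerlines are
arc-length parameterized with chord-sum error below 1e-6 relative for
analytic kinds. Flow waveforms are steady or rectified-sine pulsatile
(systolic fraction 0.35, peak/mean ratio 3 — a plausible cardiac-output
shape, fully configurable); discrete samples are rescaled so the
time-average equals the requested mean exactly. Projection streams add
Gaussian pixel noise, random dropout and occlusion windows, and return
paired ground truth. Everything is deterministic given its seed.

What passing tests therefore show: the kinematic, force-balance, and
accounting relations are implemented self-consistently and reproduce the
algebraically forced published quantities. What they do not show: real
vessels are compliant, elliptical, pulsating and irregular; friction on
endothelium differs from phantom walls; detection noise is not Gaussian;
and absolute stability thresholds depend on constants that were never
published. Those remain empirical questions.

## Numerical choices

* Rule boundaries absorb 1e-12 relative float noise so exact-boundary
  cases pass deterministically.
* Root finding: `brentq` on [0, cap] with `xtol = 1e-9`; the balance is
  monotone in Q, and thresholds beyond the cap are reported as capped, not
  extrapolated.
* Milestone assignment ties (`t = 0.5` on a segment) round up to the later
  milestone.
* Degenerate inputs (zero-length centerlines, empty catalogs, coincident
  fiducials, non-positive power-law data, infeasible elongation past the
  filament length) raise typed errors naming the offending field.
* Problem sizes in the shipped tests and regression suite are desk-scale:
  ≤ 200 Monte-Carlo replicates, ≤ 200-point phantoms, ≤ 200-sample
  detection streams — enough for the assertions made and chosen as the
  package's own verification budget.
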