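# Methods

## World and update cycle

The arena is the axis-aligned square [−L/2, L/2]² in continuous world units;
agents are cylinders (radius 10, height 5) that move freely and may overlap —
there are no contact forces, so motion is entirely controller-driven. Walls
reflect: a step that would leave the arena mirrors the heading about the
violated wall's normal and clamps the position onto the boundary.

Each step applies a fixed synchronous phase order (field dynamics → sensing
from pre-step positions → prey decisions → predator control → motion →
energy → death/rebirth), so outcomes are independent of agent iteration
order. One step is the dimensionless time unit τ; all energy rates are
per-step amounts times τ (default τ = 1).

## Prey sensing

**Vision.** Each prey carries a camera at the top of its body (eye height 5),
optical axis horizontal along the heading, 120°×90° field of view, 200×150
pixels, with a linear angle-to-pixel mapping. Because the world contains only
uniform-colour cylinders on a flat floor, a mate's image is approximated by
an axis-aligned pixel rectangle: horizontal extent over the azimuths
bearing ± asin(r/d), vertical extent over the elevation range of the
cylinder's *nearest* surface line (horizontal distance d − r). Using the
nearest line rather than the centre distance matters at arena-typical
distances: it is what the true silhouette's bounding box does, and the
per-pixel ray-casting oracle in the test suite agrees with the rectangle
union to within one pixel row/column per edge on randomized scenes. A target
whose silhouette partially overlaps the field-of-view edge is clipped, not
dropped. The matched-pixel fraction is the area of the rectangle union over
the image area (mates share one colour, so occlusion ordering cannot change
the count); the apparent size of the nearest visible mate is its vertical
angular extent divided by the vertical field of view.

**Olfaction.** Two point sensors sit at ± the body radius perpendicular to
the heading; each reads the odor field by bilinear interpolation, and the
behavioural input is their sum (maximum ≈ 2 × the field's steady-state peak
of amplitude/evaporation = 10, which is why the escape-factor range [0, 10]
spans "never flees inside the field" to "flees at the faintest trace").

## Odor field

A non-negative concentration grid (cell size 1) covering the arena. Each
step the field first diffuses (explicit 4-neighbour scheme, coefficient
0.05, zero-flux boundaries, mass-conserving), then evaporates
(multiplicative decay, rate 0.1), then — if the predator is hunting — gains
a Gaussian bump amplitude·exp(−d²/(2(Φw/2)²)) at the predator position.
The Gaussian scale Φw/2 puts ~95 % of each deposit within a disc of diameter
2Φw, honouring Φw's meaning as a *width*. With a stationary source the peak
converges geometrically to amplitude/evaporation; a moving predator leaves
the decaying trail that prey react to. The functional form and all
coefficients are this package's own modelling choices and are configurable —
the field is a behavioural signalling medium, not a calibrated plume model.

## Behaviour rules

Prey re-evaluate their state every step with strict priority:

1. **Escape** when the summed odor reading exceeds f_e. While escaping the
   heading is redrawn uniformly whenever the reading is rising (strictly
   positive temporal change) and kept otherwise; speed 2.
2. **Gather/halt** when no odor is detected (summed reading below the sensor
   floor 0.05), a mate is visible, and the matched fraction is at least f_g:
   approach the nearest visible mate at speed 1, halting while it subtends at
   least 20 % of the vertical field of view (≈ 25 units centre distance,
   roughly body contact). The odor gate is essential: without it a bold prey
   could rest and recharge inside the predator's field, predation would cost
   nothing, and the ecosystem freezes into a single halted cluster. With it
   the predator's approach disperses clusters — settled prey must either
   flee (paying escape costs) or wander without recharging.
3. **Wander** otherwise: heading perturbed uniformly within ±π/6, speed 1.

Energy: halting +1.2τ; wandering/gathering −0.2τ; escaping
−0.3·speed·τ = −0.6τ at the default escape speed. Each prey inside the
hunting predator's odor field (local concentration ≥ 0.5) additionally loses
`digest_gain_rate`·τ = 2τ to the predator — digestion is an energy
*transfer*, the model's predation pressure. Death is strictly energy < 0.

The predator steers toward the centroid of the largest single-linkage prey
cluster (link distance 30 = 3 body radii; ties broken by the lowest member
index so runs are bit-reproducible), paying 3.3τ per hunting step for odor
emission and gaining the digestion transfer. At energy ≥ 100 it rests
(stationary, no emission, −0.5τ per step) and resumes hunting once drained
10 units below the threshold. Its energy is floored at zero: energy is a
non-negative stock, and the predator—unlike prey—cannot die, so starvation
saturates instead of accumulating unbounded debt (which would otherwise make
the time-to-threshold and energy-span metrics artifacts of the initial
search phase). A `random_walk` predator policy is available for parity with
hardware platforms whose localisation latency precludes cluster tracking.

## Evolution

Steady-state, event-driven: a dying prey is replaced in the same slot by a
child whose factors come from a parent drawn among the survivors with
probability proportional to energy (floored at 10⁻⁶), perturbed by Gaussian
mutation with σ = 5 % of each factor's range and clipped into the range; the
child starts at the initial energy at a uniform position. With no survivors
the factors are redrawn uniformly (population restart). There is no
crossover and no synchronous generation structure. Energy-proportional
parentage plus clipping keeps the population size and factor ranges
invariant and concentrates lineages under sustained mortality, which is what
the evolution-degree metric detects.

## Analysis

Histograms use 20 equal-width bins over each factor's closed range (bin
widths 0.5 and 0.015); interior-edge values go to the higher bin, the upper
range edge to the last bin. The evolution degree ΔM is the difference of
histogram maxima between the final and initial snapshots. The KDE uses a
Gaussian kernel with bandwidth six times Silverman's rule of thumb
(0.9·min(sd, IQR/1.34)·n^(−1/5)), floored at 10⁻³ of the range width for
degenerate samples, evaluated on a fixed 512-point grid; the reported
smoothed representative value is the grid argmax (ties to the lower value),
with the plain mean emitted alongside. Time-to-threshold metrics are strict
first crossings; when a threshold is never reached within the horizon the
metric is missing and excluded from sweep averages (directional comparisons
in the test suite instead treat such trials as right-censored, since prey
mean energy grows over a run).

## Randomness and reproducibility

All stochastic ingredients draw from named substreams ("init", "wander",
"escape", "rebirth") derived from the run seed through numpy's SeedSequence
spawn keys, so purposes cannot perturb one another and (config, seed)
determines a run bit-for-bit, including the bytes of the written log files.
Sweep cells use a seed that is a pure function of (base seed, condition
index, trial index), making sweeps order-independent.

## What the simulator does and does not emulate

Runs emulate the virtual study system: ideal sensing (no camera noise, exact
colour matching, noiseless odor sensors), no physical contact, instantaneous
control, and a single predator. They do not emulate hardware realities —
localisation latency, limited camera resolution, collisions, communication
delays — so conclusions from passing tests transfer to the idealised model,
not to robot arenas. The test suite's stochastic checks (factor convergence
under high selective pressure; the selective-pressure trend in prey energy
at the predator's threshold time) run at a reduced scale — 1500-step
horizons, 5–10 replicate seeds — chosen so the full suite stays fast while
the effects remain detectable; single-run checks use 100–2000 steps.

## Parameter defaults

Defaults encode the reference study condition: L = 200, Φw = 20, 20 prey,
1 predator, 6000 steps, factor ranges [0, 10] and [0, 0.3], prey-mean energy
threshold 20, predator rest threshold 100, emission cost 3.3τ, move cost
0.2τ, rest gain 1.2τ. Quantities the study conditions do not pin down are
set once on mechanistic grounds and exposed in the config: speeds
(wander/gather 1, escape 2, predator 1.5), escape cost coefficient 0.3,
initial energies 10, digestion transfer 2τ per prey, digestion range
concentration 0.5, odor detection floor 0.05, halt threshold 0.2 of the
vertical field of view, cluster link distance 30, mutation σ 5 % of range,
rest hysteresis 10, rest drain 0.5τ, field cell 1.0, evaporation 0.1,
diffusion 0.05, injection amplitude 1.0. The rationale for the less obvious
choices appears above; every one of them is a plain config key.

## Known limitations

- Single-predator engine (the config validates n_predator ∈ {0, 1}).
- The rectangle-union camera ignores perspective curvature of cylinder
  silhouettes; the test oracle bounds the error at one pixel per edge on
  50×38 images, and the approximation error shrinks with resolution.
- The odor-field dynamics are a configurable stand-in, not a calibrated
  plume model; absolute concentrations are meaningful only relative to the
  thresholds that read them.
- Trait convergence at short horizons (≤ 1500 steps) is driven by tens of
  death events and is therefore noisy; single-seed ΔM values of −1…+4 are
  normal, and only seed-averaged values are interpretable.
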