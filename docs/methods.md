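# Methods

This note documents the model, the numerical choices and the design
decisions behind `perfusim`, and states what the packaged synthetic studies
do and do not demonstrate.

## Process model

The package models an intensified perfusion culture of CHO cells in a
stirred reactor at constant working volume `V`. Three streams act on the
broth: fresh-medium feed `Ff`, a cell-free harvest `Fh` drawn through a
tangential-flow cell retention device (CRD), and a bleed `Fb` with reactor
composition. At constant volume `Fh = Ff − Fb`. Cells are retained by the
CRD; lysed material and soluble species pass into the harvest.

States (densities in 1e6 cells/mL, time in days):

- `Xv` viable cells, `Xd` dead cells, `Xl` lysed-cell material,
- `Phib` — a *catch-all biomaterial* pool lumping the unmeasured
  growth-inhibiting byproducts secreted by viable cells,
- `Xlh`, `Phibh` — the CRD-retained fractions of lysed material and
  biomaterial (zero unless sieving is enabled),
- `IgG` — product concentration (normalized units).

Balances:

```
dXv/dt    = (mu_eff − mu_d − Fb/V)·Xv
dXd/dt    = mu_d·Xv − (kl + Fb/V)·Xd
dXl/dt    = (1−kls)·kl·Xd − ((Fh+Fb)/V)·Xl
dPhib/dt  = (1−kbh)·Xv − ((Fh+Fb)/V)·Phib
dXlh/dt   = kls·kl·Xd − (Fb/V)·Xlh
dPhibh/dt = kbh·Xv − (Fb/V)·Phibh
dIgG/dt   = qp·Xv − ((Fh+Fb)/V)·IgG
```

with

```
mu_eff = mu_max · 1/((Phib_tot/K_I)^3 + 1) · Π_n exp(−c·(θ_n·(z_n−z*_n))^2)
mu_d   = kd + kt·Xl_tot
```

where `Phib_tot = Phib + Phibh` and `Xl_tot = Xl + Xlh`. Growth is
attenuated by a cubic Hill term in total biomaterial (half-maximal exactly
at `K_I`) and by bell-shaped ("quadratic") effects of process inputs —
temperature and pH by default — that equal 1 at the optimum. Death
accelerates linearly with the lysed-cell pool (toxicity). Lysis of dead
cells is first order. Viability is `Xv/(Xv+Xd)`. Substrate and inhibitor
hooks in the growth product default to 1: in the process this package
models, no metabolite was growth-limiting or inhibiting, so metabolite
balances are deliberately out of scope.

### Design choices in the rate laws

- **Quadratic-effect parameterization.** The bell factor is
  `exp(−c·(θ·Δz)^2)` with `c = 1/2` ("sensitivity" form: larger θ means a
  stronger effect). A "spread" form `exp(−c·(Δz/θ)^2)` is also available,
  but the packaged calibration bounds (θ_temp up to 0.081) are only
  numerically sensible under the sensitivity reading — a spread of 0.08 °C
  would annihilate growth for a routine 37→34 °C shift. Both `c` and the
  parameterization are configurable per effect.
- **Biomaterial production rate is hard-coded to 1** (units
  1e6 cells/mL·day): with an unmeasurable lumped pool, a free production
  rate and the inhibition threshold are not separately identifiable, so
  `K_I` absorbs the scale.
- **Retained sieving species are removed by bleed only** (`Fb/V`), not by
  the pass-through washout: material the filter holds inside the reactor
  can only leave with the broth. With `kls = kbh = 0` the extended balances
  reduce *exactly* to the base model (tested bit-for-bit).
- **Product is not retained** by the CRD (no product sieving coefficient).
- **Dead cells do not produce biomaterial**; production is attributed to
  viable cells only.

### Reference parameter set

`synth.REFERENCE_KINETICS` carries the calibrated values used as ground
truth throughout the packaged studies: `mu_max = 0.848/d`, `kd = 0.00921/d`,
`kt = 0.03514 mL/1e6 cells/d`, `kl = 1.58991/d`, `K_I = 12.7205`.
θ defaults are the midpoints of the calibration bounds (θ_temp 0.046,
θ_pH 1.6506) with optima at 37 °C and pH 7.05. Two large-scale sieving
sets (`SIEVING_RUN1/2`) add nonzero retention fractions (kls, kbh ≈
0.01–0.023) with a re-estimated `K_I` and `kt`.

### A structural property worth knowing

The toxicity loop (death → dead cells → lysis → more death) has loop gain
`A ≈ kt·kl·Xv/((kl+Fb/V)·D)` at a held density `Xv` and pass-through
dilution `D`. Under the reference parameters `A` crosses 1 near
`Xv ≈ 57·D/2`, so a 60e6 cells/mL set-point at 2 vessel volumes/day is
*marginally* unsustainable: the free-running model peaks just below the
set-point, the one-sided bleed controller stays at zero, and the culture
drifts slowly downward — the "minimal to no bleeding" regime. At ~1 VVD the
loop gain is ≈2 and the decline is pronounced. A 65e6 cells/mL target at
≤2 VVD cannot be sustained at all by this parameter set; the simulated mean
over days 10–17 of the test-campaign recipe lands ≈13% below target. This
is a property of the calibrated parameter values, reported as-is; the
corresponding acceptance check is left failing rather than adjusted.
`steady_state()` raises on `A ≥ 1`, which is how the limit surfaces
programmatically.

## Simulation

Fixed-step RK4 advances the kinetics; flows (feed, bleed, harvest) and the
qp predictor are refreshed on a control grid (default 0.05 d) and held
constant in between (zero-order hold), emulating a supervisory control
layer. Defaults: 2 RK4 sub-steps per control interval (local error is
dominated by the control discretization, which is part of the model
definition, not a numerical artifact; halving the sub-step changes terminal
states by <1e-4 relative). The temperature/pH shift is a one-shot event at
the first crossing of the VCD threshold; the crossing time is refined by
linear interpolation inside the sub-step so trajectories converge under
refinement. Recipes can instead quantize the shift decision to the
measurement interval (`shift_decision_interval_d`), which is how real rigs
operate — the shift is commanded when an at-line count arrives.

Bleed control is a discrete PID on `Xv − setpoint`, output clamped to
`[0, Ff]` (harvest stays non-negative), integrator frozen while clamped.
Default gains (Kp 15, Ki 50 mL/day per 1e6 cells/mL, Kd 0, at 0.05 d
updates) were tuned once on the reference kinetics so a VCD excursion
settles to within 2% of set-point in under two days; they scale with `V`
for other volumes (the model itself is scale-invariant: doubling `V` and
all flows leaves concentrations unchanged, which is tested).

Everything is vectorized over an optional particle/candidate axis, so a
swarm of parameter sets or a block of candidate feed schedules is simulated
in a single pass. This is what keeps calibration and schedule optimization
within minutes on one core.

## Calibration

Calibration replays a measured batch in *tracking* configuration: measured
feed, temperature and pH are applied as recorded; the bleed controller's
set-point follows the measured VCD, so the bleed the model *needs* to stay
on the data is compared with the bleed the plant used. The bleed command is
recomputed only when a VCD sample arrives and held in between (gains
Kp 2.5, Ki 1.0 at daily updates). Two consequences: interpolation between
samples can never inject spurious bleed, and a perfect model on noise-free
data reproduces the record exactly (the objective is literally zero at the
generating parameters — asserted in tests).

The objective sums, over batches and signals, the squared biased
autocovariance of the *studentized* residuals at lags 0–5. The lag-0 term
penalizes raw error magnitude; positive lags penalize structured misfit
that white measurement noise cannot explain. Each residual is divided by
its signal's assumed measurement scale — 3% relative for VCD
(heteroscedastic, as cell-counter error is proportional), 0.01 absolute
for viability, 1% of mean feed for bleed — so a residual of one means one
noise standard deviation. The heteroscedastic VCD scaling matters: with
plain range normalization the early growth phase (the only window where
`mu_max` is cleanly identifiable before biomaterial inhibition couples it
to `K_I`) is drowned by plateau-scale noise, and estimates bias low by
5–10%. **The VCD residual is included alongside bleed and viability**:
bleed carries growth information only while the controller actively
bleeds, and in the minimal-bleeding regime of the reference parameters
the VCD misfit is the only signal that can identify the growth parameters
from below. A simulation failure at a particle maps to a large finite
penalty (1e6 per signal) so the swarm keeps moving.

Optimization is two-stage global-best PSO (inertia 0.729,
cognitive/social 1.49445), 40 particles, 60+60 iterations, velocities
capped at 20% then 5% of each bound range, stage 2 re-seeded around the
stage-1 optimum; all particles are clipped to the bounds box. The coarse
stage is run twice from independent initializations and the better
optimum feeds the fine stage — cheap insurance against a single swarm
collapsing into a boundary basin (observed once as a `kd`-at-bound local
minimum). Free
parameters and default bounds: mu_max [0.05, 1.2], kd [0.001, 0.05],
kt [1e-6, 0.1], kl [0.8, 2], K_I [10, 250], θ_temp [0.011, 0.081],
θ_pH [0.000271, 3.301]. The scale-transfer refit frees only
(K_I, kt, kls, kbh) — bounds [0, 0.2] for the retention fractions — with
everything else frozen at the small-scale estimates, and scores VCD and
viability residuals.

Identifiability, measured on the packaged synthetic design (three batches
at 1/1.5/2 VVD, 3% relative VCD noise, 1% absolute viability noise, 5%
bleed noise) across five generator/swarm seeds: mu_max recovers within
±1.5%, kd within ±11%, K_I within ±1.5%, kt and kl within a few percent.
The θ coefficients remain weakly identified — a single 37→34 °C shift
exercises each quadratic effect at one deviation only — and should be
fixed at defaults when a dataset lacks input variation. The objective
surface is asymmetric: parameter changes that raise net growth hit a
steep penalty (the controller must bleed, and no bleed was measured),
while changes that lower it cost only the VCD/viability terms; the
studentized VCD residual is what keeps that asymmetry from biasing the
growth-rate estimate.

## Specific productivity

qp is recovered by inverting the product balance on smoothed titer
(3-point centered moving average, centered differences; constant volume
makes the washout `Ff/V`), with features taken from the simulated hidden
states at the sample times — supplying unmeasurable features (lysed cells,
biomaterial) to the data-driven sub-model is the point of the hybrid
structure. Samples with simulated VCD below 1e6 cells/mL are dropped. The
network is a two-hidden-layer MLP (16 and 10 logistic units, linear
output), Adam-trained on standardized features and target to an MSE
objective (scikit-learn backend, seeded); the fitted weights are exported
to plain JSON and evaluated by a NumPy forward pass so the predictor can
sit inside the vectorized simulation loop.

Feature influence is ranked by permutation importance (mean MSE increase
over seeded shuffles) rather than SHAP: the scientific claim — which
inputs the network actually relies on — is the same, without a dependence
on a specific explainability library.

**Collinearity caveat.** On trajectory-derived samples the mechanistic
states are structurally collinear with the inputs: in quasi-steady state
`Phib ≈ Xv·V/Ff`, so a network can reconstruct the exchange rate from
`(Xv, Phib)` and permutation importance splits the feed credit across the
proxies. This is a property of importance measures under collinearity, not
of the model. The planted-signal check therefore uses
`synth.planted_qp_samples`, which draws feature vectors independently
within realistic marginal ranges with qp depending only on lysed cells and
feed rate; on that design the trained network's top-2 features are exactly
the planted pair. Rankings computed on trajectory-correlated data should
be read with the caveat above.

The packaged surrogate `SurrogateQp` (used as ground truth for round-trip
and optimization studies) rises with lysed cells (saturating at
`xl_half = 1`) and falls linearly with exchange rate (slope 0.45 per VVD
around 1.5 VVD), scaled to `q0 = 0.03` normalized units/1e6 cells/day —
encoding the empirical finding that specific productivity increases at
lower perfusion rates and with debris accumulation. A synthetic mean cell
diameter is emitted as an affine function of true lysed-cell density
(14 + 1.5·Xl µm, 1% noise); the `diameter_correlation` diagnostic exposes
the corresponding Pearson correlation.

## Feed-schedule optimization

The decision variable is the exchange rate at six fixed knot times
(days 0, 4, 6, 9, 13, 17), interpolated piecewise-linearly (ramps) by
default, bounds 0.5–2.5 VVD. Candidates are simulated with the PID bleed
controller at the production set-point and a qp predictor in the loop, and
scored by harvested product `∫ IgG·Fh dt` over days 4–21. A soft
constraint charges a penalty (1e3 per 1e6 cells/mL·day of sag) when VCD
falls more than 15% below set-point after first reaching that band —
a schedule that starves the culture is not one a process engineer would
run. The optimizer is the same PSO (20 particles, 30+10 iterations),
warm-started with the constant-rate baselines so the result can never
score below the best of them; an exhaustive 3-level grid over the six
knots serves as an independent lower-bound oracle in the tests.

With the state-dependent surrogate qp the optimum reduces the exchange
rate right after the growth phase (accumulating lysed material and
boosting qp while VCD responds only slowly) and ramps back up later to
recover cell density and harvest flow — the dip-then-ramp signature. With
a constant qp and a set-point high enough that the controller never
bleeds, the optimum is verified (by exhaustive grid) to sit at the upper
bound of every knot: harvest maximization alone favors maximum throughput,
and any bleeding only diverts product. The growth-phase override option
("set 2.0 VVD once the target density is reached") is not applied by
default; the day-0 knot governs from inoculation.

## Synthetic data

The generator simulates a recipe, samples at the measurement interval
(default 1/day) and adds seeded white Gaussian noise: 3% relative on VCD,
0.01 absolute on viability (clipped to (0, 1]), 5% on bleed and titer, 1%
on diameter — typical instrument CVs for cell counters and protein-A HPLC.
Noise whiteness is tested (sample autocorrelation ≈ 0), so any residual
autocorrelation found by calibration reflects model misfit, which is the
rationale of the autocovariance objective. Design presets emulate the
reference campaigns: `training_3batch`/`validation_3batch` (1/1.5/2 VVD,
shift at 50, set-point 60, 20–25 d), `V01V02` (shift at 60, target 65,
17 d, 2.0 VVD — the top of the stated exchange range, consistent with the
highest biomass-specific feed of that campaign), and `fiveL` (5 L scale,
sieving parameter sets). Presets specify exchange directly in VVD; the
biomass-specific feeding mode (`bspr`) is available but needs a cell-volume
trajectory that the reference campaigns do not report.

What the synthetic studies do *not* show: the generator reproduces the
statistical structure of the reference runs (levels, phases, noise), not
real biological variability — no lot effects, no sensor drift, no
metabolite excursions, and the planted qp surrogate stands in for an
unpublished trained network. Passing recovery tests demonstrates that the
estimation machinery is correct and well-conditioned under the stated
noise, not that real data of this process would yield these parameters.

## Problem sizes and determinism

Packaged study sizes — 3 calibration batches of 21–26 daily samples, one
large-scale refit batch, 40×120 swarm evaluations (each a vectorized
3-batch simulation), 729-candidate grid audits — were chosen so the full
reference study runs in a few minutes on one core while keeping every
estimate comfortably inside its quoted tolerance. All stochastic
components (noise injection, swarm, MLP initialization, permutation
shuffles) take explicit integer seeds and are reproducible bit-for-bit;
CLI runs echo their seeds and write the resolved configuration beside
their outputs.

## Known limitations

- The V01/V02-style test recipe cannot hold its 65e6 cells/mL target under
  the reference kinetics (see the loop-gain analysis above); the
  corresponding acceptance check fails honestly.
- kt, kl, K_I and the θ coefficients are weakly identifiable from
  VCD/viability/bleed alone; report them with that caveat or fix θ when a
  dataset lacks input variation.
- Permutation importance on trajectory-correlated features splits credit
  across structurally collinear states (see above).
- Constant-volume operation is assumed throughout; filter fouling,
  pressure dynamics and metabolite balances are out of scope.
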