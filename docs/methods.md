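# Methods

`hemopoint` studies whether a point-cloud regression network can act as a
surrogate for a flow solver on coronary–aortic anatomies, before and after
bypass grafting.  Because patient imaging data and full 3-D CFD are outside
the package's scope, both ends of the problem are synthetic and fully
controlled: an idealized stenosed vessel-tree generator stands in for patient
anatomies, and an analytic reduced-order flow solver stands in for CFD.  This
note documents the models, their assumptions, the parameters that matter, and
what the synthetic setting does and does not demonstrate.

## Idealized vasculature

A model is a network of straight circular tubes: an ascending aorta (inlet at
the origin, +z cranial), an arch that turns by the configured angulation and
carries 0–3 superior side branches, a descending aorta, and three coronary
branches (LAD, LCX, RA) leaving a common ostium node on the ascending trunk.
The LAD is always split into a proximal and a distal segment at the stenosis
site.  Three built-in templates differ in branch counts and dimensions; a
`scale_seed` jitters the overall length scale by ±5 % to emulate per-patient
variability among base anatomies.

Corpus expansion redraws, per variant and uniformly from configured ranges:
stenosis count (1–2), stenosis rate (0.60–0.90), stenosis center position,
LAD–LCX bifurcation angle (30–90°), side-branch count (0–3), ascending and
descending aortic diameters (20–30 mm, 15–20 mm) and arch angulation
(80–140°).  Coronary and side-branch dimensions are not covered by those
ranges and are the package's own defaults (LAD/LCX/RA radii 1.3–1.6 mm,
side branches 3.5–4.5 mm, lengths of a few centimeters), chosen at adult
human scale.

Stenosis rate is interpreted as *diameter* reduction (the prevailing clinical
convention): the radius profile inside a window of extent 8 mm is the cosine
bump `r(x) = R − (R·s/2)(1 + cos(2π(x − x_c)/extent))`, giving throat radius
`R(1 − s)` and a smooth, integrable resistance.  Overlapping bumps take the
tightest constriction.

The bypass graft (radius 1 mm) runs from the coronary ostium to the node just
distal to the worst LAD stenosis, along a laterally bowed (sine-displaced)
centerline so its lumen does not intersect the native LAD; hydraulically it
is exactly parallel to the stenosed proximal segment.  Postoperative trees
therefore contain exactly one cycle, and removing the graft restores a tree.

Known geometric idealizations: tubes overlap slightly near junction nodes
(points there can carry the field of either parent tube); all coronary ostia
share one node; the arch angulation affects only coordinates, not the 1-D
hydraulics — tests must not expect flow changes from angle-only
perturbations.

## Reduced-order flow oracle

The ground-truth fields come from a Poiseuille hydraulic network: each
segment is a resistor `R_h = ∫ 8μ/(π r(x)⁴) dx` (closed form on uniform
stretches, fixed 1001-point composite Simpson inside stenosis windows), and
Kirchhoff balance with a fixed inlet flow (`v_in · π R_inlet²`, v_in
1.125 m/s — a peak-systolic value) and zero pressure at every outlet yields
nodal pressures and signed segment flows.  Blood is Newtonian with density
1050 kg/m³ and viscosity 0.0035 Pa·s.  Inside a segment, velocity closes to
the parabolic profile `u(ρ) = 2·ū·(1 − ρ²)` along the local tangent
(no-slip at ρ=1) and pressure drops with the cumulative resistance integral,
so both fields are available analytically at any interior point.

The model is linear (creeping flow): inertial and expansion losses across
stenoses are neglected, and there is no secondary or vortical motion.  This
keeps the solve exactly reproducible and lets conservation (`<1e−10`
relative nodal imbalance, asserted on every solve), closed-form limits and
monotonicity properties (resistance strictly increasing in stenosis rate;
postoperative distal-LAD flow strictly above preoperative) hold as hard
invariants.  The price is fidelity: real aortic flow at these Reynolds
numbers is inertial and vortex-laden, so the oracle's fields are far
smoother than solver-grade CFD.  Vortex-analysis machinery is exercised
against analytic fields (rigid rotation, the Poiseuille vorticity
`|ω| = 4ūρ/r`) rather than against oracle output.

## Point clouds and corpora

Each model yields a wall ("model") cloud — coordinates only, sampled
uniformly in wall area at a configured density — and an interior ("query")
cloud sampled uniformly in lumen volume: segments chosen proportionally to
volume, axial station uniform, radial fraction `ρ = √u` (uniform over the
cross-sectional disk).  Query points carry 3-component targets: the velocity
vector, or the scalar pressure replicated into three equal components so one
output head serves both field kinds.  Four corpora (pre/post-operative ×
velocity/pressure) are built and trained independently.  Desk-scale defaults
are ~512 wall and 2048 interior points per model, 100 expanded training
models from 10 bases and 20 test models from 2 disjoint bases; variants of
one base never straddle the train/test split.  Coordinates and targets are
*not* normalized.

## Network

The surrogate is a dual-input, dual-sampling-channel point-cloud regressor.
Both clouds pass through a per-point trunk FC1→FC2 (64/64, shared across
channels by default); the wall branch continues FC3 (512), is max-pooled
over points into one 512-vector global feature (max-pooling is the symmetric
function that makes the output independent of point order) and broadcast to
all N query points; the query branch continues FC4 (128 local features);
concatenation (N×640) feeds the per-point head FC5→FC6→3.  Hidden layers are
rectifiers, the output is linear.  Loss is mean absolute error; optimization
is Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e−8); one model's full clouds form
one optimization step, with model order reshuffled per epoch; 50 epochs by
default.  Ablation flags provide the single-channel variant (global and
local features from the same input cloud) and the unshared-trunk variant.

The implementation is plain numpy (float32, BLAS-backed) with explicit
forward/backward passes validated against finite differences; training is
exactly reproducible from one seed on one platform.

Numerical choices:

* **Initialization** — uniform fan-in `U(±1/√fan_in)`; the first layer's
  bound is multiplied by a fixed gain (default 20) and its biases drawn from
  `U(−1, 1)`, calibrating unit-scale pre-activations for meter-valued
  coordinates at anatomical extent (~0.05–0.2 m).  This is an initialization
  choice only; inputs are never rescaled.
* **FC5 width 64** — the head width is the package's own desk-scale default,
  sized to the analytic oracle fields (which are much smoother than
  solver-grade CFD output) and to single-CPU wall-clock budgets; it is
  configurable.
* **Optional target standardization** (default OFF) — pressure targets are
  O(10–100 Pa) while Adam's per-parameter step is bounded by the learning
  rate, so raw-scale pressure fitting cannot converge within desk-scale
  budgets; the toggle trains in `(T − mean)/std` space and de-standardizes
  predictions (the affine is persisted with the weights).  Loss histories
  are always reported in physical units.  Using it is a documented deviation
  from the raw-field default.
* **Ties in max-pooling** — `argmax` takes the first maximizer; the pooled
  value (hence the forward pass) is permutation-invariant regardless.
* **Degenerate inputs** — empty clouds, mixed field kinds or op states in a
  corpus, and non-finite outputs raise immediately.

## Evaluation

Two error functions over a selected point set, reported in percent, with
`‖·‖` the per-point Euclidean norm (absolute value for scalars):
range-normalized mean absolute error `NMAE = (1/N) Σ‖P−P̂‖ / (max‖P‖ −
min‖P‖) × 100` and mean relative error `MRE = (1/N) Σ ‖P−P̂‖/‖P‖ × 100`.
The vector-norm reading makes both metrics invariant under rigid rotations;
MRE is scale-invariant, and NMAE's range scales with the field.  Points with
reference magnitude below 1e−9 of the region maximum are excluded from MRE
(and counted); a region whose reference magnitudes are constant has no NMAE
and is reported as an error, not as zero.  Regional reports compute
per-model, per-region values (region-local NMAE range) and aggregate
mean ± *population* standard deviation across models.  The LAD is split
proximal/distal at the highest-grade stenosis.

**FFR** is the ratio of mean pressure over a thin cross-sectional slab 3 cm
downstream of the worst LAD stenosis to the mean over the LAD entry slab.
Because the oracle works in gauge pressure with zero-pressure outlets, the
raw ratio is not a clinical FFR; a fixed aortic reference (default 100 mmHg
= 13 332 Pa) is added to both means.  This keeps FFR in (0, 1], preserves
monotonicity in stenosis rate and is applied identically to oracle and
predicted fields — but, at this oracle's small gauge pressures, it also
compresses all FFR values toward 1, so FFR *differences* between models are
small; agreement statistics remain well defined.  Slabs are 2 % of segment
length; the preferred entry points are sampled by the function itself
(uniform over the cross-section) so sparse query clouds are no obstacle; a
point-cloud variant widens the slab ×2 up to ×8 before giving up.  The 3 cm
offset is clamped (with a warning) to 80 % of the distal segment when the
segment is shorter.

**Graft flow** is the mean axial velocity over the graft-inlet slab times
`π d²/4`, with slab points sampled uniformly over the lumen disk (the
estimator is unbiased for the parabolic profile; 20 000 points put the Monte
Carlo error well under 1 %).

**Agreement** between two methods is Pearson correlation plus Bland–Altman
mean difference and limits `mean ± 1.96 × population SD`, verified against
independent implementations.

**Vorticity** is estimated per point from a weighted least-squares fit of
the velocity-gradient tensor over k nearest neighbors (Gaussian distance
weights, k default 20); the vortex mask thresholds `‖∇×u‖` (default: 90th
percentile of unflagged magnitudes).  Rank-deficient neighborhoods are
flagged and excluded from the mask.  This is a vorticity-magnitude stand-in
for eigen-helicity-style vortex extraction; exact iso-level reproduction of
any particular visualization tool is out of scope.  High-error overlap
statistics report which fraction of points with per-point relative error
above a threshold (default 10 %) falls inside the vortex mask, overall and
per region; with no high-error points the overlap is reported as undefined
with count zero, not as an error.

**Training-size sweeps** fix the test set, draw one random order of training
models, and train fresh networks on nested prefixes (10–100 % by default);
fraction 1.0 reproduces a standard run with the same derived seed exactly.
The learning curve and its Spearman trend are reported.

## Determinism and seeds

One master seed drives everything; child streams derive via
`numpy.random.SeedSequence([master, *path])` where the path names the
consumer (base index, expansion index, sample, shuffle, init, ...).  Corpus
generation is bitwise reproducible on one platform; training is reproducible
for a fixed thread configuration (float32 reductions depend on BLAS
blocking, so predictions may differ at ~1e−8 when cloud sizes change).

## What the synthetic setting shows — and does not

Passing tests demonstrate: the metrics, clinical indices and agreement
statistics are correct against independent oracles; the flow solver obeys
conservation, closed forms and monotonicity exactly; the network honors its
permutation-invariance and locality contracts, trains stably and
reproducibly, and learns the coarse structure of the fields (range-normalized
trunk errors fall to the 10–20 % range at desk scale).

They do not demonstrate surrogate-grade accuracy on real hemodynamics.  Two
structural reasons are worth recording.  First, the oracle's fields lack
vortices, secondary flow and inertial pressure losses, so the hard part of
real aortic flow is absent.  Second, mean *relative* error over a
volume-uniform query cloud is dominated by the no-slip boundary layer: with
`ρ = √u` sampling, reference magnitudes near the wall vanish like `1 − ρ²`,
and the expectation of `1/(1−ρ²)` diverges logarithmically, so MRE stays
large (hundreds of percent at desk scale) unless the predictor resolves the
wall position to well under a percent of the radius.  Desk-scale training
budgets (5 000 Adam steps, 64-wide trunks) do not reach that regime — loss
curves plateau while near-wall relative errors remain large, and extending
to 200 epochs changes this only marginally.  Range-normalized NMAE, which is
not wall-dominated, is the informative desk-scale error measure; MRE is
reported for completeness and for the error-attribution machinery.  Small
coronary branches contribute almost nothing to the MAE loss (their
velocities are 10–100× below aortic ones), so their relative errors at desk
scale are very large; balancing the loss across regions is a possible
extension, deliberately not taken here to keep the training objective the
plain mean absolute error.

## Problem sizes used by the shipped runs

The test suite trains on 100 models × (≈512 + 2048) points for 50 epochs
(three runs: default, single-channel, unshared); the acceptance script uses
20 training models per corpus at the same cloud sizes.  These sizes are the
package's chosen desk-scale study conditions; all counts are configurable.
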