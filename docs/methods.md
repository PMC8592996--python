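# Methods

This note documents the model, its parameters and numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations. It is the package's own account of its science; every number
quoted here is computed by the test suite or `scripts/acceptance.py`.

## Static trunk model

**Kinematic chain.** Seven rigid bodies — pelvis, L5…L1, and one rigid
thoracic segment carrying the head and both arms — connected by six 3-DoF
spherical joints (L5-S1 caudally to T12-L1). Coordinates are right-handed
with X anterior, Y to the subject's left, Z superior; rotations are
intrinsic flexion (about +Y) → lateral bend (+X) → axial rotation (+Z),
degrees at all interfaces. Segment lengths are stature fractions
(`geometry.yaml`); the lumbar region (10.35% of stature) is split equally
over the five vertebrae. Segment masses come from the variant's mass table;
the printed "lumbar" row is divided equally over the five lumbar bodies (an
interpretation — the tables do not subdivide it).

**Lumbar rhythm.** The total trunk–pelvis rotation is distributed over the
six joints by per-plane fractions that sum to one: caudally increasing in
flexion (0.10 → 0.24), near-uniform in lateral bending and axial rotation.
The cited rhythm's numeric values are not in print, so these are package
defaults; every consumer can supply its own `rhythm` table, and the
distribution operation conserves the per-plane totals exactly. For postures
combining several planes, the thorax orientation is the composition of the
six per-joint Euler rotations, which differs from a single rotation by the
summed angles by second-order cross terms (< 1° at task amplitudes); the
single-plane round trip is exact.

**Muscle architecture.** The commercial 188-fascicle geometry this model
class descends from is proprietary, so the package ships an editable,
simplified bilateral set (34 fascicles):

* *local*: five multifidus fascicles (pelvis → each vertebra), six short
  rotator fascicles (one per joint) representing the deep oblique
  multifidus/rotatores fibres, four erector spinae pars lumborum fascicles,
  psoas major (two fascicles), and
* *global*: longissimus and iliocostalis pars thoracis (pelvis → thorax,
  running over via points on every lumbar vertebra), quadratus lumborum
  (iliac crest → 12th-rib region of the thorax), rectus abdominis, and the
  internal and external obliques anchored at realistic anterolateral waist
  radii.

Three geometric choices matter and were made deliberately:

1. **Via points.** A straight pelvis→thorax extensor line bow-strings in
   flexion: its moment arm at T12-L1 collapses to ~0.015 m and deep-flexion
   tasks become unbalanceable. With via points fixed to each vertebra the
   path follows the spinal curvature and posterior arms stay at 0.04–0.06 m
   in all postures. For a frictionless via-point path the moment about a
   joint — and the net force on the free body above it — depend only on the
   path segment crossing that joint (the bending forces at via points on
   superior segments cancel pairwise), so the moment-arm row is still
   (attachment − joint centre) × unit line of action of that segment. This
   is verified against a tendon-excursion finite-difference oracle
   (−dL/dθ) to 1e-4 m over a grid of postures.
2. **Per-level rotators.** Without them, no positive combination of muscle
   forces can satisfy axial balance at every joint in twisted postures (a
   cone deficiency, demonstrable by the phase-1 LP certificate: the deficit
   persists with no muscle at its bound). The rotator fascicles carry 0.06
   of the multifidus PCSA each and provide the few N·m of per-level axial
   trim that in vivo comes from deep rotators and facet contact.
3. **Oblique anchors.** The effective fibre lines of the abdominal obliques
   run between anterolateral waist points (~0.14 m lateral), giving axial
   moment arms of 0.04–0.05 m — the prime trunk-rotator geometry. Moving
   them closer to the spine makes twisting tasks infeasible.

The erector spinae PCSA is split 60% thoracic / 40% lumbar, matching the
thoracic dominance of that muscle group; all weights are editable and must
sum to one per group.

**Strength.** Fascicle strength = PCSA share × specific tension × scale.
Specific tension defaults to 90 N/cm² (mid-range of trunk-model practice;
configurable — only force ratios and load sums are anchored by the PCSA
tables). The length–mass–fat scale is (lean-mass ratio)/(stature ratio)
relative to a 75 kg, 1.75 m, 20%-fat reference subject, with configurable
exponents; it is 1 at the reference and scales linearly with lean mass.

**Body fat.** The BMI regression used for fat percentage is cited but not
printed in the source literature, so the package ships Deurenberg-style
linear coefficients per sex (documented stand-ins in `parameters.yaml`).
Base variants use the generic (male) coefficients; the female-specific
variant substitutes the female ones, making fat percentage one of the three
parameters the variant changes (with PCSAs and mass fractions).

**Intra-abdominal pressure.** IAP is modelled as an upward force
(pressure × 0.010 m² effective area) at a point 0.050 m anterior to the
T12-L1 joint, giving an extension moment at every lumbar level and a
compression-relieving thrust at L5-S1. It enters the recruitment problem as
a bounded, zero-cost actuator capped at 26.6 kPa; the volume-based
generation mechanism of the original full-body model is not reproduced.

**Passive joints.** Intervertebral stiffness is linear per plane and
defaults to zero, making muscle recruitment fully responsible for
equilibrium (the conservative choice given that no stiffness constants are
in print); any N·m/deg values can be configured.

**Arms and head.** No arm joints are modelled: each arm's segment centres
of mass sit at fixed fractions (0.35/0.70/1.0) of the shoulder→hand line,
so the hand targets determine the arm gravity levers; hand loads act at the
hand points (boxes and dumbbell pairs split 50/50, one-handed loads on the
right hand by default). Their weights transmit to the thorax.

## Recruitment solver

In activity variables x = f/N the objective Σx³ is strictly convex on
x ≥ 0 and the 18 equilibrium constraints are linear, so the muscle-force
optimum is unique (the zero-cost IAP variable is driven to whichever bound
minimizes muscle cost). The solve proceeds in two phases: a linear program
minimizing total constraint slack detects infeasibility (naming the joint
and axis of the worst deficit) and supplies a feasible start; SLSQP with
analytic gradients then minimizes the cubic objective (trust-constr is the
fallback). All-zero constraint rows (axes with neither demand nor actuator)
are dropped to keep the Jacobian full-rank. The accepted solution must
satisfy ‖residual moment‖ < 1e-6 × max(1, ‖demand‖) at every joint;
measured residuals across the full battery are ~1e-14. Optimality is
checked two ways: against a brute-force grid search over the feasible
activity simplex on random 2–5-muscle problems, and against the KKT closed
form fᵢ ∝ Nᵢ^{3/2} rᵢ^{1/2} for two-muscle problems.

**L5-S1 loads.** The joint reaction balances the superincumbent weight,
hand loads, the muscle forces crossing L5-S1 (taken along their crossing
path segment) and the IAP thrust. Components are expressed in the S1
superior-endplate frame, taken as the pelvis frame plus a configurable
sacral tilt (default 0°) — the choice of S1 rather than L5 frame is a
documented convention. Compression is the axial component; resultant shear
is the norm of the two in-plane components; %BW = 100 × force/(mass × g).

## Task battery

The twelve static holds are qualitative in the protocol; their angle values
are package defaults in `tasks.yaml`, every one overridable. Notable
choices: T2 (full flexion, no load) is 45° pelvis + 45° lumbar; T10 (stoop
lift) 30° + 40°; hand heights are stature fractions per named class (knee
0.30 … head 0.95). T12's 45° whole-trunk twist is split 30° pelvis + 15°
lumbar because lumbar axial rotation is facet-limited to roughly 3° per
level; pushing the full twist through the lumbar joints is both
unphysiological and statically unbalanceable. T11 loads the right hand (the
"favored side" default).

## Synthetic data

The generator replaces the study's recordings, which are not deposited. For
a sampled subject (truncated-normal stature/mass/age at the participant-
group means ± SDs, ±3 SD truncation) and task it solves the model to get
ground-truth forces, activities and loads, then emits what the laboratory
would record over a 3-s hold:

* posture channels at 200 Hz: constant angles/hand positions plus Gaussian
  tremor (default SD 0.2°, 2 mm);
* two force plates at 1000 Hz: each carrying half the supported weight plus
  sensor noise (default SD 5 N per plate);
* twelve-site raw EMG at 2000 Hz: per site a Gaussian carrier band-limited
  to 30–450 Hz, scaled by activity × MVC amplitude, plus white noise whose
  SD is a configured fraction of the signal amplitude (default 5%); three
  MVC trials are generated at activity 1.

This is deliberately the *minimal* signal model that the band-pass →
rectify → low-pass → MVC-normalize chain provably inverts: envelopes scale
linearly with activity, so task/MVC ratios recover activities up to a common
per-site factor. Real surface EMG adds cross-talk, electrode drift,
non-stationary spectra and motion artifact, and real motion capture adds
soft-tissue artifact and marker occlusion — none of which are emulated.
Passing the closure tests therefore shows the pipeline is self-consistent
and correctly implemented, not that it would achieve the same correlations
on in vivo recordings. All randomness flows from a single integer seed
through named substreams (seed, subject, task, channel), so identical seeds
regenerate identical trials bit for bit.

A site whose ground-truth activity is (near-)constant across the twelve
tasks — rectus abdominis is silent in every extension-demand task, since
the cubic objective never co-contracts antagonists without a mechanical
reason — has no defined correlation; the recovery checks therefore apply to
sites whose activity range exceeds 1e-3 and report the rest as undefined.

## Study pipeline and statistics

The battery simulates 10 male base + 10 female base + 10 female-specific
models × 12 tasks = 360 runs (females appear under both variants with
identical subject ordering, so the base-vs-specific comparison is paired).
Infeasible runs would be flagged rather than dropped; with the shipped
geometry none occur. Unpaired (pooled-variance) and paired t statistics and
the Pearson r with its t-transform p-value are computed from their textbook
formulas — only the t CDF comes from scipy — and are cross-checked against
an independent statistics implementation in the tests. Percent differences
between groups are reported under both denominator conventions (relative to
the smaller and the larger mean) because aggregate percentages are
denominator-ambiguous; across-task aggregates weight tasks equally. No
multiple-testing correction is applied.

On the shipped synthetic battery the female-specific tables lower mean
L5-S1 compression relative to the female base model (about −9% across
tasks, computed by `scripts/acceptance.py`): the female-specific variant
moves mass from the trunk to the thighs and shrinks the posterior-muscle
PCSAs, and both effects reduce the compressive force at the lumbosacral
junction in sagittally symmetric tasks.

## Problem sizes and tolerances

The default acceptance run uses the full 360-simulation battery, 100 random
recruitment problems for the grid-search oracle (grid resolution 25 for ≤4
muscles, 12 for 5), and one group-mean female subject for the 12-task
closure loop; it completes in a few minutes on one CPU. Key tolerances:
equilibrium 1e-6 relative (achieved ~1e-14), moment-arm oracle 1e-4 m,
filter-gain check ±0.02, MVC self-normalization 1e-9, compression recovery
0.5% (achieved ~4e-6%, limited by the 9-significant-digit CSV round trip).

## Known limitations

* Static analysis only: no inertial terms, no lifting/lowering phases.
* Force–length–velocity muscle behaviour, spinal ligaments, facet
  articulations and moving centres of rotation are excluded by design.
* The fascicle set is an effective-geometry reduction, not an anatomical
  reconstruction; per-fascicle PCSA subdivision follows configurable weights.
* The fat regression and rhythm coefficients are documented stand-ins.
* Marker-level processing (labelling, gap filling, soft-tissue-artifact
  correction) is out of scope; the kinematic entry point is a posture or
  already-continuous marker series, and the static hold window is supplied
  explicitly rather than auto-detected.
* Muscle moment arms are not sex-specific; variants differ only through
  PCSAs, mass fractions and fat percentage.
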