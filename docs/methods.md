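# Methods

This note documents the models, conventions and design choices behind
`gravicomp`, in the order the pipeline applies them.

## Scope and data model

The unit of analysis is the transcript cluster (TC), the array-level proxy
for a gene/transcript locus; a TC is *annotated* when it carries a gene
symbol. Intensities are stored linear (positive fluorescence units) in
TSV; all log transforms happen in memory. The analyzed TC universe is
whatever the input matrix contains — the package imposes no array-wide
filter, and reported fractions are always relative to that universe.
Counts are reported for all TCs and for annotated TCs separately
(bracketed in rendered tables), because annotation coverage differs
between responsive and non-responsive sets.

## Quantile normalization

Performed once per platform across all of its samples, on log2
intensities: each column's k-th order statistic is replaced by the mean of
the k-th order statistics across columns, then mapped back through the
column's own ranks and returned on the linear scale. Ties within a column
receive the mean of the tied reference positions, which keeps the
transform deterministic and rank-stable. Normalizing per platform (not per
comparison) keeps every within-platform comparison in one normalized
space.

Two consequences worth knowing:

* identical columns are a fixed point, and all columns share one sorted
  multiset afterwards (both are tested properties);
* an effect large enough to push a value outside the pooled range of the
  other samples saturates: the value is clamped to the extreme reference
  order statistic, so extreme-tail fold changes are compressed. This is a
  property of quantile normalization itself, not of this implementation.
  It is why the exact-recovery guarantee below is stated for
  distribution-matched data.

## Differential expression calling

For groups *A* (numerator) and *B*:

* **Signed fold change** — ratio of *linear* group means, written
  +Ā/B̄ when Ā ≥ B̄ and −B̄/Ā otherwise, so the magnitude is always ≥ 1
  and swapping the groups flips the sign.
* **p-value** — one-way two-group ANOVA on the log2 normalized values,
  df (1, n_A+n_B−2), identical to the two-sided pooled-variance t-test
  (F = t²; asserted to 1e-12 against an independent implementation).
  Degenerate convention when the pooled within-group variance is zero:
  p = 1 for equal means, p = 0 for unequal means — this makes noise-free
  synthetic data behave sensibly.
* **Call** — `up` iff FC ≥ +1.3 and p < 0.05, `down` iff FC ≤ −1.3 and
  p < 0.05 (FC gate inclusive, p gate strict). Defaults are parameters of
  `run_comparison`.
* **No multiple-testing correction.** The calling convention is a
  per-TC threshold rule; at the array scale the expected false-positive
  count under the p-gate alone is substantial, and only the FC gate and
  the control-exclusion step temper it. Interpret single-TC calls
  accordingly; the package deliberately does not add FDR control because
  the downstream set arithmetic is defined on the thresholded sets.

The ANOVA scale (log2) is a convention choice: fold changes are defined on
linear means, but the test is run on log2 values, which stabilizes the
variance of intensity data and matches common microarray-console practice.

## Control-exclusion filtering

Pure set subtraction: the primary set loses every member whose tc_id
appears in any designated control comparison's called set, regardless of
the direction of regulation there. The operation partitions the primary
set into (controlled, eliminated), is idempotent, and is monotone in the
number of controls. Schemes:

| platform | maximal | minimal | none |
|---|---|---|---|
| GBF | {1 g control vs BL} | *undefined* | {} |
| rocket | {H/W 1 g GC vs CC, 1 g IF vs H/W 1 g GC} (union) | {1 g IF vs H/W 1 g GC} | {} |

The rocket maximal scheme excludes the **union** of its two control
comparisons. The GBF platform defines no minimal level (it has a single
control comparison), and requesting one is an error. The reference group
of the primary rocket microgravity comparison is configurable (1 g IF for
the main analysis; H/W 1 g GC for the variant used in the
stringency-comparison figures).

## Response classification

Per TC, from two direction calls (`up`/`down`/`none`) and an eliminated
flag that always dominates:

* **temporal** (early = 75 s rocket hypergravity, late = 300 s
  centrifuge): same non-none direction → `continuous`; early response with
  no or opposite late response → `adaptation`; late response only →
  `late`; neither → `non_responsive`.
* **cross-microgravity** (flight µg vs vag): same non-none direction →
  `same_response`; flight response without matching vag response →
  `no_or_reverse`; vag response only → `vag_only`; neither →
  `non_responsive`.

Both label sets partition the universe, so class counts always sum to the
TC count — an invariant the tests enforce. The `eliminated` class mixes
TCs removed by control filtering at either stage; the pipeline exposes the
per-stage eliminated sets alongside their union, since published summaries
report only the union.

`classify_counts` aggregates a classifier over cross-tabulated
(primary, secondary, count) cells, which is how the published class totals
are reproduced without per-TC data. Percentages for report output are
rounded half-up to one decimal (`round_percent`); raw ratios are preserved
in JSON. An empty primary row reports 0% with an explicit `empty_row`
marker, since 0/0 is undefined.

Direction concordance of double-sensitive TCs is sign agreement of the two
signed fold changes; it is symmetric in its arguments.

## Synthetic studies

The generator emulates the two-platform design: GBF groups at 6 replicates
each, rocket groups at 7/7/9/7/9 (CC, H/W GC, 1 g IF, hyp-g, µg). Each TC
receives one effect class; the class determines which groups' means are
multiplied by the planted signed fold change (on the linear scale, so the
planted FC is exact under zero noise). Classes cover single-condition
responders (vag, flight µg, each hypergravity), within-platform and
cross-platform double-sensitives, handling-sensitive TCs and null. The
handling class models the pipetting response: affected TCs shift in every
pipette-handled group (exponent 1 for the control groups, 2 for the
experimental groups), making them differentially expressed in the control
comparison *and* in every primary comparison — exactly the false positives
control-exclusion is designed to remove.

Noise is i.i.d. Gaussian on log2 intensities (log-normal linear), one sd
parameter. The real study reports no within-group variance; the default
sd = 0.1 (log2) reflects its qualitative remark that within-group variance
was low and is the value used for the parameter-recovery calibration. The
baseline log2 intensity per TC is N(8, 1.5), shared across groups and
platforms. Planted |FC| is uniform in [1.3, 4.3], the span of the
published fold-change tables, with 35% down-regulated (the study saw more
up- than downregulation on the ground platforms). Class proportions
default to ~13% non-null overall, dominated by the handling and GBF
hypergravity classes, echoing the relative sizes of the published sets.
All randomness flows from one integer seed through a single generator
stream; identical configs are bit-identical.

What the generator does **not** emulate: probe-level structure, array
spatial artifacts, intensity-dependent variance, correlated TCs, batch
effects beyond the handling term, and the heavy-tailed baseline of real
arrays. Passing tests therefore demonstrate correctness of the pipeline's
logic and calibration under the stated noise model, not performance on
real microarray data.

### Guarantees under zero noise

With noise sd = 0 and the caller applied to the raw generated matrix, the
called sets equal the planted sets exactly: planted TCs have the exact
|FC| ≥ 1.3 with zero within-group variance (p = 0), nulls have FC = 1 and
p = 1. Through quantile normalization the recovery is near-exact rather
than exact, because planted effects in the distribution tails saturate
(see above) and rank shifts between columns with different planted
content perturb values by up to one order-statistic spacing. The tests
assert exact recovery on the raw path and high recovery through the full
pipeline.

## Calibration checks

* **Type-I error**: on null TCs the full caller (both gates) calls at a
  rate far below 0.05 at the default noise level — the FC gate dominates;
  the p-gate alone is calibrated (fraction of p < 0.05 within binomial
  3σ of 0.05 on unplanted studies).
* **Parameter recovery**: with planted |FC| = 1.5, 6 replicates/group,
  noise sd 0.1 and 200 generator replicates, per-class sensitivity through
  the full pipeline agrees within ±0.05 with a Monte-Carlo oracle of the
  same two-sample design written independently of the pipeline code path.
  At these settings the design is strongly powered (sensitivity ≈ 1), so
  the check primarily guards against pipeline-induced losses
  (normalization, bookkeeping), not subtle power differences.

Problem sizes used by the test suite (TC counts of 300–4000, the 200-rep
recovery experiment at 400 TCs) were chosen to make the suite complete in
seconds while keeping Monte-Carlo error well inside the asserted
tolerances.

## Clinostat mechanics

Assumptions: rigid sphere, solid-body rotation of the medium, particle
co-rotating on the circle of radius R. The inertial (spiralling) drift of
a denser-than-medium particle is neglected over a 5-minute run — at these
dimensions the trajectory does not markedly deviate from circular motion,
and the shear Reynolds number r²ω/ν ~ 2×10⁻⁴ puts the flow deep in the
Stokes regime. The particle spin ratio 1 − 0.3076·Ta^(3/2) is
indistinguishable from 1, so particle and fluid rotation rates are equal.

Parameters (SI internally; conversion only at the reporting boundary):

| symbol | meaning | default |
|---|---|---|
| r | cell radius | 5.75 µm |
| ρ_c | cell density | 1.05–1.12 g/mL (range; midpoint default) |
| ρ_f | medium density | 1.00 g/mL |
| µ | medium viscosity | 1.09–1.14 mPa·s (range; midpoint default) |
| R | rotation radius | 1.5 mm |
| ω | angular rate | 2π rad/s (60 rpm) |
| g | gravitational acceleration | 9.81 m/s² |

Derived quantities and conventions:

* **Centrifugal acceleration** ω²R/g = 0.006 g — three orders of magnitude
  below 1 g (functional weightlessness for any mechanism with a threshold
  above that).
* **Weight** mg with m = ρ_c(4/3)πr³; in the rotating frame the weight
  vector rotates at −ω, so any body-fixed component oscillates with
  peak-to-peak 2mg = 17.5 pN at the upper density bound (the bound is used
  for this maximal figure; single-valued calls default to the midpoint).
* **Hydrostatic pressure** is referenced to the top of the particle's
  circular path: p(θ) = ρ_f g R(1−cos θ), period mean ρ_f g R = 14.7 Pa,
  top-to-bottom range 2ρ_f g R = 29.4 Pa. The pipette radius (~1.75 mm) is
  close enough to R that the distinction does not change these figures at
  the quoted precision; the circular-path reference is the one that
  reproduces both printed values with Δh = 2R = 3 mm.
* **Sedimentation shear**: Stokes terminal velocity
  v = 2r²(ρ_c−ρ_f)a/(9µ) and maximum surface shear stress 3µv/(2r),
  which collapses to the viscosity-free closed form r(ρ_c−ρ_f)a/3 —
  2.3 mPa at 1 g with the upper density bound. This reconstruction (1 g
  sedimentation, not centrifugal drift) is the one consistent with the
  published magnitude. Buoyant particles (ρ_c < ρ_f) are out of scope and
  rejected.
* **Coriolis force** −2m(ω×v), with the co-rotation assumption implying
  v ≈ 0 in the rotating frame apart from the slow sedimentation drift.
* **Taylor number**: the literature formula as printed
  (r²ωµ/ρ) is dimensionally inconsistent; this package implements the
  kinematic reading r²ω·ρ_f/µ, which is numerically identical to the
  shear Reynolds number (~1.9×10⁻⁴) and *not* the sometimes-quoted 10⁻⁵.
  `particle_spin_ratio` takes Ta as an explicit argument so it is
  independent of this interpretation; either value leaves the spin ratio
  at 1 to within 10⁻⁵.
* **Quadrature**: force cycles are sampled on n uniform steps over [0, T),
  so periodic means (zero gravity average, 14.7 Pa pressure mean) are
  exact to floating-point rounding rather than O(1/n).

## Known limitations

* The caller implements thresholded per-TC testing without FDR control by
  design; it reproduces a published convention rather than current best
  practice (moderated-variance tests with FDR).
* Normalization operates on TC-level summaries; probe-level background
  correction/summarization (RMA) is upstream of this package's inputs.
* The synthetic noise model is spherical Gaussian on log2; real arrays
  have intensity-dependent variance and correlated probes, so absolute
  sensitivity numbers from simulations should not be read as array
  performance estimates.
* The physics module describes the phenomenological per-revolution force
  budget; it does not integrate particle trajectories (inertial
  migration), model particle–wall interactions, or solve the flow field.
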