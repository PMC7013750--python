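# gravicomp

Cross-platform comparison of differential gene expression under altered
gravity, with the particle mechanics of a fast 2D clinostat.

## The problem

Ground-based facilities (GBFs) — fast-rotating 2D clinostats and small
centrifuges — are routinely used to stand in for spaceflight microgravity
and launch hypergravity. Whether they actually reproduce the transcriptome
response seen in flight is an open question. The study design this package
implements compares human Jurkat T-cell expression across two platforms:

* **GBF**: baseline (BL), 1 g hardware control, 2D clinostat at 60 rpm
  (vector-averaged gravity, *vag*), 9 g centrifuge — 6 replicates per group;
* **suborbital rocket**: cell-culture control (CC), hardware ground control
  (H/W 1 g GC), 1 g in-flight centrifuge (1 g IF), 75 s launch hypergravity
  (TX hyp-g) and 5 min flight microgravity (TX µg).

`gravicomp` provides the full analysis chain for such designs as a Python
library: tabular I/O, a synthetic-data generator with planted truth,
quantile normalization, fold-change/ANOVA differential-expression calling,
control-exclusion filtering, response classification, and the closed-form
clinostat mechanics used to reason about what a suspended cell can sense.

## The statistics and the model

**Differential expression.** Per platform, intensities are
quantile-normalized on the log2 scale (each sample's order statistics are
replaced by the across-sample mean of order statistics; ties receive the
mean of the tied reference values). For a comparison of groups *A* vs *B*,
the signed fold change is the linear group-mean ratio,
FC = Ā/B̄ if Ā ≥ B̄ else −B̄/Ā (so |FC| ≥ 1), and significance comes
from a one-way two-group ANOVA on log2 values (df 1, n_A+n_B−2; identical
to the pooled-variance t-test via F = t²). A transcript cluster (TC) is
called differentially expressed when |FC| ≥ 1.3 and p < 0.05 — no
multiple-testing correction, mirroring the published thresholds.

**Control-exclusion filtering.** Any TC differentially expressed in a
designated control comparison (e.g. 1 g control vs BL, which captures the
surprisingly large handling/pipetting response) is removed from the
primary sets by tc_id, regardless of direction.

**Classification.** Calls from two comparisons are combined per TC:
temporal classes {continuous, adaptation, late, non-responsive,
eliminated} for 75 s vs 300 s hypergravity, and {same response,
no-or-reverse, vag-only, non-responsive, eliminated} for flight
microgravity vs vag; both partition the TC universe. Direction concordance
of double-sensitive TCs is counted by fold-change sign agreement.

**Clinostat mechanics.** For a cell of radius r and density ρ_c co-rotating
at ω on a circle of radius R in medium of density ρ_f and viscosity µ:
centrifugal acceleration ω²R/g (0.006 g at defaults); rotating-frame weight
mg with peak-to-peak swing 2mg (17.5 pN); hydrostatic pressure
ρ_f g R (1 − cos θ) with mean 14.7 Pa and range 29.4 Pa; Stokes
sedimentation shear 3µv/(2r) = r(ρ_c−ρ_f)a/3 (2.3 mPa at 1 g); Coriolis
force −2m(ω×v); shear Reynolds number r²ω/ν ≈ 2×10⁻⁴ and a particle spin
ratio Ω_p/ω = 1 − 0.3076·Ta^{3/2} ≈ 1.

## Worked example

```bash
python examples/04_response_classification.py
```

prints (abridged):

```
temporal (75 s vs 300 s hypergravity) — universe 43395 TCs
  non_responsive    40909   94.3%
  late               1459    3.4%
  eliminated          727    1.7%
  adaptation          267    0.6%
  continuous           33    0.1%

flight microgravity vs vag — universe 43395 TCs
  non_responsive    42086   97.0%
  eliminated          727    1.7%
  no_or_reverse       358    0.8%
  vag_only            215    0.5%
  same_response         9    0.0%
```

Reading: after 75 s of launch hypergravity, most responsive TCs are
*late* responders (only seen after 300 s at 9 g) and a minority respond
continuously — centrifuge hypergravity broadly confirms launch
hypergravity. In the microgravity block, only 9 of 43,395 TCs (< 0.1%)
respond the same way to rocket microgravity and to fast clinorotation:
vector-averaged gravity does not reproduce the flight response, which —
given that a 60 rpm clinostat only nullifies gravity-vector effects for
mechanisms integrating over ≥ 1 s — points to a sub-second gravity-sensing
step. The other examples cover the clinostat force budget
(`01_clinostat_forces.py`), synthetic studies and planted-effect recovery
(`02`), control filtering (`03`) and cross-platform concordance (`05`).

A thin CLI wraps the same stages:

```bash
gravicomp simulate --seed 5 --out study/
gravicomp diffexp --matrix study/matrix_GBF.tsv --sheet study/sheet_GBF.tsv \
    --compare CLINOSTAT_2D:CONTROL_1G --out clino.tsv
gravicomp physics --preset clinostat --out phys.json
gravicomp run --config pipeline.yaml --out bundle/
```

## Layout

```
src/gravicomp/
  io.py        TSV/JSON dialects; ExpressionMatrix, SampleSheet, TranscriptSet
  simulate.py  synthetic two-platform studies with planted truth
  diffexp.py   quantile normalization, signed FC, ANOVA, DE calling
  controls.py  control-exclusion schemes and set subtraction
  classify.py  temporal/cross classifiers, concordance, Venn, overlap ledger
  physics.py   clinostat/centrifuge particle mechanics
  datasets.py  published summary tables used as worked-example inputs
  pipeline.py  end-to-end orchestration and report bundles
  cli.py       thin click CLI over all of the above
```
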