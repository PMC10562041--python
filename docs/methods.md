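# Methods

This note documents the models, conventions and design choices in
`adaptrig`, in the order the pipeline runs them.

## DVH engine

Dose grids are 3-D arrays in Gy, axis order `(z, y, x)`, spacing in mm,
voxel-centre origin. Structures are binary masks congruent with the grid;
voxels are wholly in or out (no partial-volume weighting). The cumulative
DVH is the exact empirical survival function of the in-mask voxel dose
multiset, sampled at bin edges `0, h, 2h, …` padded to cover the maximum
dose (default `h = 0.01` Gy — finer than any clinically reported difference
in these metrics, so binning never limits the analysis).

Metric conventions (all exactly reproducible, no interpolation between
voxel doses):

* **Dx% / Dxcc** use the step-function (empirical) quantile: the returned
  dose is the smallest voxel dose within the hottest requested volume,
  resolved on the bin-edge grid. Curve lookups therefore agree with a
  brute-force sorted-voxel computation to within one bin width. `x = 0` cc
  returns the maximum dose, `x ≥` total volume the minimum.
* **Vx% / VxGy** return the percent of volume at or above the threshold.
  Thresholds between bin edges resolve to the next edge up; every shipped
  clinical threshold (2.0, 2.5, 2.7, 2.75, 3.25, 5.0, 8.0 Gy, …) is a
  multiple of the default bin width, where the lookup is exact.
* Commercial treatment-planning systems each use their own (undocumented)
  DVH binning and interpolation; numeric parity with any particular TPS is
  out of scope, reproducibility is not.

Total volume is conserved exactly (`voxel count × voxel volume`), asserted
in tests rather than assumed.

## Metric catalog

Sixteen metric slots cover targets and organs at risk uniformly across the
four site/technique groups. A slot may bind two structures: the femoral
head-and-neck D0.03cc slot is evaluated on each femur and the two rows are
pooled in summaries, which keeps both the per-structure evaluation table
and the 16-row summary layout consistent.

Because every analyzed distribution is a *single-fraction* dose, cumulative
VxGy limits are scaled by the number of treatments (V40Gy under 20
fractions → 2 Gy per fraction; the inverse round-trip is exact), and Vx%
thresholds use the per-fraction prescription dose.

Per-site applicability is a lookup, not a formula: the bladder-as-target
course flags the three bladder OAR slots `not_appropriate` and rectum V65Gy
`inadequate_dose`; the 40 Gy/5 fx SBRT course flags bowel V55Gy and both
V65Gy slots `inadequate_dose` (their cumulative limits exceed the total
prescription); the two conventional prostate courses keep all slots valid.
A formula such as "per-fraction threshold reachable" would misclassify
slots that are legitimately reported as identically zero, which is why the
statuses are tables, with per-patient override hooks in
`evaluate_fraction`.

Direction assignment: PTV/CTV D99%, D95%, V100% are coverage metrics
(lower is worse); every OAR slot and all D0.03cc hot spots — including the
target hot spots, by clinical convention — are higher-is-worse. The
direction is carried on `MetricSpec` and can be overridden by constructing
a custom spec.

## Differences and summaries

Contrasts are differences in the metric's native unit (Gy or percentage
points), not ratios — matching how such tables are reported. `ADP_SCH` is
*defined* as `ADP_REF − SCH_REF`, making the algebraic identity exact in
floating point; tests assert it on every record. Summaries use
linear-interpolation quantiles (numpy default) for median and quartiles,
IQR = Q3 − Q1, pooling fractions across a site's patients; a
`per_patient` option reduces each patient to a median first. Only
`valid`-status rows with all three values enter; incomplete rows are
skipped whole, never half-emitted.

## Trigger framework

The decision rule is inclusive at the boundary (fires on equality): the
paper-level convention is unstated in the field, and inclusivity makes the
proportion-adapted curve *exactly* the empirical CDF of the trigger
parameter (in the strictness direction) restricted to
preference-satisfying fractions — an oracle the tests exploit. Preference
ties (`ADP_SCH == 0`) do not adapt: no dosimetric gain, no workload.

Grids default to `floor(min) … ceil(max)` of the observed differences,
padded one step on each side so both limits are realized, at 0.25 Gy for
dose metrics and 1 percentage point for volume metrics (configurable).
Integer-only action levels would hide the sub-integer levels where the
interesting nonlinearity lives.

Fractions whose trigger metric has non-valid status never enter a sweep
(the sweep refuses such metric/site pairs outright), mirroring their
exclusion from the summary tables.

## Synthetic metric cohort

The generator draws, per patient and metric: a Reference baseline
(nominal value + Gaussian patient offset, constant over the course), a
patient-level random intercept for SCH−REF, skew-normal fraction noise,
and Gaussian ADP−REF noise. Defaults encode the reported structure of an
Ethos pelvic program: coverage SCH−REF left-skewed (shape −4) with
site-specific median/IQR targets; ADP−REF tight around zero; most OAR
metrics symmetric and zero-centred; the fossa-boost rectum/bowel slots
positively biased (the one OAR family that adaptation systematically
helps). The bladder and fossa-boost targets are taken from published
per-site summaries; the prostate+SV PTV D95 % row is the published example
(median −0.14 Gy, IQR 0.28 Gy, ADP−REF 0.00/0.01 Gy); the remaining
prostate+SV and SBRT rows are package defaults chosen once to be of like
magnitude, since per-metric summaries for those groups are not available.

**Calibration.** Writing the skew-normal as `δ|U| + √(1−δ²)V` shows that
adding an independent Gaussian intercept yields another skew-normal with
shape `δ_eff = δ/√(1+r²)` and scale `ω√(1+r²)` (`r` = intercept SD /
noise scale). The marginal SCH−REF law is therefore known in closed form,
and a single Brent solve on its IQR followed by a location shift makes the
generated marginal hit the configured median/IQR exactly — so
parameter-recovery tests test the pipeline, not a tautology. The patient
intercept defaults to a quarter of the target IQR and is shrunk if it
alone would exceed the target.

A configurable 5 % of fractions are forced to violate preference (adapted
no better than scheduled); on top of this, violations arise naturally
whenever the day's anatomy incidentally *improves* coverage (SCH−REF > 0)
— together these produce the sub-100 % adaptation ceiling. Volume-percent
values are clipped to [0, 100], which slightly distorts the configured
difference targets for V-metrics near their bounds; recovery assertions
therefore use the Gy-valued calibration metric.

Randomness: every patient has its own `SeedSequence(master, (site,
patient))` substream, so regenerating with more patients reproduces the
existing ones byte-for-byte.

What the generator does *not* emulate: correlations between metrics within
a fraction, autocorrelation across a patient's fractions, and any real
anatomy-to-dose mechanism. Passing tests demonstrate the analysis
machinery is correct under the configured statistical structure, not that
the structure matches any particular clinic.

## Voxel phantom

A spherical CTV (radius 20 mm) sits at the centre of a ~100 mm cube;
PTV = CTV + margin (default 4 mm, constrained to the clinical 3–5 mm
range); rectum, bladder, bowel and femurs are offset spheres. The dose is
the per-fraction prescription inside the PTV with a Gaussian penumbra
(σ = 4 mm) outside. Each fraction the whole anatomy shifts rigidly by a
Gaussian displacement (default SD 3 mm per axis), clipped so structures
stay on the grid and, by default, snapped to whole voxels. The Scheduled
dose is the unmoved dose field over the shifted anatomy; the Adapted dose
is the same field re-centred on the shifted target — a deliberate
caricature of replanning (no reoptimization, no deformation) whose payoff
is exactness: with voxel-snapped shifts, translation invariance makes the
Adapted metrics equal the Reference metrics *exactly*, so the
compromise/recovery signature (zero shift → SCH ≡ REF; shift ≫ margin →
scheduled coverage collapses, adapted coverage restored) is a sharp test
rather than a tolerance judgement. Setting `snap_to_grid=False` restores
continuous shifts at the cost of voxelization noise.

## Pipeline and I/O

Metric tables, difference tables and summaries are CSV (UTF-8, comma,
`.` decimal, 4-decimal values — finer than the 2 decimals used for
reporting views); each row carries its unit. Readers validate the dialect
and the content invariants (status vocabulary, values present iff valid,
Reference constant across a patient's fractions) and report offending line
numbers. Phantom grids are `.npy` arrays with JSON sidecar headers. Sweeps
serialize to JSON and tidy CSV; figures (proportion curve + percentile
bands) are rendered from already-computed results only. Every artifact is
a pure function of (config, seed); the manifest records config, seed,
versions and row counts. CLI exit codes: 0 ok, 2 configuration, 3 data,
4 internal.

## Problem sizes

Default analysis cohort: 16 patients / 320 fractions across the four
groups, matching the clinical cohort the framework is designed around.
Recovery and property tests use a single-metric prostate+SV cohort of
193 patients × 26 fractions (≈ 5000) with bootstrap standard errors, and
the DVH oracle cross-check uses 200 random grids up to 20³ voxels —
desk-scale sizes chosen so the whole suite runs in well under a minute.

## Known limitations

* No dose accumulation across fractions; each treatment is analyzed
  independently.
* Single-metric triggers only; no logical combinations of triggers and no
  cross-metric effect analysis.
* No DICOM-RT input; clinical data enters via the metric-table CSV.
* Descriptive statistics only — no inference on the difference
  distributions.
* Absolute dose-limit pass/fail reporting is out of scope; all triggers
  are relative to the Reference dose.
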