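# adaptrig

Trigger analysis for **daily online adaptive radiotherapy (ART)** in the
pelvis: when is re-planning a treatment on the anatomy of the day worth the
effort, and what does any given decision threshold buy dosimetrically?

## The problem

Online ART systems can, at every treatment fraction, recalculate the
original plan on the day's anatomy and re-optimize a new *adapted* plan.
Adapting every day is safe but expensive; never adapting wastes the
technology. A practical middle ground is an **adaptive trigger** — a
*parameter-value pair*: a monitored dosimetric quantity (the parameter) and
an action level (the value) at which adaptation is indicated.

`adaptrig` implements the analysis framework behind that idea. For each
treatment fraction it compares three dose distributions:

| | |
|---|---|
| **Reference (REF)** | original plan on the planning CT; constant over the course |
| **Scheduled (SCH)** | original plan recalculated on the daily anatomy |
| **Adapted (ADP)** | plan re-optimized on the daily anatomy |

A standardized set of 16 dose-volume metric slots (PTV D99 %, D95 %,
D0.03 cc; CTV D99 %, V100 %, D0.03 cc; bowel, bladder, rectum and femoral
constraints) is evaluated on each distribution, and the pairwise contrasts

```
SCH−REF   (what the anatomy change cost)
ADP−REF   (how well adaptation restores the plan)
ADP−SCH = (ADP−REF) − (SCH−REF)   (the gain from adapting)
```

are tabulated per fraction and summarized as median/IQR per site and
metric. Each contrast in each metric is then a candidate trigger parameter.
For a trigger value *v* the rule is direction-aware and inclusive:

* coverage metric (lower is worse): fire when `SCH−REF ≤ v`;
* OAR metric (higher is worse): fire when `SCH−REF ≥ v`;
* adapt when the trigger fires **and** the adapted plan is preferred
  (`ADP−SCH > 0` for coverage, `< 0` for OARs).

Sweeping *v* across the observed range yields the **proportion of
treatments adapted** — exactly the empirical CDF (in the strictness
direction) of the trigger parameter restricted to preference-satisfying
fractions — and the **counterfactual distribution** of metric changes, built
from ADP−REF values where the policy adapts and SCH−REF values elsewhere,
summarized by its 5/10/25/50/75/90/95th percentile bands.

Because per-fraction clinical dose data of this kind cannot be shared, the
package ships a **synthetic cohort generator**: four pelvic site/technique
groups (hypofractionated bladder 55 Gy/20 fx, post-operative prostate fossa
boost 19.8 Gy/11 fx, prostate + seminal vesicles 70.2 Gy/26 fx, prostate
SBRT 40 Gy/5 fx; 16 patients, 320 fractions) with left-skewed scheduled-dose
coverage deficits, tightly centred adapted-dose changes, patient-level
random effects and a sub-100 % adaptation ceiling — plus a voxel-level
**phantom** (spherical targets and organs, Gaussian-penumbra dose, rigid
daily shifts) that exercises the DVH engine end to end.

## Worked example

```python
import numpy as np
from adaptrig import cohort, differences, triggers

spec = cohort.default_cohort_spec(master_seed=7)
records = cohort.generate_metric_cohort(spec)        # 320-fraction metric table
diffs = differences.compute_differences(records)     # SCH−REF / ADP−REF / ADP−SCH
summary = differences.summarize_cohort(diffs)
print(summary[(summary.site == "prostate_sv_hypofx")
              & (summary.metric_id == "ptv_d95pct")].to_string(index=False))

sweep = triggers.sweep_trigger(diffs, "ptv_d95pct", site="prostate_sv_hypofx",
                               grid=np.array([-1.0, -0.5, -0.25]))
for v, p in zip(sweep.grid, sweep.proportion_adapted):
    print(f"trigger {v:+.2f} Gy -> {100*p:.1f}% of treatments adapted")
```

prints

```
              site  metric_id contrast    median      iqr   n
prostate_sv_hypofx ptv_d95pct  SCH_REF -0.166567 0.255115 208
prostate_sv_hypofx ptv_d95pct  ADP_REF -0.000815 0.009879 208
prostate_sv_hypofx ptv_d95pct  ADP_SCH  0.150909 0.266674 208
trigger -1.00 Gy -> 0.0% of treatments adapted
trigger -0.50 Gy -> 8.2% of treatments adapted
trigger -0.25 Gy -> 35.1% of treatments adapted
```

Read: over 208 prostate + SV fractions, daily anatomy typically costs
0.17 Gy of PTV D95 % (broad, left-skewed spread of 0.26 Gy), while the
adapted plan sits within 0.01 Gy of the planned value; and because the
coverage-deficit distribution is left-skewed, tightening the trigger from
−0.5 to −0.25 Gy (half the previous step) more than quadruples the fraction
of treatments adapted — strictness has strongly nonlinear workload
consequences.

The same analysis is available from the shell:

```bash
adaptrig run --mode metric-cohort --seed 7 --out results/run \
         --metric ptv_d95pct --contrast SCH_REF
```

which writes `metrics.csv`, `differences.csv`, `summary.csv`, per-site sweep
JSON/CSV, two-panel sweep figures and a reproducibility manifest.
`adaptrig simulate | metrics | diff | sweep` expose the individual stages,
including the voxel phantom (`--mode phantom`).

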