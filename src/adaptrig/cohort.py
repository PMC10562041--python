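"""Synthetic cohorts for exercising the trigger-analysis pipeline.

The clinical dataset behind this kind of analysis (per-fraction metric
values from a CBCT-guided online-ART program) is not publicly shareable, so
this module generates stand-ins at two levels of realism:

**Metric-level cohorts** (:func:`generate_metric_cohort`) draw per-fraction
Reference/Scheduled/Adapted metric value triples directly, with the
statistical structure such programs report:

* Scheduled-dose coverage changes (SCH-REF) are broad and left-skewed —
  anatomy usually degrades, occasionally improves, target coverage;
* Adapted-dose changes (ADP-REF) are tight and centred near zero — the
  reoptimized plan restores the planned dosimetry;
* patients differ systematically (a random intercept per patient and
  metric);
* a configurable minority of fractions have an adapted value *worse* than
  the scheduled one, so adaptation is never preferred for them and the
  proportion of treatments adapted cannot reach 100%;
* most OAR metrics behave randomly (symmetric, zero-centred), with a
  positively biased preset for the fossa-boost rectum/bowel pattern.

Fraction noise is skew-normal.  Given a target median and IQR for the
SCH-REF marginal, the skew-normal location and scale are calibrated
*jointly with* the patient-level Gaussian intercept (Gauss-Hermite
convolution + Brent root finding), so the generated marginal hits the
configured summary statistics and downstream recovery tests are genuine.

**Voxel-level phantoms** (:func:`generate_phantom_fraction`) build toy dose
grids and spherical structure masks that run the DVH engine end to end: a
uniform-core dose with Gaussian penumbra conforms to the PTV; each fraction
the anatomy shifts rigidly by a sampled displacement; the Scheduled dose is
the unmoved dose over the shifted anatomy, the Adapted dose is the same
dose field re-centred on the shifted target.  This is a deliberate
caricature of online replanning — no reoptimization, no deformation — but
it reproduces the compromise/recovery signature that the analysis is about.

All randomness derives from per-patient (or per-fraction) substreams of a
master seed, so cohorts are bit-reproducible and adding patients never
perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import skewnorm

from . import catalog
from .catalog import (
    DISTRIBUTIONS,
    METRIC_INDEX,
    METRIC_SLOTS,
    RECORD_COLUMNS,
    SITE_N_PATIENTS,
    SITE_REGISTRY,
    MetricStatus,
    Prescription,
    metric_status,
)
from .dvh import DoseGrid, StructureMask
from .errors import ConfigurationError

# normal inter-quartile width: IQR = _NORMAL_IQR * sigma
_NORMAL_IQR = 1.3489795003921634

#: Default left-skew shape for coverage metrics; OARs default to symmetric.
COVERAGE_SHAPE = -4.0


# --------------------------------------------------------------------------
# marginal calibration: patient intercept (Gaussian) + fraction noise
# (skew-normal) jointly hitting a target median / IQR
# --------------------------------------------------------------------------

def _effective_skewnorm(scale: float, shape: float, patient_sd: float) -> tuple[float, float]:
    """Exact skew-normal law of ``skewnorm(shape, 0, scale) + N(0, patient_sd)``.

    Writing the skew-normal as ``delta |U| + sqrt(1 - delta^2) V`` with
    independent standard normals U, V shows that adding an independent
    Gaussian only fattens the symmetric part, so the sum is again
    skew-normal.  Returns its ``(shape, scale)``; location is additive.
    """
    if scale <= 0:
        return 0.0, max(patient_sd, 0.0)
    delta = shape / np.sqrt(1.0 + shape * shape)
    r2 = (patient_sd / scale) ** 2
    delta_eff = delta / np.sqrt(1.0 + r2)
    shape_eff = delta_eff / np.sqrt(1.0 - delta_eff * delta_eff)
    return float(shape_eff), float(scale * np.sqrt(1.0 + r2))


def _mixture_cdf(x, loc: float, scale: float, shape: float, patient_sd: float) -> np.ndarray:
    """CDF of (N(0, patient_sd) + skewnorm(shape, loc, scale)), vectorized."""
    x = np.asarray(x, dtype=float)
    a_eff, w_eff = _effective_skewnorm(scale, shape, patient_sd)
    if w_eff <= 0:
        return (x >= loc).astype(float)
    return skewnorm.cdf(x, a_eff, loc=loc, scale=w_eff)


def _mixture_quantile(q: float, loc: float, scale: float, shape: float, patient_sd: float) -> float:
    a_eff, w_eff = _effective_skewnorm(scale, shape, patient_sd)
    if w_eff <= 0:
        return loc
    return float(skewnorm.ppf(q, a_eff, loc=loc, scale=w_eff))


@lru_cache(maxsize=512)
def calibrate_sch_noise(
    target_median: float, target_iqr: float, shape: float, patient_sd: float
) -> tuple[float, float, float]:
    """Solve (loc, scale) of the skew-normal fraction noise so the marginal
    SCH-REF distribution (including the patient intercept) has the target
    median and IQR.  Returns ``(loc, scale, patient_sd)``; the patient SD is
    shrunk if it alone would already exceed the target IQR.
    """
    if target_iqr < 0:
        raise ConfigurationError("target IQR must be >= 0")
    if target_iqr == 0:
        return (target_median, 0.0, 0.0)
    # the Gaussian intercept alone contributes _NORMAL_IQR * patient_sd of IQR
    max_sd = target_iqr / _NORMAL_IQR * 0.95
    patient_sd = min(patient_sd, max_sd)

    def iqr_of(scale: float) -> float:
        return _mixture_quantile(0.75, 0.0, scale, shape, patient_sd) - _mixture_quantile(
            0.25, 0.0, scale, shape, patient_sd
        )

    scale = brentq(lambda s: iqr_of(s) - target_iqr, 1e-12, 20.0 * target_iqr, xtol=1e-10)
    loc = target_median - _mixture_quantile(0.5, 0.0, scale, shape, patient_sd)
    return (float(loc), float(scale), float(patient_sd))


# --------------------------------------------------------------------------
# metric-level cohort specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricGenerator:
    """Generator parameters for one metric slot within one site group.

    All values are in the metric's native unit (Gy or percentage points).

    Parameters
    ----------
    ref_value, ref_sd
        Nominal Reference-dose metric value and its patient-to-patient SD
        (drawn once per patient, constant across that patient's fractions).
    sch_median, sch_iqr, sch_shape
        Target median/IQR of the SCH-REF marginal and the skew-normal shape
        of the fraction noise (negative = left tail, 0 = symmetric).
    patient_sd
        SD of the per-patient random intercept added to every SCH-REF draw.
    adp_median, adp_iqr
        Centre and IQR of the (Gaussian) ADP-REF changes.
    preference_violation_rate
        Fraction of treatments forced to have the adapted value no better
        than the scheduled one (models e.g. renormalization undoing an
        incidental coverage gain).
    bounds
        Optional (lo, hi) clip applied to the generated metric values;
        volume-percent metrics use (0, 100).
    """

    ref_value: float
    ref_sd: float
    sch_median: float
    sch_iqr: float
    sch_shape: float
    patient_sd: float
    adp_median: float
    adp_iqr: float
    preference_violation_rate: float = 0.05
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("ref_sd", "sch_iqr", "patient_sd", "adp_iqr"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.preference_violation_rate <= 1:
            raise ConfigurationError("preference_violation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SiteCohortSpec:
    """One site group: patient count and per-metric generators.

    The per-patient fraction count is pinned to the site's prescription
    (20/11/26/5 for the four shipped regimens).
    """

    site_label: str
    n_patients: int
    metrics: Mapping[str, MetricGenerator]

    def __post_init__(self) -> None:
        if self.site_label not in SITE_REGISTRY:
            raise ConfigurationError(f"unknown site {self.site_label!r}")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for metric_id in self.metrics:
            if metric_id not in METRIC_INDEX:
                raise ConfigurationError(f"unknown metric {metric_id!r}")
            if metric_status(self.site_label, metric_id) is not MetricStatus.VALID:
                raise ConfigurationError(
                    f"metric {metric_id!r} is not valid for site {self.site_label!r}"
                )

    @property
    def n_fractions(self) -> int:
        return SITE_REGISTRY[self.site_label].n_fractions


@dataclass(frozen=True)
class CohortSpec:
    """A multi-site synthetic cohort, fully reproducible from ``master_seed``."""

    sites: tuple[SiteCohortSpec, ...]
    master_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "sites": [
                {
                    "site_label": s.site_label,
                    "n_patients": s.n_patients,
                    "metrics": {mid: asdict(g) for mid, g in s.metrics.items()},
                }
                for s in self.sites
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortSpec":
        sites = []
        for s in data["sites"]:
            metrics = {}
            for mid, g in s["metrics"].items():
                g = dict(g)
                if g.get("bounds") is not None:
                    g["bounds"] = tuple(g["bounds"])
                metrics[mid] = MetricGenerator(**g)
            sites.append(SiteCohortSpec(s["site_label"], int(s["n_patients"]), metrics))
        return cls(sites=tuple(sites), master_seed=int(data.get("master_seed", 0)))


# --------------------------------------------------------------------------
# default cohort: the four shipped pelvic site groups
# --------------------------------------------------------------------------

# Per site: metric_id -> (sch_median, sch_iqr, sch_shape, adp_median, adp_iqr).
# Bladder-hypofx and fossa-boost targets follow published per-site summaries
# of an Ethos pelvic program; the prostate+SV PTV D95% row is the reported
# example (-0.14 Gy median, 0.28 Gy IQR; ADP-REF 0.00/0.01).  Remaining
# prostate+SV and SBRT rows are package defaults chosen to be of like
# magnitude (see docs/methods.md).
_DEFAULT_TARGETS: dict[str, dict[str, tuple[float, float, float, float, float]]] = {
    "bladder_hypofx": {
        "ptv_d99pct": (-0.87, 0.74, COVERAGE_SHAPE, -0.01, 0.02),
        "ptv_d95pct": (-0.42, 0.59, COVERAGE_SHAPE, 0.00, 0.02),
        "ptv_d0.03cc": (0.03, 0.13, 0.0, -0.01, 0.02),
        "ctv_d99pct": (-0.31, 0.65, COVERAGE_SHAPE, 0.00, 0.01),
        "ctv_v100pct": (-4.50, 14.10, COVERAGE_SHAPE, 0.00, 0.00),
        "ctv_d0.03cc": (0.05, 0.06, 0.0, 0.01, 0.03),
        "bowel_d2cc": (0.07, 0.27, 0.0, 0.00, 0.10),
        "bowel_v55gy": (0.30, 1.73, 4.0, 0.00, 0.33),
        "bowel_d0.03cc": (0.06, 0.12, 0.0, 0.00, 0.08),
        "rectum_v40gy": (0.00, 0.10, 0.0, 0.00, 0.30),
        "rectum_d0.03cc": (0.21, 0.35, 0.0, 0.11, 0.27),
        "femur_d0.03cc": (0.00, 0.09, 0.0, 0.05, 0.23),
    },
    "prostate_fossa_boost": {
        "ptv_d99pct": (-0.05, 0.15, COVERAGE_SHAPE, 0.01, 0.03),
        "ptv_d95pct": (-0.02, 0.04, COVERAGE_SHAPE, 0.00, 0.01),
        "ptv_d0.03cc": (0.02, 0.02, 0.0, 0.02, 0.04),
        "ctv_d99pct": (-0.01, 0.03, COVERAGE_SHAPE, 0.00, 0.01),
        "ctv_v100pct": (-2.65, 7.53, COVERAGE_SHAPE, -0.05, 1.75),
        "ctv_d0.03cc": (0.01, 0.02, 0.0, -0.01, 0.05),
        "bowel_d2cc": (0.09, 0.20, 0.0, 0.05, 0.07),
        "bowel_v55gy": (0.00, 0.00, 0.0, 0.00, 0.00),
        "bowel_d0.03cc": (0.44, 0.97, 0.0, 0.18, 0.16),
        "bladder_v65gy": (2.05, 9.55, 4.0, 3.25, 10.50),
        "bladder_v40gy": (3.05, 18.50, 4.0, 2.15, 16.90),
        "bladder_d0.03cc": (0.00, 0.03, 0.0, 0.00, 0.04),
        "rectum_v65gy": (4.00, 4.43, 4.0, -0.45, 3.05),
        "rectum_v40gy": (6.85, 6.73, 4.0, 0.90, 0.85),
        "rectum_d0.03cc": (0.03, 0.07, 0.0, -0.01, 0.02),
        "femur_d0.03cc": (0.01, 0.05, 0.0, 0.00, 0.14),
    },
    "prostate_sv_hypofx": {
        "ptv_d99pct": (-0.25, 0.45, COVERAGE_SHAPE, 0.00, 0.02),
        "ptv_d95pct": (-0.14, 0.28, COVERAGE_SHAPE, 0.00, 0.01),
        "ptv_d0.03cc": (0.02, 0.10, 0.0, 0.00, 0.03),
        "ctv_d99pct": (-0.10, 0.25, COVERAGE_SHAPE, 0.00, 0.01),
        "ctv_v100pct": (-3.00, 9.00, COVERAGE_SHAPE, 0.00, 0.40),
        "ctv_d0.03cc": (0.03, 0.06, 0.0, 0.00, 0.03),
        "bowel_d2cc": (0.05, 0.20, 0.0, 0.00, 0.08),
        "bowel_v55gy": (0.10, 0.80, 4.0, 0.00, 0.25),
        "bowel_d0.03cc": (0.05, 0.15, 0.0, 0.00, 0.08),
        "bladder_v65gy": (0.50, 3.00, 4.0, 0.00, 1.00),
        "bladder_v40gy": (1.00, 6.00, 0.0, 0.00, 2.00),
        "bladder_d0.03cc": (0.01, 0.05, 0.0, 0.00, 0.04),
        "rectum_v65gy": (0.20, 2.00, 4.0, 0.00, 0.80),
        "rectum_v40gy": (0.50, 4.00, 0.0, 0.00, 1.50),
        "rectum_d0.03cc": (0.05, 0.15, 0.0, 0.00, 0.06),
        "femur_d0.03cc": (0.00, 0.08, 0.0, 0.02, 0.15),
    },
    "prostate_sbrt": {
        "ptv_d99pct": (-0.60, 1.00, COVERAGE_SHAPE, -0.02, 0.06),
        "ptv_d95pct": (-0.30, 0.60, COVERAGE_SHAPE, -0.01, 0.04),
        "ptv_d0.03cc": (0.05, 0.25, 0.0, 0.00, 0.08),
        "ctv_d99pct": (-0.25, 0.60, COVERAGE_SHAPE, 0.00, 0.04),
        "ctv_v100pct": (-3.50, 10.00, COVERAGE_SHAPE, 0.00, 0.60),
        "ctv_d0.03cc": (0.05, 0.15, 0.0, 0.00, 0.06),
        "bowel_d2cc": (0.05, 0.30, 0.0, 0.00, 0.10),
        "bowel_d0.03cc": (0.05, 0.20, 0.0, 0.00, 0.10),
        "bladder_v40gy": (1.00, 5.00, 0.0, 0.00, 2.00),
        "bladder_d0.03cc": (0.02, 0.10, 0.0, 0.00, 0.06),
        "rectum_v40gy": (0.50, 4.00, 0.0, 0.00, 1.50),
        "rectum_d0.03cc": (0.05, 0.20, 0.0, 0.00, 0.08),
        "femur_d0.03cc": (0.00, 0.10, 0.0, 0.02, 0.15),
    },
}

# Reference-dose baselines: D-metrics as a multiple of the per-fraction
# prescription, V-metrics as absolute percents.
_REF_FACTORS: dict[str, float] = {
    "ptv_d99pct": 0.97,
    "ptv_d95pct": 0.99,
    "ptv_d0.03cc": 1.06,
    "ctv_d99pct": 1.00,
    "ctv_d0.03cc": 1.06,
    "bowel_d2cc": 0.55,
    "bowel_d0.03cc": 0.85,
    "bladder_d0.03cc": 1.02,
    "rectum_d0.03cc": 1.02,
    "femur_d0.03cc": 0.45,
}
_REF_PERCENTS: dict[str, tuple[float, float]] = {
    "ctv_v100pct": (99.5, 0.4),
    "bowel_v55gy": (1.0, 0.5),
    "bladder_v65gy": (10.0, 3.0),
    "bladder_v40gy": (35.0, 8.0),
    "rectum_v65gy": (8.0, 3.0),
    "rectum_v40gy": (30.0, 8.0),
}


def default_metric_generator(
    site_label: str, metric_id: str, preference_violation_rate: float = 0.05
) -> MetricGenerator:
    """The shipped generator for one site/metric pair."""
    targets = _DEFAULT_TARGETS[site_label]
    if metric_id not in targets:
        raise ConfigurationError(f"no default generator for {metric_id!r} at {site_label!r}")
    sch_median, sch_iqr, shape, adp_median, adp_iqr = targets[metric_id]
    rx = SITE_REGISTRY[site_label]
    spec = METRIC_INDEX[metric_id]
    if spec.unit == "Gy":
        ref_value = _REF_FACTORS[metric_id] * rx.dose_per_fraction
        ref_sd = 0.01 * rx.dose_per_fraction
        bounds = None
    else:
        ref_value, ref_sd = _REF_PERCENTS[metric_id]
        bounds = (0.0, 100.0)
    return MetricGenerator(
        ref_value=ref_value,
        ref_sd=ref_sd,
        sch_median=sch_median,
        sch_iqr=sch_iqr,
        sch_shape=shape,
        patient_sd=0.25 * sch_iqr,
        adp_median=adp_median,
        adp_iqr=adp_iqr,
        preference_violation_rate=preference_violation_rate,
        bounds=bounds,
    )


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """The shipped four-site cohort: 4 + 2 + 8 + 2 patients, 320 fractions."""
    sites = []
    for site_label in catalog.SITE_ORDER:
        metrics = {
            mid: default_metric_generator(site_label, mid) for mid in _DEFAULT_TARGETS[site_label]
        }
        sites.append(SiteCohortSpec(site_label, SITE_N_PATIENTS[site_label], metrics))
    return CohortSpec(sites=tuple(sites), master_seed=master_seed)


def calibration_cohort_spec(
    n_patients: int = 193, master_seed: int = 0, site_label: str = "prostate_sv_hypofx"
) -> CohortSpec:
    """A single-metric cohort for parameter-recovery checks: the prostate+SV
    PTV D95% generator (median -0.14 Gy, IQR 0.28 Gy) at ``n_patients`` x 26
    fractions (193 patients ~ 5000 fractions)."""
    metrics = {"ptv_d95pct": default_metric_generator(site_label, "ptv_d95pct")}
    return CohortSpec(
        sites=(SiteCohortSpec(site_label, n_patients, metrics),), master_seed=master_seed
    )


# --------------------------------------------------------------------------
# metric-level generation
# --------------------------------------------------------------------------


def _patient_rng(master_seed: int, site_index: int, patient_index: int) -> np.random.Generator:
    # Fixed spawn keys: adding sites/patients never perturbs existing streams.
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(site_index, patient_index))
    )


def generate_metric_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-fraction metric table (the metric-table CSV dialect).

    Non-valid metric slots of each site are emitted with their status and
    empty values, exactly as a clinical export would carry them.
    """
    all_rows: list[pd.DataFrame] = []
    for site_index, site_spec in enumerate(spec.sites):
        rx = SITE_REGISTRY[site_spec.site_label]
        nfx = rx.n_fractions
        for p in range(site_spec.n_patients):
            rng = _patient_rng(spec.master_seed, site_index, p)
            patient_id = f"{site_spec.site_label}_{p:03d}"
            frames = []
            for metric_spec in METRIC_SLOTS:
                mid = metric_spec.metric_id
                status = metric_status(site_spec.site_label, mid)
                if status is not MetricStatus.VALID or mid not in site_spec.metrics:
                    stat = status if status is not MetricStatus.VALID else MetricStatus.VALID
                    if stat is MetricStatus.VALID:
                        continue  # valid but unconfigured: omit silently
                    for structure in metric_spec.structures:
                        frames.append(
                            pd.DataFrame(
                                {
                                    "patient_id": patient_id,
                                    "fraction_index": np.arange(nfx),
                                    "site": site_spec.site_label,
                                    "structure": structure,
                                    "metric_id": mid,
                                    "status": stat.value,
                                    "ref_value": np.nan,
                                    "sch_value": np.nan,
                                    "adp_value": np.nan,
                                    "unit": metric_spec.unit,
                                }
                            )
                        )
                    continue
                gen = site_spec.metrics[mid]
                for structure in metric_spec.structures:
                    frames.append(
                        _draw_metric_block(
                            rng, gen, metric_spec, structure, patient_id, site_spec.site_label, nfx
                        )
                    )
            all_rows.extend(frames)
    if not all_rows:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(all_rows, ignore_index=True)[RECORD_COLUMNS]


def _draw_metric_block(
    rng: np.random.Generator,
    gen: MetricGenerator,
    metric_spec,
    structure: str,
    patient_id: str,
    site_label: str,
    nfx: int,
) -> pd.DataFrame:
    loc, scale, patient_sd = calibrate_sch_noise(
        gen.sch_median, gen.sch_iqr, gen.sch_shape, gen.patient_sd
    )
    ref = gen.ref_value + (rng.normal(0.0, gen.ref_sd) if gen.ref_sd > 0 else 0.0)
    bias = rng.normal(0.0, patient_sd) if patient_sd > 0 else 0.0
    if scale > 0:
        noise = skewnorm.rvs(gen.sch_shape, loc=loc, scale=scale, size=nfx, random_state=rng)
    else:
        noise = np.full(nfx, loc)
    sch_delta = bias + noise
    adp_sigma = gen.adp_iqr / _NORMAL_IQR
    adp_delta = (
        rng.normal(gen.adp_median, adp_sigma, size=nfx)
        if adp_sigma > 0
        else np.full(nfx, gen.adp_median)
    )
    # forced preference violations: adapted no better than scheduled
    viol = rng.random(nfx) < gen.preference_violation_rate
    if viol.any():
        eps = np.abs(rng.normal(0.0, adp_sigma if adp_sigma > 0 else 0.0, size=nfx))
        worse = (
            sch_delta - eps
            if metric_spec.direction == "higher_better"
            else sch_delta + eps
        )
        adp_delta = np.where(viol, worse, adp_delta)

    ref_vals = np.full(nfx, ref)
    sch_vals = ref + sch_delta
    adp_vals = ref + adp_delta
    if gen.bounds is not None:
        lo, hi = gen.bounds
        ref_vals = np.clip(ref_vals, lo, hi)
        sch_vals = np.clip(sch_vals, lo, hi)
        adp_vals = np.clip(adp_vals, lo, hi)
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "fraction_index": np.arange(nfx),
            "site": site_label,
            "structure": structure,
            "metric_id": metric_spec.metric_id,
            "status": MetricStatus.VALID.value,
            "ref_value": ref_vals,
            "sch_value": sch_vals,
            "adp_value": adp_vals,
            "unit": metric_spec.unit,
        }
    )


# --------------------------------------------------------------------------
# voxel-level phantom fractions
# --------------------------------------------------------------------------

#: Structure sphere layout: name -> (offset_mm (z, y, x) from grid centre, radius_mm, role).
_DEFAULT_LAYOUT: dict[str, tuple[tuple[float, float, float], float, str]] = {
    "rectum": ((0.0, 28.0, 0.0), 10.0, "oar"),
    "bladder": ((0.0, -28.0, 0.0), 12.0, "oar"),
    "bowel": ((28.0, 0.0, 0.0), 12.0, "oar"),
    "femur_l": ((0.0, 0.0, -32.0), 8.0, "oar"),
    "femur_r": ((0.0, 0.0, 32.0), 8.0, "oar"),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and motion model of a toy pelvic phantom patient.

    The CTV is a sphere at the grid centre; the PTV expands it by ``margin``
    (kept within the 3-5 mm clinical range).  Each fraction the whole
    anatomy shifts rigidly by a Gaussian displacement, snapped to the voxel
    grid by default so that re-centring the dose restores the Reference
    dosimetry exactly.
    """

    site_label: str = "prostate_sv_hypofx"
    shape: tuple[int, int, int] = (40, 40, 40)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    ctv_radius: float = 20.0
    margin: float = 4.0
    penumbra_sigma: float = 4.0
    displacement_sd: tuple[float, float, float] = (3.0, 3.0, 3.0)
    snap_to_grid: bool = True
    seed: int = 0
    layout: Mapping[str, tuple[tuple[float, float, float], float, str]] = field(
        default_factory=lambda: dict(_DEFAULT_LAYOUT)
    )

    def __post_init__(self) -> None:
        if self.site_label not in SITE_REGISTRY:
            raise ConfigurationError(f"unknown site {self.site_label!r}")
        if not 3.0 <= self.margin <= 5.0:
            raise ConfigurationError("CTV-to-PTV margin must be within 3-5 mm")
        if any(s <= 0 for s in self.displacement_sd) and any(
            s < 0 for s in self.displacement_sd
        ):
            raise ConfigurationError("displacement SDs must be >= 0")

    @property
    def prescription(self) -> Prescription:
        return SITE_REGISTRY[self.site_label]

    @property
    def ptv_radius(self) -> float:
        return self.ctv_radius + self.margin


def _axis_coords(spec: PhantomSpec):
    return [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]


def _dist2(spec: PhantomSpec, centre):
    z, y, x = _axis_coords(spec)
    return (
        (z - centre[0])[:, None, None] ** 2
        + (y - centre[1])[None, :, None] ** 2
        + (x - centre[2])[None, None, :] ** 2
    )


def _sphere(spec: PhantomSpec, centre, radius: float) -> np.ndarray:
    return _dist2(spec, centre) <= radius**2


def _dose_field(spec: PhantomSpec, centre) -> np.ndarray:
    """Per-fraction prescription inside the PTV, Gaussian penumbra outside."""
    dpf = spec.prescription.dose_per_fraction
    r = np.sqrt(_dist2(spec, centre))
    excess = np.maximum(r - spec.ptv_radius, 0.0)
    return dpf * np.exp(-(excess**2) / (2.0 * spec.penumbra_sigma**2))


def _grid_centre(spec: PhantomSpec) -> np.ndarray:
    return np.array([(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)])


def _max_shift(spec: PhantomSpec) -> np.ndarray:
    """Largest per-axis shift keeping every structure inside the grid."""
    half = np.array([(n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)])
    worst = max(
        [spec.ptv_radius] + [np.max(np.abs(off)) + r for off, r, _ in spec.layout.values()]
    )
    return np.maximum(half - worst - float(np.max(spec.spacing)), 0.0)


def sample_displacement(spec: PhantomSpec, fraction_index: int) -> np.ndarray:
    """The fraction's rigid anatomy displacement (mm, (z, y, x)); clipped to
    keep all structures on the grid and snapped to whole voxels if configured."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(fraction_index,))
    )
    shift = rng.normal(0.0, spec.displacement_sd, size=3)
    limit = _max_shift(spec)
    shift = np.clip(shift, -limit, limit)
    if spec.snap_to_grid:
        shift = np.round(shift / np.asarray(spec.spacing)) * np.asarray(spec.spacing)
    return shift


def _mask_set(spec: PhantomSpec, shift: np.ndarray) -> dict[str, StructureMask]:
    centre = _grid_centre(spec) + shift
    masks = {
        "ctv": StructureMask(_sphere(spec, centre, spec.ctv_radius), "ctv", "target"),
        "ptv": StructureMask(_sphere(spec, centre, spec.ptv_radius), "ptv", "target"),
    }
    for name, (offset, radius, role) in spec.layout.items():
        masks[name] = StructureMask(_sphere(spec, centre + np.asarray(offset), radius), name, role)
    return masks


def generate_phantom_fraction(
    spec: PhantomSpec,
    fraction_index: int,
    displacement: np.ndarray | None = None,
) -> tuple[dict[str, DoseGrid], dict[str, dict[str, StructureMask]]]:
    """One treatment fraction of the phantom patient.

    Returns ``(grids, masks)`` keyed by distribution: REF is the planned
    dose over the planning anatomy; SCH keeps the planned dose field but
    moves the anatomy; ADP re-centres the dose on the moved target.
    ``displacement`` overrides the sampled shift (mm, (z, y, x)).
    """
    shift = (
        sample_displacement(spec, fraction_index)
        if displacement is None
        else np.asarray(displacement, dtype=float)
    )
    centre = _grid_centre(spec)
    spacing = spec.spacing
    ref_dose = DoseGrid(_dose_field(spec, centre), spacing)
    adp_dose = DoseGrid(_dose_field(spec, centre + shift), spacing)
    ref_masks = _mask_set(spec, np.zeros(3))
    day_masks = _mask_set(spec, shift)
    grids = {"REF": ref_dose, "SCH": ref_dose, "ADP": adp_dose}
    masks = {"REF": ref_masks, "SCH": day_masks, "ADP": day_masks}
    return grids, masks


def phantom_metric_records(
    spec: PhantomSpec,
    patient_id: str = "phantom_000",
    n_fractions: int | None = None,
    bin_width: float | None = None,
) -> pd.DataFrame:
    """Evaluate every fraction of a phantom patient into a metric table."""
    rx = spec.prescription
    nfx = rx.n_fractions if n_fractions is None else n_fractions
    kwargs = {} if bin_width is None else {"bin_width": bin_width}
    frames = []
    for f in range(nfx):
        grids, masks = generate_phantom_fraction(spec, f)
        frames.append(
            catalog.evaluate_fraction(
                grids, masks, rx, patient_id=patient_id, fraction_index=f, **kwargs
            )
        )
    return pd.concat(frames, ignore_index=True)
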