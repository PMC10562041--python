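"""Standardized dose-metric catalog for pelvic online-ART trigger analysis.

The analysis compares three dose distributions per treatment fraction:

* **Reference (REF)** — the original plan on the planning anatomy; constant
  across a patient's fractions,
* **Scheduled (SCH)** — the original plan recalculated on the daily anatomy,
* **Adapted (ADP)** — a plan reoptimized on the daily anatomy.

A fixed set of 16 metric slots characterizes targets and organs at risk
across four pelvic site/technique groups regardless of the individual
prescriptions: PTV D99%/D95%/D0.03cc, CTV D99%/V100%/D0.03cc, bowel
D2cc/V55Gy/D0.03cc, bladder V65Gy/V40Gy/D0.03cc, rectum
V65Gy/V40Gy/D0.03cc, and femoral head-and-neck D0.03cc (one slot evaluated
on both femurs, summarized jointly).

Because every analyzed dose distribution is a single-fraction dose, the
cumulative VxGy limits are scaled by the number of treatments (e.g. V40Gy
under a 20-fraction course is evaluated at 40/20 = 2 Gy), and Vx% uses the
per-fraction prescription dose.

Per site, a slot may be flagged ``not_appropriate`` (the constraint makes no
sense given the target, e.g. bladder-as-OAR limits when the bladder is the
target) or ``inadequate_dose`` (the prescription cannot meaningfully reach
the limit).  Non-valid slots carry no values and are excluded from
difference and trigger analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import dvh
from .dvh import DoseGrid, DVHCurve, StructureMask
from .errors import (
    ConfigurationError,
    DataCompletenessError,
    DomainError,
    UsageError,
)

DISTRIBUTIONS = ("REF", "SCH", "ADP")

RECORD_COLUMNS = [
    "patient_id",
    "fraction_index",
    "site",
    "structure",
    "metric_id",
    "status",
    "ref_value",
    "sch_value",
    "adp_value",
    "unit",
]


class MetricStatus(str, enum.Enum):
    """Applicability of a metric slot for a given site."""

    VALID = "valid"
    NOT_APPROPRIATE = "not_appropriate"
    INADEQUATE_DOSE = "inadequate_dose"


@dataclass(frozen=True)
class Prescription:
    """A fractionation regimen: total dose, number of daily treatments, dose/fraction."""

    total_dose: float
    n_fractions: int
    dose_per_fraction: float
    site_label: str

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ConfigurationError("n_fractions must be >= 1")
        if abs(self.dose_per_fraction * self.n_fractions - self.total_dose) > 0.01:
            raise ConfigurationError(
                f"{self.site_label}: dose_per_fraction x n_fractions "
                f"({self.dose_per_fraction} x {self.n_fractions}) does not match "
                f"total_dose {self.total_dose} within 0.01 Gy"
            )


#: The four shipped site/technique groups.
SITE_REGISTRY: dict[str, Prescription] = {
    "bladder_hypofx": Prescription(55.0, 20, 2.75, "bladder_hypofx"),
    "prostate_fossa_boost": Prescription(19.8, 11, 1.8, "prostate_fossa_boost"),
    "prostate_sv_hypofx": Prescription(70.2, 26, 2.7, "prostate_sv_hypofx"),
    "prostate_sbrt": Prescription(40.0, 5, 8.0, "prostate_sbrt"),
}

SITE_ORDER = tuple(SITE_REGISTRY)

#: Clinical patient counts per site group (cohort of 16, 320 fractions).
SITE_N_PATIENTS: dict[str, int] = {
    "bladder_hypofx": 4,
    "prostate_fossa_boost": 2,
    "prostate_sv_hypofx": 8,
    "prostate_sbrt": 2,
}


@dataclass(frozen=True)
class MetricSpec:
    """One metric slot: the primitive, its parameter, unit and direction.

    ``direction`` is ``"higher_better"`` for coverage metrics (a decrease is
    a compromise) and ``"lower_better"`` for OAR/hot-spot metrics (an
    increase is a compromise).  ``scale_per_fraction`` marks VxGy limits
    whose dose threshold is divided by the number of treatments.
    """

    metric_id: str
    label: str
    structures: tuple[str, ...]
    kind: str  # D_relvol | D_absvol | V_reldose | V_absdose
    parameter: float
    unit: str  # "Gy" | "%"
    direction: str
    scale_per_fraction: bool = False

    def __post_init__(self) -> None:
        d_kinds = {"D_relvol", "D_absvol"}
        v_kinds = {"V_reldose", "V_absdose"}
        if self.kind in d_kinds and self.unit != "Gy":
            raise ConfigurationError(f"{self.metric_id}: D-metrics return Gy")
        if self.kind in v_kinds and self.unit != "%":
            raise ConfigurationError(f"{self.metric_id}: V-metrics return percent")
        if self.kind not in d_kinds | v_kinds:
            raise ConfigurationError(f"{self.metric_id}: unknown kind {self.kind!r}")
        if self.direction not in ("higher_better", "lower_better"):
            raise ConfigurationError(f"{self.metric_id}: bad direction {self.direction!r}")


def _slot(mid, label, structures, kind, parameter, unit, direction, scaled=False):
    return MetricSpec(mid, label, tuple(structures), kind, parameter, unit, direction, scaled)


#: The 16 metric slots, in reporting order.  Target hot spots (D0.03cc) are
#: treated as lower-better by clinical convention (the direction the source
#: analysis leaves implicit); override via a custom MetricSpec if needed.
METRIC_SLOTS: tuple[MetricSpec, ...] = (
    _slot("ptv_d99pct", "D99%", ["ptv"], "D_relvol", 99.0, "Gy", "higher_better"),
    _slot("ptv_d95pct", "D95%", ["ptv"], "D_relvol", 95.0, "Gy", "higher_better"),
    _slot("ptv_d0.03cc", "D0.03cc", ["ptv"], "D_absvol", 0.03, "Gy", "lower_better"),
    _slot("ctv_d99pct", "D99%", ["ctv"], "D_relvol", 99.0, "Gy", "higher_better"),
    _slot("ctv_v100pct", "V100%", ["ctv"], "V_reldose", 100.0, "%", "higher_better"),
    _slot("ctv_d0.03cc", "D0.03cc", ["ctv"], "D_absvol", 0.03, "Gy", "lower_better"),
    _slot("bowel_d2cc", "D2cc", ["bowel"], "D_absvol", 2.0, "Gy", "lower_better"),
    _slot("bowel_v55gy", "V55Gy", ["bowel"], "V_absdose", 55.0, "%", "lower_better", True),
    _slot("bowel_d0.03cc", "D0.03cc", ["bowel"], "D_absvol", 0.03, "Gy", "lower_better"),
    _slot("bladder_v65gy", "V65Gy", ["bladder"], "V_absdose", 65.0, "%", "lower_better", True),
    _slot("bladder_v40gy", "V40Gy", ["bladder"], "V_absdose", 40.0, "%", "lower_better", True),
    _slot("bladder_d0.03cc", "D0.03cc", ["bladder"], "D_absvol", 0.03, "Gy", "lower_better"),
    _slot("rectum_v65gy", "V65Gy", ["rectum"], "V_absdose", 65.0, "%", "lower_better", True),
    _slot("rectum_v40gy", "V40Gy", ["rectum"], "V_absdose", 40.0, "%", "lower_better", True),
    _slot("rectum_d0.03cc", "D0.03cc", ["rectum"], "D_absvol", 0.03, "Gy", "lower_better"),
    _slot("femur_d0.03cc", "D0.03cc", ["femur_l", "femur_r"], "D_absvol", 0.03, "Gy", "lower_better"),
)

METRIC_INDEX: dict[str, MetricSpec] = {m.metric_id: m for m in METRIC_SLOTS}

METRIC_ORDER = tuple(METRIC_INDEX)

#: All structures any slot may require.
STRUCTURES = ("ptv", "ctv", "bowel", "bladder", "rectum", "femur_l", "femur_r")

# Per-site status overrides (everything else is valid).  The bladder-as-target
# course invalidates bladder OAR constraints and cannot reach the rectum 65 Gy
# limit; the 40 Gy SBRT course cannot reach the 55/65 Gy cumulative limits.
_STATUS_OVERRIDES: dict[str, dict[str, MetricStatus]] = {
    "bladder_hypofx": {
        "bladder_v65gy": MetricStatus.NOT_APPROPRIATE,
        "bladder_v40gy": MetricStatus.NOT_APPROPRIATE,
        "bladder_d0.03cc": MetricStatus.NOT_APPROPRIATE,
        "rectum_v65gy": MetricStatus.INADEQUATE_DOSE,
    },
    "prostate_fossa_boost": {},
    "prostate_sv_hypofx": {},
    "prostate_sbrt": {
        "bowel_v55gy": MetricStatus.INADEQUATE_DOSE,
        "bladder_v65gy": MetricStatus.INADEQUATE_DOSE,
        "rectum_v65gy": MetricStatus.INADEQUATE_DOSE,
    },
}


def metric_status(site_label: str, metric_id: str) -> MetricStatus:
    """Applicability status of a metric slot for a site (a function of site only)."""
    if site_label not in SITE_REGISTRY:
        raise ConfigurationError(f"unknown site {site_label!r}")
    if metric_id not in METRIC_INDEX:
        raise ConfigurationError(f"unknown metric {metric_id!r}")
    return _STATUS_OVERRIDES[site_label].get(metric_id, MetricStatus.VALID)


def standard_metric_set(
    prescription: Prescription,
) -> list[tuple[MetricSpec, MetricStatus]]:
    """All 16 metric slots with their site-specific statuses, in reporting order."""
    if prescription.site_label not in SITE_REGISTRY:
        raise ConfigurationError(f"unknown site {prescription.site_label!r}")
    return [(m, metric_status(prescription.site_label, m.metric_id)) for m in METRIC_SLOTS]


def per_fraction_threshold(
    threshold_gy: float,
    prescription: Prescription,
    metric: MetricSpec | None = None,
) -> float:
    """Scale a cumulative VxGy dose limit to its per-treatment equivalent.

    A 40 Gy limit under a 20-fraction course becomes 2 Gy per fraction.
    When ``metric`` is given it must be a slot flagged ``scale_per_fraction``.
    """
    if metric is not None and not metric.scale_per_fraction:
        raise UsageError(f"{metric.metric_id} is not a per-fraction-scaled metric")
    if threshold_gy <= 0:
        raise DomainError("threshold must be positive")
    return threshold_gy / prescription.n_fractions


def relative_dose_threshold(x_percent: float, prescription: Prescription) -> float:
    """Dose (Gy) corresponding to ``x`` percent of the per-fraction prescription."""
    if x_percent <= 0:
        raise DomainError("relative dose must be positive")
    return x_percent / 100.0 * prescription.dose_per_fraction


def metric_value(curve: DVHCurve, spec: MetricSpec, prescription: Prescription) -> float:
    """Evaluate one metric slot on a DVH curve."""
    if spec.kind == "D_relvol":
        return dvh.dose_at_relative_volume(curve, spec.parameter)
    if spec.kind == "D_absvol":
        return dvh.dose_at_absolute_volume(curve, spec.parameter)
    if spec.kind == "V_reldose":
        return dvh.volume_at_dose(curve, relative_dose_threshold(spec.parameter, prescription))
    # V_absdose: cumulative limit scaled to this fractionation
    return dvh.volume_at_dose(
        curve, per_fraction_threshold(spec.parameter, prescription, metric=spec)
    )


MaskSet = Mapping[str, StructureMask]


def _masks_per_distribution(masks) -> dict[str, MaskSet]:
    """Accept either one shared mask set or one per dose distribution."""
    if all(k in DISTRIBUTIONS for k in masks):
        return {d: masks[d] for d in DISTRIBUTIONS}
    return {d: masks for d in DISTRIBUTIONS}


def evaluate_fraction(
    grids: Mapping[str, DoseGrid],
    masks,
    prescription: Prescription,
    *,
    patient_id: str = "p000",
    fraction_index: int = 0,
    statuses: Mapping[str, MetricStatus] | None = None,
    bin_width: float = dvh.DEFAULT_BIN_WIDTH_GY,
) -> pd.DataFrame:
    """Compute the full metric table of one treatment fraction.

    Parameters
    ----------
    grids
        One :class:`DoseGrid` per distribution, keys ``REF``/``SCH``/``ADP``.
    masks
        Either ``{structure: mask}`` shared by the three distributions, or
        ``{distribution: {structure: mask}}`` when the daily anatomy differs
        from the planning anatomy (REF masks on the planning anatomy, SCH and
        ADP on the day's).
    statuses
        Optional per-patient overrides of the site-level statuses.

    Returns
    -------
    DataFrame in the metric-table dialect: one row per (slot, structure);
    non-valid slots carry their status and empty values.
    """
    missing = [d for d in DISTRIBUTIONS if d not in grids]
    if missing:
        raise ConfigurationError(f"missing dose distributions: {missing}")
    per_dist = _masks_per_distribution(masks)
    curves: dict[tuple[str, str], DVHCurve] = {}

    def curve_for(dist: str, structure: str) -> DVHCurve:
        key = (dist, structure)
        if key not in curves:
            mask_set = per_dist[dist]
            if structure not in mask_set:
                raise DataCompletenessError(
                    f"structure {structure!r} missing for distribution {dist}"
                )
            curves[key] = dvh.compute_cumulative_dvh(grids[dist], mask_set[structure], bin_width)
        return curves[key]

    rows = []
    for spec, status in standard_metric_set(prescription):
        if statuses and spec.metric_id in statuses:
            status = statuses[spec.metric_id]
        for structure in spec.structures:
            row = {
                "patient_id": patient_id,
                "fraction_index": fraction_index,
                "site": prescription.site_label,
                "structure": structure,
                "metric_id": spec.metric_id,
                "status": status.value,
                "ref_value": float("nan"),
                "sch_value": float("nan"),
                "adp_value": float("nan"),
                "unit": spec.unit,
            }
            if status is MetricStatus.VALID:
                for dist, col in zip(DISTRIBUTIONS, ("ref_value", "sch_value", "adp_value")):
                    row[col] = metric_value(curve_for(dist, structure), spec, prescription)
            rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
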