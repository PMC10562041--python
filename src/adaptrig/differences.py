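"""Per-fraction metric difference tables and cohort summaries.

For every valid metric the three pairwise contrasts are formed in the
metric's native unit (Gy for D-metrics, percentage points for V-metrics):

* ``SCH_REF`` — how much the day's anatomy compromised the original plan,
* ``ADP_REF`` — how closely the reoptimized plan restores the original,
* ``ADP_SCH`` — the dosimetric gain of adapting, defined as
  ``ADP_REF - SCH_REF`` so the algebraic identity holds exactly.

Cohort summaries report median and interquartile range (IQR = Q3 - Q1) per
site, metric and contrast, using linear interpolation between closest ranks
for all quantiles.  Fractions are pooled across the patients of a site by
default; ``per_patient=True`` first reduces each patient to a median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .catalog import METRIC_INDEX, METRIC_ORDER, SITE_ORDER, MetricStatus
from .errors import DomainError, SchemaError

logger = logging.getLogger(__name__)

CONTRASTS = ("SCH_REF", "ADP_REF", "ADP_SCH")

CONTRAST_COLUMNS = {"SCH_REF": "sch_ref", "ADP_REF": "adp_ref", "ADP_SCH": "adp_sch"}

DIFFERENCE_COLUMNS = [
    "patient_id",
    "fraction_index",
    "site",
    "structure",
    "metric_id",
    "sch_ref",
    "adp_ref",
    "adp_sch",
    "unit",
]

SUMMARY_COLUMNS = ["site", "metric_id", "contrast", "median", "iqr", "n"]


def compute_differences(records: pd.DataFrame) -> pd.DataFrame:
    """Build the difference table from a metric-value table.

    Only rows with ``status == "valid"`` and all three values present are
    emitted; incomplete rows are skipped (and logged), never half-filled.
    ``adp_sch`` is derived as ``adp_ref - sch_ref`` so the identity is exact.
    """
    required = {"status", "ref_value", "sch_value", "adp_value"}
    if not required.issubset(records.columns):
        raise SchemaError(f"metric table missing columns: {sorted(required - set(records.columns))}")
    valid = records["status"] == MetricStatus.VALID.value
    complete = records[["ref_value", "sch_value", "adp_value"]].notna().all(axis=1)
    skipped = int((valid & ~complete).sum())
    if skipped:
        logger.warning("skipping %d valid rows with missing values", skipped)
    rows = records.loc[valid & complete].copy()
    rows["sch_ref"] = rows["sch_value"] - rows["ref_value"]
    rows["adp_ref"] = rows["adp_value"] - rows["ref_value"]
    rows["adp_sch"] = rows["adp_ref"] - rows["sch_ref"]
    return rows[DIFFERENCE_COLUMNS].reset_index(drop=True)


def median_iqr(values: np.ndarray) -> tuple[float, float]:
    """Median and IQR under the linear-interpolation quantile convention."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("cannot summarize an empty group")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    return float(med), float(q3 - q1)


def summarize_cohort(differences: pd.DataFrame, per_patient: bool = False) -> pd.DataFrame:
    """Median/IQR per site, metric and contrast (the standard summary table).

    Rows are ordered site, then metric slot (structure blocks), then
    contrast ``SCH_REF, ADP_REF, ADP_SCH``.  Structures sharing a slot (the
    two femurs) are pooled.  Empty groups are omitted.
    """
    if differences.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    long = differences.melt(
        id_vars=["patient_id", "site", "metric_id"],
        value_vars=list(CONTRAST_COLUMNS.values()),
        var_name="contrast",
        value_name="value",
    )
    long["contrast"] = long["contrast"].str.upper()
    if per_patient:
        long = (
            long.groupby(["site", "metric_id", "contrast", "patient_id"], sort=False)["value"]
            .median()
            .reset_index()
        )
    out = []
    for (site, metric_id, contrast), group in long.groupby(
        ["site", "metric_id", "contrast"], sort=False
    ):
        med, iqr = median_iqr(group["value"].to_numpy())
        out.append(
            {
                "site": site,
                "metric_id": metric_id,
                "contrast": contrast,
                "median": med,
                "iqr": iqr,
                "n": int(group["value"].size),
            }
        )
    summary = pd.DataFrame(out, columns=SUMMARY_COLUMNS)
    summary["site"] = pd.Categorical(summary["site"], categories=list(SITE_ORDER), ordered=True)
    summary["metric_id"] = pd.Categorical(
        summary["metric_id"], categories=list(METRIC_ORDER), ordered=True
    )
    summary["contrast"] = pd.Categorical(
        summary["contrast"], categories=list(CONTRASTS), ordered=True
    )
    summary = summary.sort_values(["site", "metric_id", "contrast"]).reset_index(drop=True)
    for col in ("site", "metric_id", "contrast"):
        summary[col] = summary[col].astype(str)
    return summary


def attach_units(summary: pd.DataFrame) -> pd.DataFrame:
    """Add the metric unit column to a summary table (reporting helper)."""
    out = summary.copy()
    out["unit"] = [METRIC_INDEX[m].unit for m in out["metric_id"]]
    return out
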