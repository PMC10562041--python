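"""File formats: metric-table CSV dialect, phantom array container, YAML specs.

CSV dialect: UTF-8, comma-separated, ``.`` decimal, header required, one
unit per row (Gy or %) so dose and volume metrics cannot be confused.
Numbers are written with 4 decimal places — finer than clinical reporting
precision; round-trips are lossless at that precision.

Phantom grids are stored as ``.npy`` arrays with a JSON sidecar header
recording shape, axis order (z, y, x), spacing (mm), origin (mm) and the
dose unit (Gy).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import RECORD_COLUMNS, MetricStatus
from .cohort import CohortSpec, PhantomSpec
from .dvh import DoseGrid, DVHCurve, StructureMask
from .errors import DataIntegrityError, SchemaError
from .triggers import SweepResult

FLOAT_FORMAT = "%.4f"

_VALUE_COLUMNS = ("ref_value", "sch_value", "adp_value")
_STATUS_VALUES = {s.value for s in MetricStatus}


def write_metric_table(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    records.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def read_metric_table(path) -> pd.DataFrame:
    """Read and validate a metric-table CSV.

    Enforces the dialect invariants and reports offending line numbers:
    required columns present; known status vocabulary; values present iff
    the status is valid; Reference values constant across each patient's
    fractions.  Unknown extra columns are preserved.
    """
    path = Path(path)
    records = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    def lines(index) -> str:
        # +2: header line plus 1-based numbering
        return ", ".join(str(i + 2) for i in list(index)[:10])

    bad_status = ~records["status"].isin(_STATUS_VALUES)
    if bad_status.any():
        raise SchemaError(
            f"{path}: unknown status values at lines {lines(records.index[bad_status])}"
        )
    has_values = records[list(_VALUE_COLUMNS)].notna()
    valid = records["status"] == MetricStatus.VALID.value
    stray = ~valid & has_values.any(axis=1)
    if stray.any():
        raise DataIntegrityError(
            f"{path}: non-valid rows carry metric values at lines {lines(records.index[stray])}"
        )
    incomplete = valid & ~has_values.all(axis=1)
    if incomplete.any():
        raise DataIntegrityError(
            f"{path}: valid rows with missing values at lines {lines(records.index[incomplete])}"
        )
    # REF must not vary across a patient's fractions
    ref_rows = records[valid]
    if not ref_rows.empty:
        nunique = ref_rows.groupby(
            ["patient_id", "site", "structure", "metric_id"], sort=False
        )["ref_value"].transform("nunique")
        varying = nunique > 1
        if varying.any():
            raise DataIntegrityError(
                f"{path}: Reference values vary across fractions at lines "
                f"{lines(ref_rows.index[varying])}"
            )
    return records


def write_differences(differences: pd.DataFrame, path) -> Path:
    path = Path(path)
    differences.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_summary(summary: pd.DataFrame, path) -> Path:
    path = Path(path)
    summary.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_dvh_curve(curve: DVHCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame(curve.to_table(), columns=["dose_Gy", "cum_volume_fraction"]).to_csv(
        path, index=False
    )
    return path


def write_sweep_json(sweep: SweepResult, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(sweep.to_dict(), indent=2))
    return path


def write_sweep_csv(sweep: SweepResult, path) -> Path:
    path = Path(path)
    sweep.to_frame().to_csv(path, index=False, float_format="%.6f")
    return path


# --------------------------------------------------------------------------
# phantom array container
# --------------------------------------------------------------------------


def save_dose_grid(grid: DoseGrid, path) -> Path:
    """Write ``<path>.npy`` + ``<path>.json`` (shape/spacing/origin header)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), grid.values)
    header = {
        "kind": "dose_grid",
        "axis_order": "zyx",
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
        "dose_unit": "Gy",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path.with_suffix(".npy")


def load_dose_grid(path) -> DoseGrid:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    values = np.load(path.with_suffix(".npy"))
    return DoseGrid(values, tuple(header["spacing_mm"]), tuple(header["origin_mm"]))


def save_mask(mask: StructureMask, path) -> Path:
    path = Path(path)
    np.save(path.with_suffix(".npy"), mask.occupancy)
    header = {
        "kind": "structure_mask",
        "axis_order": "zyx",
        "shape": list(mask.occupancy.shape),
        "name": mask.name,
        "role": mask.role,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path.with_suffix(".npy")


def load_mask(path) -> StructureMask:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    return StructureMask(np.load(path.with_suffix(".npy")), header["name"], header["role"])


# --------------------------------------------------------------------------
# YAML specs
# --------------------------------------------------------------------------


def save_cohort_spec(spec: CohortSpec, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))
    return path


def load_cohort_spec(path) -> CohortSpec:
    return CohortSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def save_phantom_spec(spec: PhantomSpec, path) -> Path:
    data = dataclasses.asdict(spec)
    data["layout"] = {
        name: {"offset_mm": list(off), "radius_mm": r, "role": role}
        for name, (off, r, role) in spec.layout.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
    return Path(path)


def load_phantom_spec(path) -> PhantomSpec:
    data = yaml.safe_load(Path(path).read_text())
    if "layout" in data:
        data["layout"] = {
            name: (tuple(entry["offset_mm"]), float(entry["radius_mm"]), entry["role"])
            for name, entry in data["layout"].items()
        }
    for key in ("shape", "spacing", "displacement_sd"):
        if key in data:
            data[key] = tuple(data[key])
    return PhantomSpec(**data)
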