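"""Adaptive-trigger parameter-value analysis.

A *trigger* is a parameter-value pair: the parameter is a monitored
per-fraction difference (e.g. the SCH-REF change in PTV D95%), the value is
the action level at which online adaptation is indicated.  The decision rule
is direction-aware and inclusive at the boundary:

* coverage metrics (``higher_better``): the trigger fires when the observed
  difference is **<=** the trigger value — more negative means more
  compromised, and *raising* the value makes the trigger stricter;
* OAR/hot-spot metrics (``lower_better``): fires when the difference is
  **>=** the value — *lowering* the value makes the trigger stricter.

Adapting additionally requires that the adapted plan is dosimetrically
preferred over the scheduled one (``ADP_SCH > 0`` for coverage, ``< 0`` for
OAR metrics; exact ties are not preferred — no gain, no adaptation).  This
second condition is why the proportion of treatments adapted need not reach
100% even under an arbitrarily strict trigger.

Sweeping the trigger value over a grid yields (a) the proportion of
treatments adapted — by construction the strictness-direction empirical CDF
of the trigger parameter restricted to preference-satisfying fractions —
and (b) the counterfactual distribution of metric changes versus the
Reference Dose: ADP-REF where the policy adapts, SCH-REF elsewhere,
summarized by its 5/10/25/50/75/90/95th percentile bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import METRIC_INDEX, MetricStatus, metric_status
from .differences import CONTRAST_COLUMNS, CONTRASTS
from .errors import DataError, DomainError, UsageError

PERCENTILE_LEVELS = (5.0, 10.0, 25.0, 50.0, 75.0, 90.0, 95.0)

#: Default trigger-grid step: 0.25 Gy for dose metrics, 1 point for volume
#: metrics.  Finer than integer spacing so that sub-integer action levels
#: (e.g. -0.5 and -0.25 Gy) are representable.
DEFAULT_STEP = {"Gy": 0.25, "%": 1.0}


@dataclass(frozen=True)
class TriggerPolicy:
    """A trigger parameter (metric + contrast) and its action-level value."""

    metric_id: str
    value: float
    contrast: str = "SCH_REF"

    def __post_init__(self) -> None:
        if self.metric_id not in METRIC_INDEX:
            raise UsageError(f"unknown metric {self.metric_id!r}")
        if self.contrast not in CONTRASTS:
            raise UsageError(f"unknown contrast {self.contrast!r}")

    @property
    def direction(self) -> str:
        return METRIC_INDEX[self.metric_id].direction


@dataclass(frozen=True)
class TriggerDecision:
    patient_id: str
    fraction_index: int
    fired: bool
    preferred: bool
    adapt: bool


def trigger_fires(difference: float, policy: TriggerPolicy) -> bool:
    """Whether the trigger fires on one observed difference (inclusive boundary)."""
    if not math.isfinite(difference):
        raise DomainError("difference must be finite")
    if policy.direction == "higher_better":
        return difference <= policy.value
    return difference >= policy.value


def is_preferred(adp_sch: float, direction: str) -> bool:
    """Whether the adapted plan beats the scheduled one on this metric."""
    return adp_sch > 0 if direction == "higher_better" else adp_sch < 0


def adaptation_decision(diff_row, policy: TriggerPolicy) -> TriggerDecision:
    """Decide one fraction: adapt iff the trigger fires AND adaptation is preferred."""
    fired = trigger_fires(float(diff_row[CONTRAST_COLUMNS[policy.contrast]]), policy)
    preferred = is_preferred(float(diff_row["adp_sch"]), policy.direction)
    return TriggerDecision(
        patient_id=str(diff_row["patient_id"]),
        fraction_index=int(diff_row["fraction_index"]),
        fired=fired,
        preferred=preferred,
        adapt=fired and preferred,
    )


def decide_cohort(differences: pd.DataFrame, policy: TriggerPolicy) -> pd.DataFrame:
    """Vectorized :func:`adaptation_decision` over a difference table."""
    rows = differences[differences["metric_id"] == policy.metric_id]
    if rows.empty:
        raise DataError(f"no difference records for metric {policy.metric_id!r}")
    x = rows[CONTRAST_COLUMNS[policy.contrast]].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("differences must be finite")
    if policy.direction == "higher_better":
        fired = x <= policy.value
        preferred = rows["adp_sch"].to_numpy(dtype=float) > 0
    else:
        fired = x >= policy.value
        preferred = rows["adp_sch"].to_numpy(dtype=float) < 0
    out = rows[["patient_id", "fraction_index"]].copy()
    out["fired"] = fired
    out["preferred"] = preferred
    out["adapt"] = fired & preferred
    return out.reset_index(drop=True)


def proportion_adapted(decisions) -> float:
    """Fraction of treatments adapted, in [0, 1]."""
    if isinstance(decisions, pd.DataFrame):
        adapt = decisions["adapt"].to_numpy(dtype=bool)
    else:
        adapt = np.asarray([d.adapt if isinstance(d, TriggerDecision) else d for d in decisions], dtype=bool)
    if adapt.size == 0:
        raise DomainError("cannot compute a proportion over zero decisions")
    return float(adapt.mean())


def counterfactual_values(differences: pd.DataFrame, decisions, metric_id: str) -> np.ndarray:
    """Metric changes vs REF realized under a policy: ADP-REF if adapted, else SCH-REF."""
    rows = differences[differences["metric_id"] == metric_id]
    if isinstance(decisions, pd.DataFrame):
        adapt = decisions["adapt"].to_numpy(dtype=bool)
    else:
        adapt = np.asarray([d.adapt if isinstance(d, TriggerDecision) else d for d in decisions], dtype=bool)
    if adapt.size != len(rows):
        raise DataError(
            f"decision/fraction mismatch: {adapt.size} decisions for {len(rows)} fractions"
        )
    return np.where(adapt, rows["adp_ref"].to_numpy(dtype=float), rows["sch_ref"].to_numpy(dtype=float))


def percentile_bands(values, levels=PERCENTILE_LEVELS) -> np.ndarray:
    """Percentiles of a value set, linear-interpolation convention, ordered by level."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DomainError("cannot compute percentile bands of an empty set")
    return np.percentile(values, np.asarray(levels, dtype=float))


@dataclass(frozen=True)
class SweepResult:
    """Proportion-adapted curve and counterfactual percentile bands over a value grid.

    ``grid`` is ascending in the metric's native unit; ``bands`` has shape
    ``(len(grid), len(levels))`` with level columns ordered 5th..95th.
    """

    metric_id: str
    contrast: str
    site: str | None
    grid: np.ndarray
    proportion_adapted: np.ndarray
    bands: np.ndarray
    n: int
    step: float
    levels: tuple[float, ...] = field(default=PERCENTILE_LEVELS)

    @property
    def direction(self) -> str:
        return METRIC_INDEX[self.metric_id].direction

    @property
    def strictness_order(self) -> np.ndarray:
        """Grid indices ordered lax -> strict."""
        idx = np.arange(len(self.grid))
        return idx if self.direction == "higher_better" else idx[::-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per grid value x percentile level."""
        rows = []
        for i, v in enumerate(self.grid):
            for j, level in enumerate(self.levels):
                rows.append(
                    {
                        "metric_id": self.metric_id,
                        "contrast": self.contrast,
                        "site": self.site,
                        "trigger_value": float(v),
                        "proportion_adapted": float(self.proportion_adapted[i]),
                        "level": level,
                        "band_value": float(self.bands[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "metric_id": self.metric_id,
            "contrast": self.contrast,
            "site": self.site,
            "n": self.n,
            "step": self.step,
            "levels": list(self.levels),
            "grid": [float(v) for v in self.grid],
            "proportion_adapted": [float(p) for p in self.proportion_adapted],
            "bands": [[float(b) for b in row] for row in self.bands],
        }


def default_grid(values: np.ndarray, step: float, pad_steps: int = 1) -> np.ndarray:
    """Ascending action-level grid spanning floor(min) to ceil(max) of the
    observed differences, padded by ``pad_steps`` on each side so the lax and
    strict limits are always included."""
    lo = math.floor(float(np.min(values))) - pad_steps * step
    hi = math.ceil(float(np.max(values))) + pad_steps * step
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def sweep_trigger(
    differences: pd.DataFrame,
    metric_id: str,
    contrast: str = "SCH_REF",
    grid: np.ndarray | None = None,
    step: float | None = None,
    site: str | None = None,
    levels=PERCENTILE_LEVELS,
) -> SweepResult:
    """Evaluate a trigger parameter over a grid of action-level values.

    For each grid value the full decision rule is re-applied: fire, check
    preference, adapt, then measure the proportion adapted and the
    percentile bands of the counterfactual SCH/ADP-vs-REF mixture.

    ``site`` restricts the table to one site group and refuses metrics whose
    status there is not valid.
    """
    if metric_id not in METRIC_INDEX:
        raise UsageError(f"unknown metric {metric_id!r}")
    if contrast not in CONTRASTS:
        raise UsageError(f"unknown contrast {contrast!r}")
    rows = differences
    if site is not None:
        status = metric_status(site, metric_id)
        if status is not MetricStatus.VALID:
            raise UsageError(
                f"metric {metric_id!r} has status {status.value!r} for site {site!r}; "
                "not a usable trigger parameter"
            )
        rows = rows[rows["site"] == site]
    rows = rows[rows["metric_id"] == metric_id]
    if rows.empty:
        raise DataError(f"no difference records for metric {metric_id!r}")

    x = rows[CONTRAST_COLUMNS[contrast]].to_numpy(dtype=float)
    adp_ref = rows["adp_ref"].to_numpy(dtype=float)
    sch_ref = rows["sch_ref"].to_numpy(dtype=float)
    direction = METRIC_INDEX[metric_id].direction
    preferred = (
        rows["adp_sch"].to_numpy(dtype=float) > 0
        if direction == "higher_better"
        else rows["adp_sch"].to_numpy(dtype=float) < 0
    )

    if step is None:
        step = DEFAULT_STEP[METRIC_INDEX[metric_id].unit]
    if grid is None:
        grid = default_grid(x, step)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise DomainError("grid must be non-empty and strictly ascending")

    proportions = np.empty(grid.size)
    bands = np.empty((grid.size, len(levels)))
    for i, value in enumerate(grid):
        fired = x <= value if direction == "higher_better" else x >= value
        adapt = fired & preferred
        proportions[i] = adapt.mean()
        bands[i] = percentile_bands(np.where(adapt, adp_ref, sch_ref), levels)
    return SweepResult(
        metric_id=metric_id,
        contrast=contrast,
        site=site,
        grid=grid,
        proportion_adapted=proportions,
        bands=bands,
        n=int(x.size),
        step=float(step),
        levels=tuple(levels),
    )
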