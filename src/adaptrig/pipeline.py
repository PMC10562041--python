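"""End-to-end pipeline: simulate/load -> metric table -> differences ->
summaries -> trigger sweeps -> figures -> manifest.

Every artifact written is a pure function of (config, seed); the manifest
records both plus library versions and row counts, so a run can be
reproduced bit-identically.  On failure, files written so far are removed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, catalog, cohort, differences as diffmod, io as adio, plotting, triggers
from .errors import AdaptrigError, ConfigurationError

logger = logging.getLogger(__name__)

INPUT_MODES = ("metric-cohort", "phantom", "external")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input mode applies: ``metric-cohort`` draws a synthetic
    metric table (``cohort_spec`` YAML path or the shipped default),
    ``phantom`` simulates voxel phantoms through the DVH engine
    (``phantom_spec`` optional), ``external`` reads an existing metric CSV.
    """

    mode: str = "metric-cohort"
    out_dir: str = "adaptrig_out"
    seed: int = 0
    cohort_spec: str | None = None
    phantom_spec: str | None = None
    metric_table: str | None = None
    n_phantom_patients: int = 2
    triggers: list[dict] = field(
        default_factory=lambda: [{"metric_id": "ptv_d95pct", "contrast": "SCH_REF"}]
    )
    step_overrides: dict = field(default_factory=dict)
    per_patient_summary: bool = False
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in INPUT_MODES:
            raise ConfigurationError(f"mode must be one of {INPUT_MODES}, got {self.mode!r}")
        if self.mode == "external" and not self.metric_table:
            raise ConfigurationError("external mode requires metric_table")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _build_metric_table(config: RunConfig) -> pd.DataFrame:
    if config.mode == "external":
        return adio.read_metric_table(config.metric_table)
    if config.mode == "metric-cohort":
        if config.cohort_spec:
            spec = adio.load_cohort_spec(config.cohort_spec)
            spec = dataclasses.replace(spec, master_seed=config.seed)
        else:
            spec = cohort.default_cohort_spec(master_seed=config.seed)
        return cohort.generate_metric_cohort(spec)
    # phantom mode: a few phantom patients of one site
    base = (
        adio.load_phantom_spec(config.phantom_spec)
        if config.phantom_spec
        else cohort.PhantomSpec()
    )
    frames = []
    for p in range(config.n_phantom_patients):
        pspec = dataclasses.replace(base, seed=int(config.seed) * 10_000 + p)
        frames.append(cohort.phantom_metric_records(pspec, patient_id=f"phantom_{p:03d}"))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a manifest dict (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        records = _build_metric_table(config)
        emit(adio.write_metric_table(records, out / "metrics.csv"))

        diffs = diffmod.compute_differences(records)
        emit(adio.write_differences(diffs, out / "differences.csv"))
        summary = diffmod.summarize_cohort(diffs, per_patient=config.per_patient_summary)
        emit(adio.write_summary(diffmod.attach_units(summary), out / "summary.csv"))

        sweep_infos = []
        for trig in config.triggers:
            metric_id = trig["metric_id"]
            contrast = trig.get("contrast", "SCH_REF")
            for site in sorted(diffs.loc[diffs["metric_id"] == metric_id, "site"].unique()):
                if catalog.metric_status(site, metric_id) is not catalog.MetricStatus.VALID:
                    continue
                step = config.step_overrides.get(metric_id)
                sweep = triggers.sweep_trigger(
                    diffs, metric_id, contrast=contrast, site=site, step=step
                )
                stem = f"sweep_{site}_{metric_id}_{contrast}".replace("%", "pct")
                emit(adio.write_sweep_json(sweep, out / f"{stem}.json"))
                emit(adio.write_sweep_csv(sweep, out / f"{stem}.csv"))
                if config.make_figures:
                    emit(plotting.plot_sweep(sweep, out / f"{stem}.png"))
                sweep_infos.append({"site": site, "metric_id": metric_id, "contrast": contrast})

        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "versions": {
                "adaptrig": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "rows": {
                "metrics": int(len(records)),
                "differences": int(len(diffs)),
                "summary": int(len(summary)),
            },
            "sweeps": sweep_infos,
            "outputs": [p.name for p in written],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except AdaptrigError:
        for p in written:
            p.unlink(missing_ok=True)
            # remove array-container sidecars too
            if p.suffix == ".npy":
                p.with_suffix(".json").unlink(missing_ok=True)
        raise
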