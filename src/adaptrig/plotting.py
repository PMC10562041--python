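"""Figure rendering for trigger sweeps.  Presentation only — no computation."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .catalog import METRIC_INDEX
from .triggers import SweepResult

_BAND_PAIRS = ((0, 6), (1, 5), (2, 4))  # 5-95, 10-90, 25-75
_BAND_ALPHAS = (0.15, 0.25, 0.35)


def plot_sweep(sweep: SweepResult, path) -> Path:
    """Two-panel sweep figure: (a) proportion of treatments adapted versus
    trigger value, (b) counterfactual percentile bands of the metric change."""
    spec = METRIC_INDEX[sweep.metric_id]
    xlabel = f"{sweep.contrast.replace('_', '-')} trigger value for {sweep.metric_id} ({spec.unit})"
    fig, (ax_prop, ax_band) = plt.subplots(2, 1, figsize=(6.5, 7.5), sharex=True)

    ax_prop.plot(sweep.grid, 100.0 * sweep.proportion_adapted, marker="o", ms=3, color="tab:blue")
    ax_prop.set_ylabel("Treatments adapted (%)")
    ax_prop.set_ylim(-2, 102)
    ax_prop.grid(alpha=0.3)

    for (lo, hi), alpha in zip(_BAND_PAIRS, _BAND_ALPHAS):
        ax_band.fill_between(
            sweep.grid, sweep.bands[:, lo], sweep.bands[:, hi], alpha=alpha, color="tab:orange",
            linewidth=0,
        )
    ax_band.plot(sweep.grid, sweep.bands[:, 3], color="tab:red", lw=1.5, label="median")
    ax_band.axhline(0.0, color="k", lw=0.8, ls=":")
    ax_band.set_xlabel(xlabel)
    ax_band.set_ylabel(f"Resulting change vs REF ({spec.unit})")
    ax_band.grid(alpha=0.3)
    ax_band.legend(loc="best", fontsize=8)

    title = f"{sweep.site or 'pooled'} — {sweep.metric_id} ({sweep.contrast}), n={sweep.n}"
    fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
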