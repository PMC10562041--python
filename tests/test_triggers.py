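"""Trigger decision rule, sweeps, counterfactual distributions, bands."""

import numpy as np
import pandas as pd
import pytest

from adaptrig.errors import DataError, DomainError, UsageError
from adaptrig.triggers import (
    TriggerPolicy,
    adaptation_decision,
    counterfactual_values,
    decide_cohort,
    percentile_bands,
    proportion_adapted,
    sweep_trigger,
    trigger_fires,
)


def _diff_rows(rows, metric_id="ptv_d95pct"):
    out = []
    for i, (sch_ref, adp_ref) in enumerate(rows):
        out.append(
            {
                "patient_id": "p1",
                "fraction_index": i,
                "site": "prostate_sv_hypofx",
                "structure": "ptv",
                "metric_id": metric_id,
                "sch_ref": sch_ref,
                "adp_ref": adp_ref,
                "adp_sch": adp_ref - sch_ref,
                "unit": "Gy",
            }
        )
    return pd.DataFrame(out)


class TestFiringRule:
    def test_coverage_fires_at_or_below_value(self):
        policy = TriggerPolicy("ptv_d95pct", value=-0.5)
        assert trigger_fires(-0.6, policy)
        assert trigger_fires(-0.5, policy)  # inclusive boundary
        assert not trigger_fires(-0.4, policy)

    def test_oar_fires_at_or_above_value(self):
        policy = TriggerPolicy("rectum_v40gy", value=5.0)
        assert trigger_fires(6.8, policy)
        assert trigger_fires(5.0, policy)
        assert not trigger_fires(4.9, policy)

    def test_nonfinite_difference_rejected(self):
        with pytest.raises(DomainError):
            trigger_fires(float("nan"), TriggerPolicy("ptv_d95pct", value=0.0))

    def test_unknown_metric_rejected(self):
        with pytest.raises(UsageError):
            TriggerPolicy("ptv_d42pct", value=0.0)


class TestAdaptationDecision:
    def test_fired_and_preferred_adapts(self):
        diffs = _diff_rows([(-0.5, -0.05)])  # adp_sch = +0.45
        decision = adaptation_decision(diffs.iloc[0], TriggerPolicy("ptv_d95pct", value=-0.2))
        assert decision.fired and decision.preferred and decision.adapt

    def test_fired_but_not_preferred_does_not_adapt(self):
        diffs = _diff_rows([(-0.5, -0.60)])  # adapted coverage worse than scheduled
        decision = adaptation_decision(diffs.iloc[0], TriggerPolicy("ptv_d95pct", value=-0.2))
        assert decision.fired and not decision.preferred and not decision.adapt

    def test_not_fired_never_adapts(self):
        diffs = _diff_rows([(0.3, 0.35)])
        decision = adaptation_decision(diffs.iloc[0], TriggerPolicy("ptv_d95pct", value=-0.2))
        assert not decision.fired and not decision.adapt

    def test_exact_tie_is_not_preferred(self):
        diffs = _diff_rows([(-0.5, -0.5)])  # adp_sch exactly 0: no gain
        decision = adaptation_decision(diffs.iloc[0], TriggerPolicy("ptv_d95pct", value=0.0))
        assert not decision.preferred

    def test_oar_preference_sign(self):
        # OAR: adapting is preferred when it lowers the metric
        diffs = _diff_rows([(6.8, 0.9)], metric_id="rectum_v40gy")
        decision = adaptation_decision(diffs.iloc[0], TriggerPolicy("rectum_v40gy", value=5.0))
        assert decision.adapt


class TestProportionAndCounterfactual:
    def test_counting(self):
        assert proportion_adapted([True, False, True, True] + [False] * 6) == pytest.approx(0.3)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            proportion_adapted([])

    def test_all_fired_some_preferred(self):
        rows = [(-1.0, 0.0)] * 8 + [(-1.0, -1.5)] * 2  # last two not preferred
        decisions = decide_cohort(_diff_rows(rows), TriggerPolicy("ptv_d95pct", value=0.0))
        assert decisions["fired"].all()
        assert proportion_adapted(decisions) == pytest.approx(0.8)

    def test_elementwise_selection(self):
        diffs = _diff_rows([(-0.30, 0.00), (-0.10, -0.02)])
        values = counterfactual_values(diffs, [True, False], "ptv_d95pct")
        np.testing.assert_allclose(values, [0.00, -0.10])

    def test_no_adaptation_yields_scheduled_values(self):
        diffs = _diff_rows([(-0.3, 0.0), (-0.2, 0.0), (0.1, 0.0)])
        values = counterfactual_values(diffs, [False] * 3, "ptv_d95pct")
        np.testing.assert_allclose(values, diffs["sch_ref"])

    def test_decision_count_mismatch_rejected(self):
        diffs = _diff_rows([(-0.3, 0.0), (-0.2, 0.0)])
        with pytest.raises(DataError):
            counterfactual_values(diffs, [True], "ptv_d95pct")


class TestPercentileBands:
    def test_integer_ramp_median(self):
        bands = percentile_bands(np.arange(101.0))
        assert bands[3] == 50.0  # 50th of 0..100

    def test_constant_list(self):
        bands = percentile_bands(np.full(7, 3.3))
        np.testing.assert_allclose(bands, 3.3)

    def test_linear_interpolation_hand_value(self):
        bands = percentile_bands(np.array([0.0, 1.0, 2.0, 3.0]), levels=(25.0,))
        assert bands[0] == pytest.approx(0.75)

    def test_ordered_by_level(self, default_diffs):
        values = default_diffs.loc[default_diffs["metric_id"] == "ptv_d95pct", "sch_ref"]
        bands = percentile_bands(values.to_numpy())
        assert np.all(np.diff(bands) >= 0)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            percentile_bands([])


@pytest.fixture(scope="module")
def sv_sweep(default_diffs):
    return sweep_trigger(
        default_diffs, "ptv_d95pct", contrast="SCH_REF", site="prostate_sv_hypofx"
    )


class TestSweep:
    def test_brute_force_re_decision_matches(self, default_diffs, sv_sweep):
        """Each grid point equals an independent from-scratch single-value evaluation."""
        rows = default_diffs[
            (default_diffs["site"] == "prostate_sv_hypofx")
            & (default_diffs["metric_id"] == "ptv_d95pct")
        ]
        for i, value in enumerate(sv_sweep.grid):
            decisions = decide_cohort(rows, TriggerPolicy("ptv_d95pct", value=float(value)))
            assert sv_sweep.proportion_adapted[i] == pytest.approx(
                proportion_adapted(decisions), abs=1e-12
            )
            cf = counterfactual_values(rows, decisions, "ptv_d95pct")
            np.testing.assert_allclose(sv_sweep.bands[i], percentile_bands(cf))

    def test_proportion_equals_preference_restricted_cdf(self, default_diffs, sv_sweep):
        """The proportion-adapted curve is the empirical CDF of the trigger
        parameter over preference-satisfying fractions (exactly)."""
        rows = default_diffs[
            (default_diffs["site"] == "prostate_sv_hypofx")
            & (default_diffs["metric_id"] == "ptv_d95pct")
        ]
        x = rows["sch_ref"].to_numpy()
        pref = rows["adp_sch"].to_numpy() > 0
        n = x.size
        for i, value in enumerate(sv_sweep.grid):
            expected = np.sum((x[pref] <= value)) / n
            assert sv_sweep.proportion_adapted[i] == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_strictness_all_metrics_and_contrasts(self, default_diffs):
        for site in default_diffs["site"].unique():
            site_rows = default_diffs[default_diffs["site"] == site]
            for metric_id in site_rows["metric_id"].unique():
                for contrast in ("SCH_REF", "ADP_REF"):
                    sweep = sweep_trigger(site_rows, metric_id, contrast=contrast, site=site)
                    props = sweep.proportion_adapted[sweep.strictness_order]
                    assert np.all(np.diff(props) >= -1e-15), (site, metric_id, contrast)

    def test_limits(self, default_diffs, sv_sweep):
        rows = default_diffs[
            (default_diffs["site"] == "prostate_sv_hypofx")
            & (default_diffs["metric_id"] == "ptv_d95pct")
        ]
        pref_fraction = float((rows["adp_sch"] > 0).mean())
        order = sv_sweep.strictness_order
        assert sv_sweep.proportion_adapted[order[0]] == 0.0
        assert sv_sweep.proportion_adapted[order[-1]] == pytest.approx(pref_fraction)
        # sub-100% ceiling: some fractions never prefer adaptation
        assert pref_fraction < 1.0

    def test_counterfactual_band_limits(self, default_diffs, sv_sweep):
        rows = default_diffs[
            (default_diffs["site"] == "prostate_sv_hypofx")
            & (default_diffs["metric_id"] == "ptv_d95pct")
        ]
        order = sv_sweep.strictness_order
        lax = percentile_bands(rows["sch_ref"].to_numpy())
        np.testing.assert_allclose(sv_sweep.bands[order[0]], lax)
        pref = rows["adp_sch"].to_numpy() > 0
        mixture = np.where(pref, rows["adp_ref"].to_numpy(), rows["sch_ref"].to_numpy())
        np.testing.assert_allclose(sv_sweep.bands[order[-1]], percentile_bands(mixture))

    def test_bands_rows_ordered(self, sv_sweep):
        assert np.all(np.diff(sv_sweep.bands, axis=1) >= 0)

    def test_nonlinear_increment_on_left_skewed_cohort(self, default_diffs):
        """On the left-skewed coverage distribution, halving the trigger step
        near zero more than doubles the gain in proportion adapted."""
        sweep = sweep_trigger(
            default_diffs,
            "ptv_d95pct",
            site="prostate_sv_hypofx",
            grid=np.array([-1.0, -0.5, -0.25]),
        )
        p = sweep.proportion_adapted
        assert (p[2] - p[1]) > (p[1] - p[0])

    def test_invalid_status_refused(self, default_diffs):
        with pytest.raises(UsageError, match="not_appropriate"):
            sweep_trigger(default_diffs, "bladder_v40gy", site="bladder_hypofx")

    def test_oar_strictness_runs_opposite(self, default_diffs):
        sweep = sweep_trigger(
            default_diffs, "rectum_v40gy", site="prostate_fossa_boost", step=1.0
        )
        # for OAR metrics lowering the value is stricter
        props = sweep.proportion_adapted
        assert props[0] >= props[-1]
        assert props[-1] == 0.0

    def test_tidy_frame_shape(self, sv_sweep):
        frame = sv_sweep.to_frame()
        assert len(frame) == len(sv_sweep.grid) * len(sv_sweep.levels)
        assert set(frame["level"]) == set(sv_sweep.levels)
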