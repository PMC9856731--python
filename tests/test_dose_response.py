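"""Sigmoid recruitment curve: fitting, thresholds, MEP simulation, RMT."""

import numpy as np
import pandas as pd
import pytest

from tmsmap.dose_response import (
    MEPGenConfig,
    RecruitmentCurve,
    ef_at_fit_point,
    estimate_rmt,
    fit_sigmoid,
    sigmoid,
    simulate_meps,
)
from tmsmap.hotspot import multiply_maps, select_top_stimuli


class TestThresholdFormula:
    def test_tangent_intercept_matches_closed_form(self):
        """The x-intercept of the tangent at the point of maximum slope of
        the logistic equals c - 2/b (checked by finite differences)."""
        a, b, c = 2.0, 0.1, 200.0
        x = np.linspace(100.0, 300.0, 2_000_001)
        y = sigmoid(x, a, b, c)
        dy = np.gradient(y, x)
        i = np.argmax(dy)
        x0 = x[i] - y[i] / dy[i]
        assert abs(x0 - (c - 2.0 / b)) / abs(c - 2.0 / b) < 1e-6

    def test_saturation_is_symmetric_intercept(self):
        fit = fit_sigmoid(
            np.linspace(100, 300, 20), sigmoid(np.linspace(100, 300, 20), 2, 0.1, 200)
        )
        assert np.isclose(fit.ef_saturation - fit.c, fit.c - fit.ef_threshold)


class TestFitting:
    def test_noise_free_parameter_recovery(self):
        ef = np.linspace(100.0, 300.0, 20)
        fit = fit_sigmoid(ef, sigmoid(ef, 2.0, 0.1, 200.0))
        assert abs(fit.a / 2.0 - 1) < 0.01
        assert abs(fit.b / 0.1 - 1) < 0.01
        assert abs(fit.c / 200.0 - 1) < 0.01
        assert fit.r2 >= 0.999
        assert not fit.divergent
        assert np.isclose(fit.ef_threshold, 180.0, rtol=0.01)

    def test_noisy_recovery_median_error(self):
        """Median relative parameter error < 15% at lognormal sigma 0.3,
        72 EF-MEP pairs (24 placements x 3 intensities), over 20 seeds."""
        truth = (2.0, 0.1, 200.0)
        base = np.linspace(250.0, 500.0, 24)  # per-placement peak EF at 100 %MSO
        ef = np.concatenate([f * base for f in (0.35, 0.45, 0.55)])
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mep = sigmoid(ef, *truth) * np.exp(rng.normal(0, 0.3, ef.size))
            fit = fit_sigmoid(ef, mep)
            errs.append(
                [
                    abs(fit.a / truth[0] - 1),
                    abs(fit.b / truth[1] - 1),
                    abs(fit.c / truth[2] - 1),
                ]
            )
        med = np.median(np.asarray(errs), axis=0)
        assert np.all(med < 0.15)

    def test_constant_data_flagged_divergent(self):
        fit = fit_sigmoid(np.linspace(0, 100, 10), np.full(10, 1.0))
        assert fit.divergent

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError, match="6"):
            fit_sigmoid(np.arange(4), np.arange(4.0))

    def test_model_object_interface(self):
        ef = np.linspace(100.0, 300.0, 30)
        df = pd.DataFrame({"ef_max": ef, "mep_pp": sigmoid(ef, 2, 0.1, 200)})
        fit = RecruitmentCurve.from_dataframe(df).fit()
        summary = fit.summary()
        assert "turning point" in summary
        assert f"{fit.r2:.4f}" in summary
        assert np.allclose(fit.predict(ef), sigmoid(ef, fit.a, fit.b, fit.c))


class TestSimulation:
    def test_saturation_and_midpoint_limits(self, calibrated_subject, maps100):
        a, b, c = calibrated_subject.sigmoid_truth["FDI"]
        cfg = MEPGenConfig(
            sigmoid_truth=calibrated_subject.sigmoid_truth,
            noise_sigma_log=0.0,
            noise_floor_mv=0.0,
            seed=0,
        )
        recs = simulate_meps(
            calibrated_subject, maps100, cfg, intensities_pct_mso=(100.0,)
        )
        v = calibrated_subject.truth_sites["FDI"]
        best = max(maps100.values(), key=lambda m: m.ef_strength[v])
        ef_best = best.ef_strength[v]
        top = recs[
            (recs["muscle"] == "FDI") & (recs["placement_id"] == best.stimulus_id)
        ]["mep_pp"]
        assert np.allclose(top, sigmoid(ef_best, a, b, c))

    def test_determinism_under_fixed_seed(self, calibrated_subject, maps100):
        cfg = MEPGenConfig(
            sigmoid_truth=calibrated_subject.sigmoid_truth, noise_sigma_log=0.3, seed=9
        )
        r1 = simulate_meps(calibrated_subject, maps100, cfg)
        r2 = simulate_meps(calibrated_subject, maps100, cfg)
        pd.testing.assert_frame_equal(r1, r2)

    def test_protocol_shape(self, records_noisy):
        # 24 placements x 5 trials = 120 stimulations per intensity per muscle
        counts = records_noisy.groupby(["muscle", "intensity_pct_mso"]).size()
        assert set(counts) == {120}
        assert (records_noisy["mep_pp"] >= 0).all()

    def test_missing_truth_vertex_raises(self, calibrated_subject, maps100):
        import dataclasses

        bad = dataclasses.replace(calibrated_subject)
        bad.truth_sites = {"FDI": 10**9}
        cfg = MEPGenConfig(sigmoid_truth={"FDI": (2, 0.1, 200)}, seed=0)
        with pytest.raises(ValueError, match="truth vertex"):
            simulate_meps(bad, maps100, cfg)


class TestEFAtFitPoint:
    def test_value_at_argmax_vertex(self, calibrated_subject, maps100, records_noisy):
        ids = select_top_stimuli(records_noisy, "FDI", 5, 55.0)
        h = multiply_maps(
            [maps100[i].scaled(55.0) for i in ids],
            "strength",
            calibrated_subject.surface,
            "FDI",
        )
        table = ef_at_fit_point(maps100, h)
        v = int(np.argmax(h.ef_focal))
        for _, row in table.iterrows():
            assert row.ef_max == maps100[row.stimulus_id].ef_strength[v]

    def test_intensity_monotonicity_through_linear_scaling(self, maps100):
        for m in maps100.values():
            assert np.all(m.scaled(55.0).ef_strength >= m.scaled(35.0).ef_strength)


class TestRMT:
    def _records(self, rmt_pct, a=2.0, noise=0.02, seed=0, criterion=0.05):
        # pct-domain sigmoid constructed so the 50 uV crossing sits at rmt_pct
        b = 0.25
        c = rmt_pct + np.log(a / criterion - 1.0) / b
        rng = np.random.default_rng(seed)
        rows = []
        for pct in np.arange(25.0, 61.0, 5.0):
            for trial in range(5):
                mep = sigmoid(pct, a, b, c) * np.exp(rng.normal(0, noise))
                rows.append(("best", trial, "FDI", mep, pct))
            for trial in range(5):  # a weaker placement
                mep = 0.2 * sigmoid(pct, a, b, c + 10)
                rows.append(("weak", trial, "FDI", mep, pct))
        return pd.DataFrame(
            rows,
            columns=["placement_id", "trial", "muscle", "mep_pp", "intensity_pct_mso"],
        )

    def test_recovers_constructed_threshold(self):
        est = estimate_rmt(self._records(rmt_pct=42.0), "FDI")
        assert not est.flagged
        assert abs(est.pct_mso - 42.0) <= 2.0
        assert est.placement_id == "best"

    def test_degenerate_criterion_returns_lowest_intensity(self):
        est = estimate_rmt(self._records(42.0), "FDI", criterion_mv=0.0)
        assert est.pct_mso == 25.0 and not est.flagged

    def test_unreachable_criterion_flagged(self):
        est = estimate_rmt(self._records(42.0), "FDI", criterion_mv=1e6)
        assert est.flagged

    def test_requires_three_intensities(self):
        df = self._records(42.0)
        df = df[df["intensity_pct_mso"].isin([25.0, 30.0])]
        with pytest.raises(ValueError, match="3 intensities"):
            estimate_rmt(df, "FDI")

    def test_pipeline_rmt_near_construction_target(
        self, calibrated_subject, maps100
    ):
        """The calibrated subject is built so its RMT lands near 42 %MSO."""
        cfg = MEPGenConfig(
            sigmoid_truth=calibrated_subject.sigmoid_truth,
            noise_sigma_log=0.05,
            seed=4,
        )
        recs = simulate_meps(calibrated_subject, maps100, cfg)
        est = estimate_rmt(recs, "FDI")
        assert not est.flagged
        assert abs(est.pct_mso - 42.0) <= 3.0


def test_calibration_orders_threshold_below_midpoint(calibrated_subject):
    for a, b, c in calibrated_subject.sigmoid_truth.values():
        assert a > 0 and b > 0
        assert c - 2.0 / b < c < c + 2.0 / b
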