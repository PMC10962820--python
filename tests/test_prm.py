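"""PRM workflow: peak QC, weighted calibration, linear range, quantification
and paired verification statistics."""

import numpy as np
import pandas as pd
import pytest

from deltaprot.discovery import paired_test
from deltaprot.prm import (
    NoLinearRangeError,
    apply_loq_filter,
    determine_linear_range,
    fit_calibration,
    qc_peaks,
    quantify,
    verify_differential,
)
from deltaprot.simulate import (
    default_spike_design,
    simulate_calibration,
    simulate_prm_export,
)
from conftest import build_manifest, build_table


def make_rows(fragments, points=10, truncated=False, sample="S1", rep="rep1", pep="AAK"):
    """fragments: list of (light, heavy, ppm)."""
    return pd.DataFrame(
        [
            {
                "peptide_sequence": pep,
                "sample_id": sample,
                "replicate_id": rep,
                "fragment_id": f"y{i + 3}",
                "light_area": l,
                "heavy_area": h,
                "points_across_peak": points,
                "mass_error_ppm": ppm,
                "truncated": truncated,
            }
            for i, (l, h, ppm) in enumerate(fragments)
        ]
    )


class TestQC:
    def test_too_few_fragments_rejected(self):
        rows = make_rows([(100, 50, 1), (120, 60, 2)])
        meas, report = qc_peaks(rows, min_fragments=3)
        assert len(meas) == 0
        assert report["n_rejected_few_fragments"] == 1

    @pytest.mark.parametrize("points,kept", [(7, 0), (8, 1)])
    def test_points_across_peak_boundary(self, points, kept):
        rows = make_rows([(100, 50, 1), (120, 60, 2), (90, 45, 0)], points=points)
        meas, _ = qc_peaks(rows)
        assert len(meas) == kept

    def test_high_ppm_fragment_dropped_ratio_hand_summed(self):
        rows = make_rows([(100, 50, 1), (120, 60, 2), (90, 45, 0), (500, 10, 12.0)])
        meas, report = qc_peaks(rows)
        assert report["n_fragments_high_ppm"] == 1
        # ratio over the surviving 3 fragments, hand-summed
        assert meas.loc[0, "ratio"] == pytest.approx((100 + 120 + 90) / (50 + 60 + 45))
        assert meas.loc[0, "n_fragments"] == 3

    def test_truncated_replicate_superseded_by_sibling(self):
        good = make_rows([(100, 50, 1), (120, 60, 2), (90, 45, 0)], rep="rep1")
        bad = make_rows([(200, 50, 1), (240, 60, 2), (180, 45, 0)], rep="rep2", truncated=True)
        meas, report = qc_peaks(pd.concat([good, bad], ignore_index=True))
        assert list(meas["replicate_id"]) == ["rep1"]
        assert report["n_dropped_truncated"] == 1
        # both truncated -> both kept (no non-truncated sibling)
        both = pd.concat(
            [make_rows([(1, 1, 0)] * 3, rep="rep1", truncated=True),
             make_rows([(1, 1, 0)] * 3, rep="rep2", truncated=True)],
            ignore_index=True,
        )
        meas2, _ = qc_peaks(both)
        assert len(meas2) == 2

    def test_zero_heavy_sum_invalid(self):
        rows = make_rows([(100, 0, 1), (120, 0, 2), (90, 0, 0)])
        meas, report = qc_peaks(rows)
        assert len(meas) == 0
        assert report["n_invalid_zero_heavy"] == 1

    def test_orientation_switch(self):
        rows = make_rows([(100, 50, 1), (120, 60, 2), (90, 45, 0)])
        lh, _ = qc_peaks(rows, orientation="light_over_heavy")
        hl, _ = qc_peaks(rows, orientation="heavy_over_light")
        assert lh.loc[0, "ratio"] == pytest.approx(1 / hl.loc[0, "ratio"])


def points_frame(x, y, pep="AAK"):
    return pd.DataFrame(
        {
            "peptide_sequence": pep,
            "theoretical_conc": np.asarray(x, dtype=float),
            "replicate_id": "rep1",
            "ratio_to_standard": np.asarray(y, dtype=float),
        }
    )


class TestCalibrationFit:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([0.1, 0.5, 1.0, 5.0, 10.0])
        curve = fit_calibration(points_frame(x, 2.0 * x))
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared_weighted == pytest.approx(1.0)

    def test_three_point_weighted_normal_equations(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.1, 1.9, 4.2])
        w = 1.0 / x
        curve = fit_calibration(points_frame(x, y), enforce_span=False)
        # closed-form weighted normal equations, computed independently
        Sw, Swx, Swy = w.sum(), (w * x).sum(), (w * y).sum()
        Swxx, Swxy = (w * x * x).sum(), (w * x * y).sum()
        slope = (Sw * Swxy - Swx * Swy) / (Sw * Swxx - Swx**2)
        intercept = (Swy - slope * Swx) / Sw
        assert curve.slope == pytest.approx(slope, rel=1e-12)
        assert curve.intercept == pytest.approx(intercept, rel=1e-12)

    def test_matches_oracle_on_random_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            m = int(rng.integers(3, 10))
            x = np.sort(rng.uniform(0.05, 10, m))
            y = rng.normal(1.5 * x + 0.2, 0.1)
            curve = fit_calibration(points_frame(x, y), enforce_span=False)
            w = 1.0 / x
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            assert curve.intercept == pytest.approx(beta[0], rel=1e-9, abs=1e-12)
            assert curve.slope == pytest.approx(beta[1], rel=1e-9, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 calibration points"):
            fit_calibration(points_frame([1, 2], [1, 2]))
        with pytest.raises(ValueError, match="identical"):
            fit_calibration(points_frame([1, 1, 1], [1, 2, 3]))
        with pytest.raises(ValueError, match="orders of magnitude"):
            fit_calibration(points_frame([1, 2, 3], [1, 2, 3]))

    def test_simulated_duplicate_series_slope_recovery(self):
        design = default_spike_design(["AAK"])
        errs = []
        for seed in range(25):
            pts = simulate_calibration(design, slope=2.0, intercept=0.0, cv=0.05, seed=seed)
            errs.append(abs(fit_calibration(pts).slope - 2.0) / 2.0)
        assert float(np.mean(errs)) < 0.05


class TestLinearRange:
    def test_noiseless_full_range_retained(self):
        design = default_spike_design(["AAK"])
        pts = simulate_calibration(design, slope=2.0, intercept=0.0, cv=0.0, seed=0)
        _, rng_ = determine_linear_range(pts)
        assert rng_ == (pytest.approx(0.03), pytest.approx(8.0))

    def test_low_end_floor_trims_two_levels(self):
        """A response floor below 0.1 biases the two lowest levels by >20%,
        so the linear range starts at the third level."""
        design = default_spike_design(["AAK"])
        pts = simulate_calibration(
            design, slope=2.0, intercept=0.0, cv=0.0, seed=0, response_floor_conc=0.1
        )
        curve, rng_ = determine_linear_range(pts, rel_bias_tol=0.20)
        assert rng_[0] == pytest.approx(0.125)
        assert curve.linear_range == rng_

    def test_tightening_tolerance_never_widens_range(self):
        design = default_spike_design(["AAK"])
        rng = np.random.default_rng(31)
        for _ in range(20):
            pts = simulate_calibration(
                design, slope=rng.uniform(0.5, 3), intercept=0.0, cv=0.04,
                seed=int(rng.integers(1 << 30)), response_floor_conc=0.08,
            )
            lows = []
            for tol in (0.5, 0.3, 0.2, 0.1):
                try:
                    _, (lo, _) = determine_linear_range(pts, rel_bias_tol=tol)
                except NoLinearRangeError:
                    lo = np.inf
                lows.append(lo)
            assert all(a <= b + 1e-12 for a, b in zip(lows, lows[1:]))

    def test_no_linear_range_raises(self):
        x = np.repeat([1.0, 2.0, 4.0, 8.0], 2)
        y = np.array([5.0, 7.5, 1.0, 1.5, 9.0, 13.5, 2.0, 3.0])  # wildly nonlinear
        with pytest.raises(NoLinearRangeError):
            determine_linear_range(points_frame(x, y))


def fitted_curve(spike=1.0, slope=1.0, intercept=0.0, cv=0.0, seed=0):
    design = default_spike_design(["AAK"], spike_fmol_per_ul=spike)
    pts = simulate_calibration(design, slope=slope, intercept=intercept, cv=cv, seed=seed)
    curve, _ = determine_linear_range(pts)
    return curve


class TestQuantify:
    def test_ratio_at_one_to_one_returns_spike_amount(self):
        curve = fitted_curve(spike=1.0, slope=1.0)
        meas = pd.DataFrame(
            {"peptide_sequence": "AAK", "sample_id": ["S1"], "replicate_id": ["rep1"],
             "ratio": [1.0]}
        )
        out = quantify(meas, curve, spike_fmol_per_ul=1.0)
        assert out.loc[0, "log2_conc"] == pytest.approx(0.0, abs=1e-9)  # conc == spike == 1

    def test_doubling_spike_doubles_concentration(self):
        meas = pd.DataFrame(
            {"peptide_sequence": "AAK", "sample_id": ["S1"], "replicate_id": ["rep1"],
             "ratio": [2.5]}
        )
        curve = fitted_curve(spike=1.0)
        c1 = quantify(meas, curve, 1.0, calibration_spike_fmol_per_ul=1.0).loc[0, "log2_conc"]
        c2 = quantify(meas, curve, 2.0, calibration_spike_fmol_per_ul=1.0).loc[0, "log2_conc"]
        assert c2 == pytest.approx(c1 + 1.0, abs=1e-9)  # exactly x2 on the linear scale

    def test_single_valid_replicate_is_representative(self):
        curve = fitted_curve()
        meas = pd.DataFrame(
            {
                "peptide_sequence": "AAK",
                "sample_id": ["S1", "S1"],
                "replicate_id": ["rep1", "rep2"],
                "ratio": [1.0, 0.001],  # rep2 back-calculates below the LOQ
            }
        )
        out = quantify(meas, curve, 1.0)
        assert len(out) == 1
        assert out.loc[0, "n_replicates"] == 1
        assert out.loc[0, "log2_conc"] == pytest.approx(0.0, abs=1e-6)

    def test_loq_filter_idempotent(self):
        curve = fitted_curve()
        rng = np.random.default_rng(3)
        quant = pd.DataFrame(
            {"peptide_sequence": "AAK", "sample_id": [f"S{i}" for i in range(30)],
             "replicate_id": "rep1", "conc_injected": rng.uniform(0.0, 2.0, 30)}
        )
        once = apply_loq_filter(quant, curve.linear_range[0])
        twice = apply_loq_filter(once.drop(columns="below_loq"), curve.linear_range[0])
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_slope_rejected(self):
        curve = fitted_curve()
        curve.slope = -1.0
        with pytest.raises(ValueError, match="slope"):
            quantify(pd.DataFrame({"peptide_sequence": [], "sample_id": [],
                                   "replicate_id": [], "ratio": []}), curve, 1.0)

    def test_concentration_recovery_error_bounded_by_cv(self):
        """Round trip simulate -> qc -> quantify recovers true concentrations
        with mean absolute relative error at most the measurement CV."""
        cv = 0.05
        design = default_spike_design(["AAAAAAAAAK"])
        errs = []
        for seed in range(10):
            cal = simulate_calibration(design, slope=1.0, intercept=0.0, cv=cv, seed=seed)
            curve, _ = determine_linear_range(cal)
            manifest, rows, truth = simulate_prm_export(
                design, {"AAAAAAAAAK": -1.0}, n_patients=10, cv=cv, seed=seed,
                p_low_points=0.0, p_high_ppm=0.0, p_truncated=0.0,
            )
            meas, _ = qc_peaks(rows)
            out = quantify(meas, curve, 1.0)
            truth_long = truth.melt(
                id_vars=["peptide_sequence", "patient_id"],
                value_vars=["conc_baseline", "conc_followup"], value_name="true_conc",
            )
            truth_long["sample_id"] = truth_long["patient_id"] + np.where(
                truth_long["variable"] == "conc_baseline", "-BL", "-FU"
            )
            merged = out.merge(truth_long, on=["peptide_sequence", "sample_id"])
            rel = np.abs(2 ** merged["log2_conc"] - merged["true_conc"]) / merged["true_conc"]
            errs.append(rel.mean())
        assert float(np.mean(errs)) <= cv


class TestVerification:
    def test_constant_shift_zero_noise(self):
        manifest = build_manifest(4)
        quant = []
        for p in manifest.pairs().index:
            quant.append({"peptide_sequence": "AAK", "sample_id": f"{p}-BL", "log2_conc": 5.0})
            quant.append({"peptide_sequence": "AAK", "sample_id": f"{p}-FU", "log2_conc": 4.0})
        res = verify_differential(pd.DataFrame(quant), manifest)
        assert res.loc["AAK", "median_log2_fc"] == pytest.approx(-1.0)
        assert res.loc["AAK", "pct_changed"] == pytest.approx(100.0)
        assert res.loc["AAK", "zero_variance"]
        assert np.isnan(res.loc["AAK", "p_value"])

    def test_sign_recovery_under_noise(self):
        design = default_spike_design(["AAAAAAAAAK"])
        ok = 0
        n_runs = 20
        for seed in range(n_runs):
            cal = simulate_calibration(design, slope=1.0, intercept=0.0, cv=0.05, seed=seed)
            curve, _ = determine_linear_range(cal)
            manifest, rows, _ = simulate_prm_export(
                design, {"AAAAAAAAAK": -1.3}, n_patients=20, cv=0.3, seed=100 + seed,
            )
            meas, _ = qc_peaks(rows)
            out = quantify(meas, curve, 1.0)
            res = verify_differential(out, manifest, n_boot=200)
            ok += res.loc["AAAAAAAAAK", "median_log2_fc"] < 0
        assert ok / n_runs >= 0.95

    def test_matches_discovery_statistics_on_identical_matrix(self):
        """Feeding the same paired matrix through the verification and the
        discovery paths yields identical t / p / FDR."""
        manifest = build_manifest(6)
        rng = np.random.default_rng(8)
        log2_conc = rng.normal(3, 1, size=(4, 12))
        peps = [f"PEP{i}K" for i in range(4)]
        quant = pd.DataFrame(
            [
                {"peptide_sequence": pep, "sample_id": sid, "log2_conc": log2_conc[i, j]}
                for i, pep in enumerate(peps)
                for j, sid in enumerate(manifest.sample_ids)
            ]
        )
        res = verify_differential(quant, manifest)
        table = build_table(
            pd.DataFrame(2.0 ** log2_conc, index=pd.Index(peps, name="accession"),
                         columns=manifest.sample_ids)
        )
        disc = paired_test(table, manifest)
        for pep in peps:
            assert res.loc[pep, "t_stat"] == pytest.approx(disc.loc[pep, "t_stat"], rel=1e-10)
            assert res.loc[pep, "p_value"] == pytest.approx(disc.loc[pep, "p_value"], rel=1e-10)
            assert res.loc[pep, "fdr"] == pytest.approx(disc.loc[pep, "fdr"], rel=1e-10)
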