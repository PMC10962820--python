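"""Targeted (PRM) verification workflow: transition-level peak QC, weighted
calibration-curve fitting, linear-range/LOQ determination, concentration
computation with replicate handling, and paired verification statistics.

The reverse calibration curve varies the heavy standard against a constant
pool; the quantitative readout per measurement is the summed-fragment
light/heavy ratio (orientation configurable), modelled as linear in the
theoretical concentration (fmol/ul injected) with 1/concentration weights —
low-concentration points are more reproducible, high-concentration points
more variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .discovery import bh_adjust, bootstrap_median_ci, paired_t_from_diffs, summarize_fc
from .io import FormatError, SampleManifest

__all__ = [
    "CalibrationCurve",
    "NoLinearRangeError",
    "qc_peaks",
    "fit_calibration",
    "determine_linear_range",
    "quantify",
    "apply_loq_filter",
    "verify_differential",
    "read_calibration_points",
    "write_calibration_points",
]


class NoLinearRangeError(ValueError):
    """No lower trim of the dilution series meets the back-calculation bias tolerance."""


@dataclass
class CalibrationCurve:
    """Weighted linear fit of ratio-to-standard vs theoretical concentration."""

    peptide: str
    slope: float
    intercept: float
    r_squared_weighted: float
    points_used: int
    conc_min: float
    conc_max: float
    weight_rule: str = "1/theoretical_conc"
    linear_range: tuple[float, float] | None = None

    def back_calculate(self, ratio: np.ndarray | float) -> np.ndarray | float:
        """Concentration implied by an observed ratio: (ratio - a) / b."""
        return (np.asarray(ratio, dtype=float) - self.intercept) / self.slope

    def as_dict(self) -> dict:
        d = asdict(self)
        d["linear_range"] = list(self.linear_range) if self.linear_range else None
        return d


# --- calibration point tables -------------------------------------------------

CALIBRATION_COLUMNS = ["peptide_sequence", "theoretical_conc", "replicate_id", "ratio_to_standard"]


def read_calibration_points(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in CALIBRATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"calibration points missing column: {col!r}")
    out = df[CALIBRATION_COLUMNS].copy()
    out["theoretical_conc"] = pd.to_numeric(out["theoretical_conc"]).astype(float)
    out["ratio_to_standard"] = pd.to_numeric(out["ratio_to_standard"]).astype(float)
    if (out["theoretical_conc"] <= 0).any():
        raise FormatError("theoretical concentrations must be positive")
    return out


def write_calibration_points(points: pd.DataFrame, path) -> None:
    points[CALIBRATION_COLUMNS].to_csv(path, index=False)


# --- peak QC -------------------------------------------------------------------

def qc_peaks(
    rows: pd.DataFrame,
    min_fragments: int = 3,
    min_points: int = 8,
    max_ppm: float = 10.0,
    orientation: str = "light_over_heavy",
) -> tuple[pd.DataFrame, dict]:
    """Transition-level QC and per-measurement ratio computation.

    Fragments with |mass error| above ``max_ppm`` are dropped; a measurement
    (peptide, sample, replicate) is kept only if at least ``min_fragments``
    fragments survive and the peak has at least ``min_points`` points.  If a
    replicate's peak is truncated while a sibling replicate's is not, the
    non-truncated replicate alone is considered representative.  The ratio is
    the quotient of summed surviving light and heavy fragment areas.
    """
    if orientation not in {"light_over_heavy", "heavy_over_light"}:
        raise ValueError("orientation must be light_over_heavy or heavy_over_light")
    report = {
        "n_rows": len(rows),
        "n_fragments_high_ppm": int((rows["mass_error_ppm"].abs() > max_ppm).sum()),
        "n_rejected_few_fragments": 0,
        "n_rejected_few_points": 0,
        "n_dropped_truncated": 0,
        "n_invalid_zero_heavy": 0,
        "n_accepted": 0,
    }
    ok = rows[rows["mass_error_ppm"].abs() <= max_ppm]
    measurements = []
    for (pep, sample, rep), grp in ok.groupby(
        ["peptide_sequence", "sample_id", "replicate_id"], sort=True
    ):
        points = int(grp["points_across_peak"].iloc[0])
        if len(grp) < min_fragments:
            report["n_rejected_few_fragments"] += 1
            continue
        if points < min_points:
            report["n_rejected_few_points"] += 1
            continue
        light, heavy = float(grp["light_area"].sum()), float(grp["heavy_area"].sum())
        denom = heavy if orientation == "light_over_heavy" else light
        numer = light if orientation == "light_over_heavy" else heavy
        if denom == 0:
            report["n_invalid_zero_heavy"] += 1
            continue
        measurements.append(
            {
                "peptide_sequence": pep,
                "sample_id": sample,
                "replicate_id": rep,
                "ratio": numer / denom,
                "n_fragments": len(grp),
                "truncated": bool(grp["truncated"].any()),
            }
        )
    meas = pd.DataFrame(
        measurements,
        columns=["peptide_sequence", "sample_id", "replicate_id", "ratio", "n_fragments", "truncated"],
    )
    if len(meas):
        # truncated replicate dropped only when a non-truncated sibling exists
        keep = np.ones(len(meas), dtype=bool)
        for _, grp in meas.groupby(["peptide_sequence", "sample_id"], sort=False):
            if grp["truncated"].any() and (~grp["truncated"]).any():
                keep[grp.index[grp["truncated"]]] = False
        report["n_dropped_truncated"] = int((~keep).sum())
        meas = meas[keep].reset_index(drop=True)
    report["n_accepted"] = len(meas)
    return meas, report


# --- calibration fitting --------------------------------------------------------

def fit_calibration(
    points: pd.DataFrame,
    peptide: str | None = None,
    min_span_orders: float = 1.0,
    enforce_span: bool = True,
) -> CalibrationCurve:
    """Weighted least squares of ratio on concentration, weights = 1/concentration.

    Minimizes sum w_i (y_i - a - b x_i)^2; requires >=3 points and, by
    default, a concentration span of at least one order of magnitude.
    """
    if peptide is None:
        peps = points["peptide_sequence"].unique()
        if len(peps) != 1:
            raise ValueError("points contain multiple peptides; pass `peptide`")
        peptide = str(peps[0])
        sub = points
    else:
        sub = points[points["peptide_sequence"] == peptide]
    x = sub["theoretical_conc"].to_numpy(dtype=float)
    y = sub["ratio_to_standard"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 calibration points, got {len(x)}")
    if np.allclose(x, x[0]):
        raise ValueError("all concentrations identical; cannot fit a line")
    if (x <= 0).any():
        raise ValueError("theoretical concentrations must be positive")
    span = np.log10(x.max() / x.min())
    if enforce_span and span < min_span_orders:
        raise ValueError(
            f"calibration points span {span:.2f} orders of magnitude, need >= {min_span_orders}"
        )
    res = sm.WLS(y, sm.add_constant(x), weights=1.0 / x).fit()
    return CalibrationCurve(
        peptide=peptide,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared_weighted=float(res.rsquared),
        points_used=len(x),
        conc_min=float(x.min()),
        conc_max=float(x.max()),
    )


def determine_linear_range(
    points: pd.DataFrame,
    rel_bias_tol: float = 0.20,
    peptide: str | None = None,
) -> tuple[CalibrationCurve, tuple[float, float]]:
    """Automated linear-range determination by back-calculated bias.

    Starting from the full dilution series, the lowest level is trimmed until
    a weighted refit on the retained levels back-calculates every retained
    level's mean concentration within ``rel_bias_tol`` relative bias.  The
    retained bottom level is the lower limit of quantification; the top level
    closes the range.
    """
    if peptide is not None:
        points = points[points["peptide_sequence"] == peptide]
    levels = np.sort(points["theoretical_conc"].unique())
    if len(levels) < 3:
        raise ValueError("need at least 3 concentration levels")
    for i in range(len(levels) - 2):
        retained = points[points["theoretical_conc"] >= levels[i]]
        curve = fit_calibration(retained, peptide=peptide, enforce_span=False)
        ok = True
        for level in levels[i:]:
            ratios = retained.loc[
                retained["theoretical_conc"] == level, "ratio_to_standard"
            ].to_numpy()
            back = float(np.mean(curve.back_calculate(ratios)))
            if abs(back - level) / level > rel_bias_tol:
                ok = False
                break
        if ok:
            curve.linear_range = (float(levels[i]), float(levels[-1]))
            return curve, curve.linear_range
    raise NoLinearRangeError(
        f"no lower trim of the series meets relative bias <= {rel_bias_tol}"
    )


# --- quantification --------------------------------------------------------------

def apply_loq_filter(quant: pd.DataFrame, conc_lo: float) -> pd.DataFrame:
    """Flag and drop back-calculated concentrations below the linear range."""
    out = quant.copy()
    out["below_loq"] = ~(out["conc_injected"] >= conc_lo)  # NaN and <=0 also flagged
    return out[~out["below_loq"]].reset_index(drop=True)


def quantify(
    measurements: pd.DataFrame,
    curve: CalibrationCurve,
    spike_fmol_per_ul: float,
    calibration_spike_fmol_per_ul: float | None = None,
    injection_to_sample: float = 1.0,
) -> pd.DataFrame:
    """Per-sample peptide concentration from QC'd ratios via the calibration curve.

    concentration (fmol/ul injected, calibration scale) = (ratio - intercept)
    / slope; values below the curve's linear range are flagged ``below_loq``
    and dropped; the rest are rescaled by the sample's heavy spike level
    relative to the calibration's nominal spike (the reported concentration
    is proportional to the assumed spike), converted to fmol/ul sample,
    log2-transformed and averaged over trypsinated replicates (a single
    valid replicate is considered representative on its own).
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive for quantification")
    if curve.linear_range is None:
        raise ValueError("curve has no linear range; run determine_linear_range first")
    cal_spike = (
        calibration_spike_fmol_per_ul if calibration_spike_fmol_per_ul is not None else spike_fmol_per_ul
    )
    sub = measurements[measurements["peptide_sequence"] == curve.peptide].copy()
    sub["conc_injected"] = curve.back_calculate(sub["ratio"].to_numpy())
    conc_lo = curve.linear_range[0]
    kept = apply_loq_filter(sub, conc_lo)
    n_below = len(sub) - len(kept)
    if not len(kept):
        return pd.DataFrame(
            columns=["peptide_sequence", "sample_id", "log2_conc", "n_replicates", "n_below_loq"]
        )
    kept["conc_sample"] = (
        kept["conc_injected"] * (spike_fmol_per_ul / cal_spike) * injection_to_sample
    )
    kept["log2_conc"] = np.log2(kept["conc_sample"])
    out = (
        kept.groupby(["peptide_sequence", "sample_id"], sort=True)
        .agg(log2_conc=("log2_conc", "mean"), n_replicates=("log2_conc", "size"))
        .reset_index()
    )
    out["n_below_loq"] = n_below
    # spike level recorded for unit bookkeeping (fmol/ul injected at nominal 1:1)
    out["spike_fmol_per_ul"] = spike_fmol_per_ul
    return out


# --- paired verification statistics ----------------------------------------------

def verify_differential(
    quant: pd.DataFrame,
    manifest: SampleManifest,
    alpha: float = 0.05,
    min_pairs: int = 2,
    ci: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired verification statistics per peptide at the verification FDR level.

    Mirrors the discovery statistics (median log2 fold change, concordance
    percentage, paired t, BH) on the log2 concentrations; adds a seeded
    percentile-bootstrap CI of the median fold change.  Peptides with fewer
    than ``min_pairs`` complete pairs are flagged ``skipped``.
    """
    wide = quant.pivot_table(
        index="peptide_sequence", columns="sample_id", values="log2_conc", aggfunc="mean"
    )
    pairs = manifest.pairs()
    base = wide.reindex(columns=pairs["baseline"]).to_numpy(dtype=float)
    follow = wide.reindex(columns=pairs["followup"]).to_numpy(dtype=float)
    d = follow - base

    n = (~np.isnan(d)).sum(axis=1)
    fc_df = pd.DataFrame(d, index=wide.index, columns=pairs.index)
    tested = fc_df.index[n >= max(min_pairs, 1)]
    summary = summarize_fc(fc_df.loc[tested]) if len(tested) else pd.DataFrame()
    tstats = paired_t_from_diffs(d, min_pairs=min_pairs)
    tstats.index = wide.index

    rows = []
    rng = np.random.default_rng(seed)
    for pep in wide.index:
        row = {"peptide_sequence": pep, "n_pairs": int(n[wide.index.get_loc(pep)])}
        row["skipped"] = row["n_pairs"] < min_pairs
        if pep in summary.index:
            row["median_log2_fc"] = float(summary.loc[pep, "median_log2_fc"])
            row["pct_changed"] = float(summary.loc[pep, "pct_changed"])
            vals = fc_df.loc[pep].dropna().to_numpy()
            if len(vals) >= 2:
                lo, hi = bootstrap_median_ci(
                    vals, n_boot=n_boot, ci=ci, seed=int(rng.integers(2**31))
                )
                row["ci_lo"], row["ci_hi"] = lo, hi
        row["t_stat"] = float(tstats.loc[pep, "t_stat"])
        row["p_value"] = float(tstats.loc[pep, "p_value"])
        row["zero_variance"] = bool(tstats.loc[pep, "zero_variance"])
        rows.append(row)
    res = pd.DataFrame(rows).set_index("peptide_sequence")
    res["fdr"] = bh_adjust(res["p_value"])
    res["significant"] = (res["fdr"] < alpha).fillna(False)
    return res


def fit_all_curves(
    points: pd.DataFrame, rel_bias_tol: float = 0.20
) -> dict[str, CalibrationCurve]:
    """Fit and range-determine one curve per peptide in a points table."""
    curves: dict[str, CalibrationCurve] = {}
    for pep in sorted(points["peptide_sequence"].unique()):
        curve, _ = determine_linear_range(points, rel_bias_tol=rel_bias_tol, peptide=pep)
        curves[pep] = curve
    return curves
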