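"""End-to-end orchestration: simulate -> discovery -> compare -> enrich ->
prm-calibrate -> prm-quant, with one config, per-stage derived seeds and a
machine-readable run summary.

Every stage writes its artifacts under the output directory; the summary
JSON carries per-stage counts plus all seeds and thresholds, and is
byte-identical across runs of the same config.
"""

from __future__ import annotations

import json
import string
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import categorize
from .config import RunConfig
from .discovery import run_discovery
from .enrichment import enrich
from .io import (
    SampleManifest,
    read_keyword_map,
    read_manifest,
    read_prm_export,
    read_protein_table,
    read_reference_diffset,
    read_spike_design,
    read_term_annotations,
    write_keyword_map,
    write_manifest,
    write_prm_export,
    write_protein_table,
    write_reference_diffset,
    write_spike_design,
    write_term_annotations,
)
from .prm import (
    fit_all_curves,
    qc_peaks,
    quantify,
    read_calibration_points,
    verify_differential,
    write_calibration_points,
)
from .simulate import (
    SimulationConfig,
    assign_scheme,
    default_spike_design,
    simulate_calibration,
    simulate_cohort,
    simulate_prm_export,
    simulate_reference_diffset,
    simulate_term_annotations,
)

_PEPTIDE_ALPHABET = [c for c in string.ascii_uppercase if c in "ADEFGHIKLNPQRSTVWY"]


def _synthetic_peptide(rng: np.random.Generator, length: int = 10) -> str:
    body = "".join(rng.choice(_PEPTIDE_ALPHABET, size=length - 1))
    return body + str(rng.choice(["K", "R"]))


def simulate_inputs(config: RunConfig, outdir: str | Path, sim_overrides: dict | None = None) -> dict:
    """Generate and write every pipeline input plus the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(sim_overrides or {})
    overrides.setdefault("seed", config.stage_seed("simulate"))
    sim_cfg = SimulationConfig(**overrides)

    manifest, table, keyword_map, truth = simulate_cohort(sim_cfg)
    write_manifest(manifest, outdir / "manifest.tsv")
    write_protein_table(table, outdir / "protein_table.tsv")
    write_keyword_map(keyword_map, outdir / "keywords.tsv")

    n_changed = int((truth.proteins["true_shift_log2"] != 0).sum())
    n_unchanged = len(truth.proteins) - n_changed
    n_per_cat = max(1, min(10, n_changed // 3, n_unchanged // 3))
    scheme = assign_scheme(truth, n_per_cat)
    reference = simulate_reference_diffset(truth, scheme)
    write_reference_diffset(reference, outdir / "reference.tsv")
    pd.Series(scheme, name="category").rename_axis("accession").to_csv(
        outdir / "ground_truth_scheme.tsv", sep="\t"
    )

    annotations, enriched_terms = simulate_term_annotations(
        truth, seed=config.stage_seed("annotations")
    )
    write_term_annotations(annotations, outdir / "term_annotations.tsv")

    # PRM: peptides stand for the strongest injected shifts
    rng = np.random.default_rng(config.stage_seed("prm-design"))
    shifts = truth.proteins["true_shift_log2"]
    chosen = shifts.reindex(shifts.abs().sort_values(ascending=False).index)[:6]
    peptides = {_synthetic_peptide(rng): float(s) for s in chosen}
    design = default_spike_design(sorted(peptides))
    write_spike_design(design, outdir / "spike_design.tsv")
    cal_points = simulate_calibration(
        design, slope=1.0, intercept=0.0, cv=0.05, seed=config.stage_seed("calibration")
    )
    write_calibration_points(cal_points, outdir / "calibration_points.csv")
    prm_manifest, prm_rows, prm_truth = simulate_prm_export(
        design, peptides, n_patients=20, cv=0.05, seed=config.stage_seed("prm-export")
    )
    write_manifest(prm_manifest, outdir / "prm_manifest.tsv")
    write_prm_export(prm_rows, outdir / "prm_export.csv")
    prm_truth.to_csv(outdir / "prm_ground_truth.tsv", sep="\t", index=False)
    truth.proteins.to_csv(outdir / "ground_truth.tsv", sep="\t")

    return {
        "simulation": sim_cfg.__dict__,
        "n_proteins": len(table),
        "n_patients": len(manifest),
        "n_reference_entries": len(reference),
        "n_enriched_terms": len(enriched_terms),
        "n_prm_peptides": len(peptides),
    }


def run_all(config: RunConfig, outdir: str | Path, sim_overrides: dict | None = None) -> dict:
    """Execute every stage on (freshly simulated or existing) inputs.

    If ``config.input_dir`` is unset, inputs are simulated into
    ``outdir/inputs`` first.  Returns the run summary (also written as
    ``run_summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            s: config.stage_seed(s)
            for s in ("simulate", "annotations", "prm-design", "calibration", "prm-export")
        },
        "thresholds": {
            "discovery_fdr": config.discovery_fdr,
            "z_alpha": config.z_alpha,
            "concordance_pct": config.concordance_pct,
            "verification_fdr": config.verification_fdr,
            "enrichment_fdr": config.enrichment_fdr,
            "min_pairs": config.min_pairs,
            "qc": config.qc.model_dump(),
            "rel_bias_tol": config.rel_bias_tol,
        },
    }

    if config.input_dir:
        indir = Path(config.input_dir)
    else:
        indir = outdir / "inputs"
        summary["simulate"] = simulate_inputs(config, indir, sim_overrides)

    summary.update(run_stages(config, indir, outdir))
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return summary


def run_stages(config: RunConfig, indir: str | Path, outdir: str | Path) -> dict:
    """Discovery, comparison, enrichment and PRM stages on existing inputs."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # --- discovery
    manifest = read_manifest(indir / "manifest.tsv")
    table = read_protein_table(indir / "protein_table.tsv", manifest)
    keyword_map = read_keyword_map(indir / "keywords.tsv")
    records, report = run_discovery(
        table,
        manifest,
        keyword_map,
        discovery_fdr=config.discovery_fdr,
        z_alpha=config.z_alpha,
        concordance_pct=config.concordance_pct,
        min_pairs=config.min_pairs,
        force_include=config.force_include,
        ig_keywords=config.immunoglobulin_keywords,
    )
    records.to_csv(outdir / "differential_results.tsv", sep="\t")
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    summary["discovery"] = {
        "filter": report.as_dict(),
        "n_significant": int(records["significant"].sum()),
        "n_immunoglobulin": int(records["is_immunoglobulin"].sum()),
        "n_significant_immunoglobulin": int(
            (records["significant"] & records["is_immunoglobulin"]).sum()
        ),
        "n_high_fc": int(records["high_fc"].sum()),
        "n_candidates": int(records["candidate"].sum()),
    }

    # --- comparison with the reference differential list
    reference = read_reference_diffset(indir / "reference.tsv")
    assignments, cmp_summary = categorize(records, reference, discovery_fdr=config.discovery_fdr)
    assignments.to_csv(outdir / "categories.tsv", sep="\t")
    with open(outdir / "category_summary.json", "w") as fh:
        json.dump(cmp_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    summary["compare"] = cmp_summary["category_counts"]

    # --- GO over-representation
    annotations = read_term_annotations(indir / "term_annotations.tsv")
    subset = list(records.index[records["significant"]])
    background = list(records.index)
    enr = enrich(
        subset,
        background,
        annotations,
        exclude_evidence=config.exclude_evidence,
        alpha=config.enrichment_fdr,
    )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    summary["enrich"] = {
        "n_terms_tested": len(enr),
        "n_significant": int(enr["significant"].sum()) if len(enr) else 0,
    }

    # --- PRM calibration
    cal_points = read_calibration_points(indir / "calibration_points.csv")
    curves = fit_all_curves(cal_points, rel_bias_tol=config.rel_bias_tol)
    curve_rows = pd.DataFrame([c.as_dict() for c in curves.values()])
    curve_rows.to_csv(outdir / "calibration_curves.tsv", sep="\t", index=False)
    summary["prm_calibrate"] = {
        "n_curves": len(curves),
        "mean_r_squared": float(np.mean([c.r_squared_weighted for c in curves.values()]))
        if curves
        else None,
    }

    # --- PRM quantification + verification statistics
    design = read_spike_design(indir / "spike_design.tsv")
    prm_manifest = read_manifest(indir / "prm_manifest.tsv")
    prm_rows = read_prm_export(indir / "prm_export.csv")
    meas, qc_report = qc_peaks(
        prm_rows,
        min_fragments=config.qc.min_fragments,
        min_points=config.qc.min_points_across_peak,
        max_ppm=config.qc.max_ppm,
        orientation=config.ratio_orientation,
    )
    spike = design.set_index("peptide_sequence")["spike_fmol_per_ul"]
    quants = []
    for pep, curve in curves.items():
        if pep not in spike.index:
            continue
        quants.append(quantify(meas, curve, float(spike.loc[pep])))
    quant = (
        pd.concat(quants, ignore_index=True)
        if quants
        else pd.DataFrame(columns=["peptide_sequence", "sample_id", "log2_conc"])
    )
    quant.to_csv(outdir / "prm_concentrations.tsv", sep="\t", index=False)
    verification = verify_differential(
        quant,
        prm_manifest,
        alpha=config.verification_fdr,
        min_pairs=config.min_pairs,
        seed=config.stage_seed("verification-bootstrap"),
    )
    verification.to_csv(outdir / "verification_results.tsv", sep="\t")
    summary["prm_quant"] = {
        "qc": qc_report,
        "n_peptides_quantified": int(verification.shape[0]),
        "n_significant": int(verification["significant"].sum()) if len(verification) else 0,
    }
    return summary
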