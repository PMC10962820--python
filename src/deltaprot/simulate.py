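"""Synthetic paired-cohort, annotation, reference and PRM data with known truth.

The generator emulates the statistical structure the discovery analysis
assumes: log2 protein intensities with a between-protein baseline spread,
per-patient random intercepts shared by the sample pair, an additive
treatment shift for the changed proteins, a coherent negative shift for the
immunoglobulin-like class, and abundance-dependent missingness (logistic in
log2 abundance).  Everything is a pure function of its config/seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import ProteinQuantTable, SampleManifest

CATEGORIES = ("opposite", "equal", "treatment_only", "disease_only", "not_changed", "unmatched")

#: Nine-point reverse dilution series: 8x the nominal 1:1 level down to 0.03x.
DEFAULT_DILUTION_SERIES = (8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.06, 0.03)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated paired discovery cohort.

    Defaults mirror the scale of a 56-patient CSF discovery study with ~1200
    quantified proteins, ~25% of non-immunoglobulin proteins changed by
    treatment and ~60 immunoglobulins coherently decreased. All spreads are
    on the log2 scale.
    """

    n_patients: int = 56
    n_proteins: int = 1200
    frac_immunoglobulin: float = 0.05
    frac_changed: float = 0.25
    effect_size_log2: float = 0.5
    ig_effect_log2: float = -0.8
    patient_sd: float = 0.5
    protein_sd: float = 2.0
    noise_sd: float = 0.3
    missing_base_rate: float = 0.10
    missing_abundance_slope: float = 0.8
    ig_missing_extra: float = 1.0  # extra logit offset for the Ig class
    baseline_mean_log2: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_immunoglobulin", "frac_changed", "missing_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("patient_sd", "protein_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_patients < 2:
            raise ValueError("paired analysis needs at least 2 patients")


@dataclass
class GroundTruth:
    """Per-protein truth emitted alongside a simulated cohort."""

    proteins: pd.DataFrame  # index accession: true_shift_log2, is_immunoglobulin, baseline_log2
    patient_intercepts: pd.Series = field(default_factory=pd.Series)

    @property
    def changed(self) -> pd.Index:
        return self.proteins.index[self.proteins["true_shift_log2"] != 0.0]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[SampleManifest, ProteinQuantTable, dict[str, frozenset[str]], GroundTruth]:
    """Simulate a paired pre/post-treatment cohort with known per-protein shifts.

    Follow-up log2 intensity = baseline + true shift + residual noise, with
    the patient intercept shared by the pair; missingness probability
    increases as abundance decreases.
    """
    rng = np.random.default_rng(config.seed)
    n_p, n_i = config.n_proteins, config.n_patients

    patients = [f"PT{i + 1:03d}" for i in range(n_i)]
    baseline_ids = [f"{p}-BL" for p in patients]
    followup_ids = [f"{p}-FU" for p in patients]
    manifest = SampleManifest(
        pd.DataFrame(
            {
                "patient_id": patients * 2,
                "sample_id": baseline_ids + followup_ids,
                "timepoint": ["baseline"] * n_i + ["followup"] * n_i,
            }
        )
    )

    accessions = [f"SP{k + 1:05d}" for k in range(n_p)]
    n_ig = int(round(config.frac_immunoglobulin * n_p))
    is_ig = np.zeros(n_p, dtype=bool)
    is_ig[rng.choice(n_p, size=n_ig, replace=False)] = True

    shifts = np.zeros(n_p)
    non_ig_idx = np.flatnonzero(~is_ig)
    n_changed = int(round(config.frac_changed * len(non_ig_idx)))
    changed_idx = rng.choice(non_ig_idx, size=n_changed, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_changed)
    shifts[changed_idx] = signs * config.effect_size_log2
    shifts[is_ig] = config.ig_effect_log2

    mu = rng.normal(config.baseline_mean_log2, config.protein_sd, size=n_p)
    b = rng.normal(0.0, config.patient_sd, size=n_i)
    eps = rng.normal(0.0, config.noise_sd, size=(n_p, n_i, 2)) if config.noise_sd > 0 else np.zeros((n_p, n_i, 2))

    log2_true = mu[:, None, None] + b[None, :, None] + eps
    log2_true[:, :, 1] += shifts[:, None]

    if config.missing_base_rate > 0:
        offset = logit(config.missing_base_rate)
        p_miss = expit(
            offset
            + config.missing_abundance_slope * (config.baseline_mean_log2 - log2_true)
            + config.ig_missing_extra * is_ig[:, None, None]
        )
        missing = rng.random(size=log2_true.shape) < p_miss
    else:
        missing = np.zeros(log2_true.shape, dtype=bool)

    intensity = np.exp2(log2_true)
    intensity[missing] = np.nan

    meta = pd.DataFrame(
        {
            "gene_name": [f"GN{k + 1}" for k in range(n_p)],
            "unique_peptides": rng.integers(1, 30, size=n_p),
            "reverse": False,
            "contaminant": False,
            "only_identified_by_site": False,
        },
        index=pd.Index(accessions, name="accession"),
    )
    inten = pd.DataFrame(
        np.concatenate([intensity[:, :, 0], intensity[:, :, 1]], axis=1),
        index=meta.index,
        columns=baseline_ids + followup_ids,
    )
    table = ProteinQuantTable(meta, inten)

    keyword_map = {
        acc: (frozenset({"Immunoglobulin", "KW-1280"}) if ig else frozenset({"Secreted"}))
        for acc, ig in zip(accessions, is_ig)
    }
    truth = GroundTruth(
        proteins=pd.DataFrame(
            {
                "true_shift_log2": shifts,
                "is_immunoglobulin": is_ig,
                "baseline_log2": mu,
            },
            index=meta.index,
        ),
        patient_intercepts=pd.Series(b, index=patients),
    )
    return manifest, table, keyword_map, truth


# --- reference differential list ------------------------------------------------

def assign_scheme(truth: GroundTruth, n_per_category: int) -> dict[str, str]:
    """Deterministically assign proteins to the six concordance categories.

    Categories involving a treatment change draw from proteins with a true
    shift; the others draw from unchanged proteins.
    """
    shifts = truth.proteins["true_shift_log2"]
    changed = list(shifts.index[shifts != 0.0])
    unchanged = list(shifts.index[shifts == 0.0])
    need_changed = 3 * n_per_category
    need_unchanged = 3 * n_per_category
    if len(changed) < need_changed or len(unchanged) < need_unchanged:
        raise ValueError(
            f"scheme needs {need_changed} changed and {need_unchanged} unchanged proteins; "
            f"truth has {len(changed)} and {len(unchanged)}"
        )
    scheme: dict[str, str] = {}
    for i, cat in enumerate(("opposite", "equal", "treatment_only")):
        for acc in changed[i * n_per_category:(i + 1) * n_per_category]:
            scheme[acc] = cat
    for i, cat in enumerate(("disease_only", "not_changed", "unmatched")):
        for acc in unchanged[i * n_per_category:(i + 1) * n_per_category]:
            scheme[acc] = cat
    return scheme


def simulate_reference_diffset(truth: GroundTruth, scheme: Mapping[str, str]) -> pd.DataFrame:
    """Build a disease-vs-control reference list realizing a category scheme.

    Directions are constructed from the true treatment shifts so that the
    downstream categorizer must recover the scheme exactly (at zero noise).
    """
    shifts = truth.proteins["true_shift_log2"]
    rows = []
    for i, (acc, cat) in enumerate(scheme.items()):
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r} for {acc}")
        shift = float(shifts.loc[acc])
        treat = "increased" if shift > 0 else "decreased" if shift < 0 else "unchanged"
        if cat in ("opposite", "equal", "treatment_only") and treat == "unchanged":
            raise ValueError(f"category {cat!r} needs a nonzero true shift ({acc})")
        if cat in ("disease_only", "not_changed") and treat != "unchanged":
            raise ValueError(f"category {cat!r} needs a zero true shift ({acc})")
        if cat == "opposite":
            direction = "decreased" if treat == "increased" else "increased"
        elif cat == "equal":
            direction = treat
        elif cat == "treatment_only":
            direction = "unchanged"
        elif cat == "disease_only":
            direction = "increased" if i % 2 == 0 else "decreased"
        elif cat == "not_changed":
            direction = "unchanged"
        else:  # unmatched: absent from the reference list
            continue
        rows.append({"accession": acc, "direction": direction})
    return pd.DataFrame(rows, columns=["accession", "direction"])


# --- term annotations ------------------------------------------------------------

def simulate_term_annotations(
    truth: GroundTruth,
    n_terms: int = 30,
    n_enriched: int = 5,
    term_size: tuple[int, int] = (10, 40),
    frac_from_changed: float = 0.8,
    frac_iea: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Flat GO-BP-like annotations where a few terms preferentially annotate
    the truly changed proteins. Returns (annotation table, enriched term ids).

    Enriched-term members drawn from the changed set carry experimental
    evidence codes; IEA codes are sprinkled on the rest so that evidence
    filtering is exercised without erasing the signal.
    """
    rng = np.random.default_rng(seed)
    all_acc = np.asarray(truth.proteins.index)
    changed = np.asarray(truth.changed)
    exp_codes = np.array(["EXP", "IDA", "IMP"])
    rows = []
    enriched_ids = []
    for t in range(n_terms):
        term_id = f"GO:{7000000 + t}"
        term_name = f"process {t + 1}"
        size = int(rng.integers(term_size[0], term_size[1] + 1))
        enriched = t < n_enriched and len(changed) > 0
        if enriched:
            enriched_ids.append(term_id)
            n_from_changed = min(int(round(frac_from_changed * size)), len(changed))
            members = list(rng.choice(changed, size=n_from_changed, replace=False))
            rest = np.setdiff1d(all_acc, members)
            members += list(rng.choice(rest, size=size - n_from_changed, replace=False))
        else:
            members = list(rng.choice(all_acc, size=min(size, len(all_acc)), replace=False))
        for acc in members:
            from_changed = enriched and acc in set(changed)
            if from_changed or rng.random() > frac_iea:
                code = str(rng.choice(exp_codes))
            else:
                code = "IEA"
            rows.append(
                {"term_id": term_id, "term_name": term_name, "accession": acc, "evidence_code": code}
            )
    return pd.DataFrame(rows), enriched_ids


# --- calibration curves -----------------------------------------------------------

def default_spike_design(
    peptides: Sequence[str],
    spike_fmol_per_ul: float = 1.0,
    dilution_factors: Sequence[float] = DEFAULT_DILUTION_SERIES,
) -> pd.DataFrame:
    """Nine-point reverse dilution design (8x..0.03x of the nominal 1:1 level)."""
    return pd.DataFrame(
        {
            "peptide_sequence": list(peptides),
            "spike_fmol_per_ul": float(spike_fmol_per_ul),
            "dilution_factors": [tuple(float(x) for x in dilution_factors)] * len(peptides),
        }
    )


def _cv_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def simulate_calibration(
    design: pd.DataFrame,
    slope: float,
    intercept: float,
    cv: float,
    n_replicates: int = 2,
    seed: int = 0,
    response_floor_conc: float | None = None,
) -> pd.DataFrame:
    """Simulate calibration points: ratio = slope*conc + intercept, with
    multiplicative noise of the given coefficient of variation.

    ``response_floor_conc`` turns on a low-end response floor (interference /
    detection-limit plateau): below that concentration the mean response
    stops tracking the dilution, creating a detectable nonlinear region at
    the bottom of the series.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in design.iterrows():
        concs = row["spike_fmol_per_ul"] * np.asarray(row["dilution_factors"], dtype=float)
        mean = slope * concs + intercept
        if response_floor_conc is not None:
            mean = slope * np.maximum(concs, response_floor_conc) + intercept
        for r in range(n_replicates):
            noise = _cv_noise(rng, cv, len(concs))
            for conc, val in zip(concs, mean * noise):
                rows.append(
                    {
                        "peptide_sequence": row["peptide_sequence"],
                        "theoretical_conc": conc,
                        "replicate_id": f"rep{r + 1}",
                        "ratio_to_standard": val,
                    }
                )
    return pd.DataFrame(rows)


# --- PRM patient measurements ------------------------------------------------------

def simulate_prm_export(
    design: pd.DataFrame,
    effects: Mapping[str, float],
    n_patients: int = 20,
    slope: float = 1.0,
    intercept: float = 0.0,
    cv: float = 0.1,
    between_patient_sd: float = 0.5,
    n_fragments: int = 4,
    n_replicates: int = 2,
    p_low_points: float = 0.02,
    p_high_ppm: float = 0.04,
    p_truncated: float = 0.02,
    seed: int = 0,
) -> tuple[SampleManifest, pd.DataFrame, pd.DataFrame]:
    """Simulate a Skyline-style PRM export for a paired verification cohort.

    Each peptide's baseline concentration is log-normal around the 1:1 spike
    level; follow-up = baseline shifted by the peptide's true log2 effect.
    The measured light/heavy ratio responds linearly to concentration and is
    spread over fragments; occasional low-point-count, high-ppm and truncated
    records exercise the QC rules.

    Returns (manifest, export rows, truth) where truth has one row per
    (peptide, patient) with true baseline/followup concentrations (fmol/ul).
    """
    rng = np.random.default_rng(seed)
    patients = [f"VP{i + 1:03d}" for i in range(n_patients)]
    sample_ids = {(p, tp): f"{p}-{'BL' if tp == 'baseline' else 'FU'}" for p in patients for tp in ("baseline", "followup")}
    manifest = SampleManifest(
        pd.DataFrame(
            [
                {"patient_id": p, "sample_id": sid, "timepoint": tp}
                for (p, tp), sid in sample_ids.items()
            ]
        )
    )

    frag_w = np.linspace(1.0, 0.4, n_fragments)
    frag_w /= frag_w.sum()
    rows, truth_rows = [], []
    for _, drow in design.iterrows():
        pep = drow["peptide_sequence"]
        spike = float(drow["spike_fmol_per_ul"])
        effect = float(effects.get(pep, 0.0))
        base_log2 = np.log2(spike) + rng.normal(0.0, between_patient_sd, size=n_patients)
        for i, patient in enumerate(patients):
            concs = {"baseline": 2.0 ** base_log2[i], "followup": 2.0 ** (base_log2[i] + effect)}
            truth_rows.append(
                {
                    "peptide_sequence": pep,
                    "patient_id": patient,
                    "conc_baseline": concs["baseline"],
                    "conc_followup": concs["followup"],
                }
            )
            for tp, conc in concs.items():
                for r in range(n_replicates):
                    ratio = (slope * conc + intercept) * _cv_noise(rng, cv, ())
                    heavy_total = 1e6 * _cv_noise(rng, 0.2, ())
                    heavy = heavy_total * frag_w
                    light = ratio * heavy * _cv_noise(rng, 0.02, n_fragments)
                    points = int(rng.integers(9, 15))
                    if rng.random() < p_low_points:
                        points = int(rng.integers(4, 8))
                    ppm = rng.normal(0.0, 3.0, size=n_fragments)
                    if rng.random() < p_high_ppm:
                        ppm[int(rng.integers(n_fragments))] = 12.0 + 5.0 * rng.random()
                    truncated = bool(rng.random() < p_truncated)
                    for f in range(n_fragments):
                        rows.append(
                            {
                                "peptide_sequence": pep,
                                "sample_id": sample_ids[(patient, tp)],
                                "replicate_id": f"rep{r + 1}",
                                "fragment_id": f"y{f + 3}",
                                "light_area": float(light[f]),
                                "heavy_area": float(heavy[f]),
                                "points_across_peak": points,
                                "mass_error_ppm": float(np.clip(ppm[f], -20, 20)),
                                "truncated": truncated,
                            }
                        )
    return manifest, pd.DataFrame(rows), pd.DataFrame(truth_rows)
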