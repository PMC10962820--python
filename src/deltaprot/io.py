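"""Readers and writers for every external table the pipeline touches.

All dialects are plain text: the protein quantification table follows the
MaxQuant ``proteinGroups.txt`` conventions (tab-separated, ``+`` flags,
``LFQ intensity <sample>`` columns, 0 = not quantified), the PRM results
follow a Skyline transition-results export (CSV), and everything else is
simple TSV.  Accession is the join key across all tables; gene names are
display-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SampleManifest",
    "ProteinQuantTable",
    "read_manifest",
    "write_manifest",
    "read_protein_table",
    "write_protein_table",
    "read_keyword_map",
    "write_keyword_map",
    "read_reference_diffset",
    "write_reference_diffset",
    "read_term_annotations",
    "write_term_annotations",
    "read_prm_export",
    "write_prm_export",
    "read_spike_design",
    "write_spike_design",
]


class FormatError(ValueError):
    """Structured parse/validation error for an input table."""


# --- MaxQuant-style protein table column names -------------------------------

ACCESSION_COL = "Majority protein IDs"
GENE_COL = "Gene names"
UNIQUE_PEPTIDES_COL = "Unique peptides"
FLAG_COLS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_identified_by_site": "Only identified by site",
}
LFQ_PREFIX = "LFQ intensity "

REFERENCE_DIRECTIONS = {
    "up": "increased",
    "increased": "increased",
    "down": "decreased",
    "decreased": "decreased",
    "unchanged": "unchanged",
}

PRM_COLUMNS = [
    "peptide_sequence",
    "sample_id",
    "replicate_id",
    "fragment_id",
    "light_area",
    "heavy_area",
    "points_across_peak",
    "mass_error_ppm",
    "truncated",
]


@dataclass
class SampleManifest:
    """Patient <-> (baseline, followup) sample mapping with optional covariates."""

    table: pd.DataFrame  # columns: patient_id, sample_id, timepoint [, covariates]

    def __post_init__(self) -> None:
        required = {"patient_id", "sample_id", "timepoint"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing required columns: {sorted(missing)}")
        bad = set(self.table["timepoint"]) - {"baseline", "followup"}
        if bad:
            raise FormatError(f"unknown timepoint values: {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"duplicate sample ids: {sorted(set(dups))}")
        counts = self.table.pivot_table(
            index="patient_id", columns="timepoint", values="sample_id", aggfunc="count"
        ).reindex(columns=["baseline", "followup"], fill_value=0).fillna(0)
        bad_patients = counts.index[(counts["baseline"] != 1) | (counts["followup"] != 1)]
        if len(bad_patients):
            raise FormatError(
                "each patient needs exactly one baseline and one followup sample; "
                f"offending patients: {sorted(bad_patients)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def patient_ids(self) -> list[str]:
        return sorted(set(self.table["patient_id"]))

    def pairs(self) -> pd.DataFrame:
        """One row per patient with ``baseline`` and ``followup`` sample ids."""
        wide = self.table.pivot(index="patient_id", columns="timepoint", values="sample_id")
        return wide[["baseline", "followup"]].sort_index()

    def __len__(self) -> int:
        return len(self.pairs())


@dataclass
class ProteinQuantTable:
    """Per-protein per-sample intensities plus identification flags.

    ``intensities`` is indexed by accession with one column per sample id;
    NaN encodes missing (a 0 in the file).  ``meta`` is indexed by accession
    and carries gene_name, unique_peptides and the three boolean flags.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame
    keywords: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.meta.index.duplicated().any():
            dups = self.meta.index[self.meta.index.duplicated()]
            raise FormatError(f"duplicate accessions: {sorted(set(dups))}")
        if not self.meta.index.equals(self.intensities.index):
            raise FormatError("meta and intensity tables disagree on accessions")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("negative intensity encountered")

    @property
    def accessions(self) -> list[str]:
        return list(self.meta.index)

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, accessions: Iterable[str]) -> "ProteinQuantTable":
        idx = [a for a in self.accessions if a in set(accessions)]
        return ProteinQuantTable(
            self.meta.loc[idx].copy(), self.intensities.loc[idx].copy(), self.keywords
        )


# --- manifest ----------------------------------------------------------------

def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


# --- protein quantification table --------------------------------------------

def read_protein_table(path: str | Path, manifest: SampleManifest) -> ProteinQuantTable:
    """Parse a MaxQuant-proteinGroups-dialect TSV against a sample manifest.

    Zero intensities are preserved as missing markers (NaN); unknown columns
    are ignored with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [ACCESSION_COL, GENE_COL, UNIQUE_PEPTIDES_COL, *FLAG_COLS.values()]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"protein table missing required column: {col!r}")

    expected_lfq = {LFQ_PREFIX + s for s in manifest.sample_ids}
    present_lfq = {c for c in df.columns if c.startswith(LFQ_PREFIX)}
    absent = expected_lfq - present_lfq
    if absent:
        missing_samples = sorted(c[len(LFQ_PREFIX):] for c in absent)
        raise FormatError(f"intensity columns missing for manifest samples: {missing_samples}")
    unknown = set(df.columns) - set(required) - present_lfq
    if unknown:
        logger.warning("ignoring unknown protein-table columns: %s", sorted(unknown))
    extra_lfq = present_lfq - expected_lfq
    if extra_lfq:
        logger.warning("ignoring intensity columns not in manifest: %s", sorted(extra_lfq))

    accession = df[ACCESSION_COL].astype(str)
    if accession.duplicated().any():
        dups = sorted(set(accession[accession.duplicated()]))
        raise FormatError(f"duplicate accessions: {dups}")

    meta = pd.DataFrame(
        {
            "gene_name": df[GENE_COL].fillna("").astype(str).to_numpy(),
            "unique_peptides": pd.to_numeric(df[UNIQUE_PEPTIDES_COL]).astype(int).to_numpy(),
        },
        index=pd.Index(accession, name="accession"),
    )
    for attr, col in FLAG_COLS.items():
        meta[attr] = (df[col].fillna("").str.strip() == "+").to_numpy()
    if (meta["unique_peptides"] < 0).any():
        raise FormatError("negative unique peptide count")

    cols = {}
    for sid in manifest.sample_ids:
        vals = pd.to_numeric(df[LFQ_PREFIX + sid]).astype(float).to_numpy()
        cols[sid] = np.where(vals == 0.0, np.nan, vals)
    return ProteinQuantTable(meta, pd.DataFrame(cols, index=meta.index))


def write_protein_table(table: ProteinQuantTable, path: str | Path) -> None:
    cols: dict[str, object] = {
        ACCESSION_COL: table.meta.index,
        GENE_COL: table.meta["gene_name"].to_numpy(),
        UNIQUE_PEPTIDES_COL: table.meta["unique_peptides"].to_numpy(),
    }
    for attr, col in FLAG_COLS.items():
        cols[col] = np.where(table.meta[attr].to_numpy(), "+", "")
    for sid in table.intensities.columns:
        cols[LFQ_PREFIX + sid] = np.nan_to_num(table.intensities[sid].to_numpy(), nan=0.0)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# --- keyword map --------------------------------------------------------------

def read_keyword_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Accession -> set of UniProt-style keywords (semicolon separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("accession", "keywords"):
        if col not in df.columns:
            raise FormatError(f"keyword map missing column: {col!r}")
    out: dict[str, frozenset[str]] = {}
    for acc, kws in zip(df["accession"], df["keywords"]):
        parts = frozenset(k.strip() for k in kws.split(";") if k.strip())
        out[str(acc)] = out.get(str(acc), frozenset()) | parts
    return out


def write_keyword_map(keyword_map: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"accession": acc, "keywords": ";".join(sorted(kws))}
        for acc, kws in sorted(keyword_map.items())
    ]
    pd.DataFrame(rows, columns=["accession", "keywords"]).to_csv(path, sep="\t", index=False)


# --- reference differential list ----------------------------------------------

def read_reference_diffset(path: str | Path) -> pd.DataFrame:
    """Disease-vs-control reference list: one direction per accession.

    Direction tokens up/down/unchanged (case-insensitive) are normalized to
    increased/decreased/unchanged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("accession", "direction"):
        if col not in df.columns:
            raise FormatError(f"reference list missing column: {col!r}")
    directions = []
    for i, token in enumerate(df["direction"]):
        key = str(token).strip().lower()
        if key not in REFERENCE_DIRECTIONS:
            raise FormatError(f"unknown direction token {token!r} at row {i + 2}")
        directions.append(REFERENCE_DIRECTIONS[key])
    out = pd.DataFrame({"accession": df["accession"].astype(str), "direction": directions})
    conflict = out.groupby("accession")["direction"].nunique()
    bad = sorted(conflict.index[conflict > 1])
    if bad:
        raise FormatError(f"conflicting directions for accessions: {bad}")
    return out.drop_duplicates().reset_index(drop=True)


def write_reference_diffset(ref: pd.DataFrame, path: str | Path) -> None:
    tokens = {"increased": "up", "decreased": "down", "unchanged": "unchanged"}
    out = pd.DataFrame(
        {"accession": ref["accession"], "direction": ref["direction"].map(tokens)}
    )
    out.to_csv(path, sep="\t", index=False)


# --- term annotations (GO biological process emulation) ------------------------

def read_term_annotations(path: str | Path) -> pd.DataFrame:
    """Flat term -> protein annotation table with per-pair evidence codes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["term_id", "term_name", "accession", "evidence_code"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"term annotation table missing column: {col!r}")
    return df[required].astype(str).drop_duplicates().reset_index(drop=True)


def write_term_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


# --- PRM transition results (Skyline-export dialect) ---------------------------

def read_prm_export(path: str | Path) -> pd.DataFrame:
    """Skyline-style transition results: one row per (peptide, sample, replicate, fragment)."""
    df = pd.read_csv(path, dtype=str)
    for col in PRM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"PRM export missing column: {col!r}")
    out = df[PRM_COLUMNS].copy()
    for col in ("light_area", "heavy_area", "mass_error_ppm"):
        out[col] = pd.to_numeric(out[col]).astype(float)
    if (out["light_area"] < 0).any() or (out["heavy_area"] < 0).any():
        raise FormatError("negative peak area encountered")
    pts = pd.to_numeric(out["points_across_peak"])
    if not np.allclose(pts, np.round(pts)):
        raise FormatError("points_across_peak must be an integer")
    out["points_across_peak"] = pts.astype(int)
    out["truncated"] = out["truncated"].str.strip().str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if out["truncated"].isna().any():
        raise FormatError("truncated flag must be True/False")
    key = ["peptide_sequence", "sample_id", "replicate_id", "fragment_id"]
    if out.duplicated(subset=key).any():
        raise FormatError("duplicate (peptide, sample, replicate, fragment) rows")
    return out.reset_index(drop=True)


def write_prm_export(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False)


# --- heavy-spike design --------------------------------------------------------

def read_spike_design(path: str | Path) -> pd.DataFrame:
    """Per-peptide heavy spike level (fmol/ul injected at nominal 1:1) and dilution series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("peptide_sequence", "spike_fmol_per_ul", "dilution_factors"):
        if col not in df.columns:
            raise FormatError(f"spike design missing column: {col!r}")
    out = pd.DataFrame(
        {
            "peptide_sequence": df["peptide_sequence"].astype(str),
            "spike_fmol_per_ul": pd.to_numeric(df["spike_fmol_per_ul"]).astype(float),
            "dilution_factors": [
                tuple(float(x) for x in s.split(",")) for s in df["dilution_factors"]
            ],
        }
    )
    if (out["spike_fmol_per_ul"] <= 0).any():
        raise FormatError("spike amounts must be positive")
    for pep, dils in zip(out["peptide_sequence"], out["dilution_factors"]):
        arr = np.asarray(dils)
        if (arr <= 0).any():
            raise FormatError(f"non-positive dilution factor for peptide {pep}")
        if not (np.diff(arr) < 0).all():
            raise FormatError(f"dilution factors must be strictly decreasing for peptide {pep}")
    return out


def write_spike_design(design: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "peptide_sequence": design["peptide_sequence"],
            "spike_fmol_per_ul": design["spike_fmol_per_ul"],
            "dilution_factors": [
                ",".join(format(x, "g") for x in d) for d in design["dilution_factors"]
            ],
        }
    )
    out.to_csv(path, sep="\t", index=False)
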