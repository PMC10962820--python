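"""Label-free discovery analysis: filtering, paired fold changes, paired
t-tests with BH correction, immunoglobulin handling, z-score fold-change
cutoff and verification-candidate selection.

Fold-change direction is fixed as follow-up minus baseline, so proteins
decreased by treatment carry negative log2 fold changes.  Missing pairs are
dropped per protein (pairwise-complete); nothing is imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ProteinQuantTable, SampleManifest

__all__ = [
    "FilterReport",
    "filter_proteins",
    "paired_fold_changes",
    "summarize_fc",
    "paired_test",
    "paired_t_from_diffs",
    "bh_adjust",
    "flag_immunoglobulins",
    "zscore_fc_flag",
    "select_candidates",
    "run_discovery",
    "peptide_prescreen",
    "bootstrap_median_ci",
]

IG_KEYWORDS = frozenset({"KW-1280", "Immunoglobulin"})


@dataclass
class FilterReport:
    n_input: int
    n_reverse: int
    n_contaminant: int
    n_only_identified_by_site: int
    n_after_flag_filter: int
    n_after_min_pairs: int
    min_pairs: int

    def as_dict(self) -> dict:
        return asdict(self)


def _pair_matrices(
    table: ProteinQuantTable, manifest: SampleManifest
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(proteins x patients) baseline and follow-up intensity matrices."""
    pairs = manifest.pairs()
    base = table.intensities[list(pairs["baseline"])].to_numpy(dtype=float)
    follow = table.intensities[list(pairs["followup"])].to_numpy(dtype=float)
    return base, follow, list(pairs.index)


def complete_pair_counts(table: ProteinQuantTable, manifest: SampleManifest) -> pd.Series:
    """Number of patients with both baseline and follow-up values, per protein."""
    base, follow, _ = _pair_matrices(table, manifest)
    n = (~np.isnan(base) & ~np.isnan(follow)).sum(axis=1)
    return pd.Series(n, index=table.meta.index, name="n_pairs")


def filter_proteins(
    table: ProteinQuantTable, manifest: SampleManifest, min_pairs: int = 2
) -> tuple[ProteinQuantTable, FilterReport]:
    """Drop flagged proteins (decoy, contaminant, only-identified-by-site),
    then proteins quantified in fewer than ``min_pairs`` complete pairs."""
    meta = table.meta
    flagged = meta["reverse"] | meta["contaminant"] | meta["only_identified_by_site"]
    kept = table.subset(meta.index[~flagged])
    n_pairs = complete_pair_counts(kept, manifest)
    final = kept.subset(n_pairs.index[n_pairs >= min_pairs])
    report = FilterReport(
        n_input=len(table),
        n_reverse=int(meta["reverse"].sum()),
        n_contaminant=int(meta["contaminant"].sum()),
        n_only_identified_by_site=int(meta["only_identified_by_site"].sum()),
        n_after_flag_filter=len(kept),
        n_after_min_pairs=len(final),
        min_pairs=min_pairs,
    )
    return final, report


def paired_fold_changes(
    table: ProteinQuantTable, manifest: SampleManifest
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-patient log2 fold changes (follow-up − baseline) per protein.

    A fold change exists only where both intensities are present; the
    fraction of patients missing at least one value of the pair is returned
    as ``pct_blanks`` (in percent).
    """
    base, follow, patients = _pair_matrices(table, manifest)
    for arr, name in ((base, "baseline"), (follow, "followup")):
        bad = ~np.isnan(arr) & (arr <= 0)
        if bad.any():
            raise ValueError(f"nonpositive {name} intensity present (not encoded as missing)")
    fc = np.log2(follow) - np.log2(base)
    fc_df = pd.DataFrame(fc, index=table.meta.index, columns=patients)
    pct_blanks = pd.Series(
        100.0 * np.isnan(fc).mean(axis=1), index=table.meta.index, name="pct_blanks"
    )
    return fc_df, pct_blanks


def summarize_fc(fc: pd.DataFrame) -> pd.DataFrame:
    """Median log2 fold change, concordance percentage and pair count.

    ``pct_changed`` is the percentage of available fold changes whose sign
    matches the median's sign (zero fold changes count toward neither sign);
    when the median is exactly zero, the larger sign fraction is reported.
    """
    vals = fc.to_numpy(dtype=float)
    n_avail = (~np.isnan(vals)).sum(axis=1)
    if (n_avail == 0).any():
        raise ValueError("protein with no available fold changes")
    med = np.nanmedian(vals, axis=1)
    n_pos = np.nansum(vals > 0, axis=1)
    n_neg = np.nansum(vals < 0, axis=1)
    matching = np.where(med > 0, n_pos, np.where(med < 0, n_neg, np.maximum(n_pos, n_neg)))
    return pd.DataFrame(
        {
            "median_log2_fc": med,
            "pct_changed": 100.0 * matching / n_avail,
            "n_pairs": n_avail,
        },
        index=fc.index,
    )


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaN p-values are excluded from m."""
    mask = p.notna()
    out = pd.Series(np.nan, index=p.index, name="fdr")
    if mask.sum():
        out.loc[mask] = multipletests(p[mask].to_numpy(), method="fdr_bh")[1]
    return out


def paired_t_from_diffs(d: np.ndarray, min_pairs: int = 2) -> pd.DataFrame:
    """Row-wise one-sample t statistics on paired differences (NaN-aware).

    Rows with fewer than ``min_pairs`` non-missing differences, or with zero
    variance, get an undefined p-value (flagged via ``zero_variance``).
    """
    d = np.asarray(d, dtype=float)
    n = (~np.isnan(d)).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_d = np.nanmean(d, axis=1)
        sd_d = np.nanstd(d, axis=1, ddof=1)
    sd_d = np.where(n >= 2, sd_d, np.nan)
    testable = (n >= max(min_pairs, 2)) & (sd_d > 0)
    t_stat = np.full(len(d), np.nan)
    p_val = np.full(len(d), np.nan)
    idx = np.flatnonzero(testable)
    if idx.size:
        t_stat[idx] = mean_d[idx] / (sd_d[idx] / np.sqrt(n[idx]))
        p_val[idx] = 2.0 * stats.t.sf(np.abs(t_stat[idx]), df=n[idx] - 1)
    return pd.DataFrame(
        {
            "n_pairs": n.astype(int),
            "t_stat": t_stat,
            "p_value": p_val,
            "zero_variance": (n >= 2) & (sd_d == 0),
        }
    )


def paired_test(
    table: ProteinQuantTable, manifest: SampleManifest, min_pairs: int = 2
) -> pd.DataFrame:
    """Two-sided paired t-test on log2 intensities over complete pairs,
    followed by BH adjustment across the testable proteins.

    Proteins with fewer than ``min_pairs`` complete pairs or zero variance
    of the differences get an undefined p-value (flagged, excluded from the
    BH denominator).
    """
    base, follow, _ = _pair_matrices(table, manifest)
    d = np.log2(follow) - np.log2(base)
    res = paired_t_from_diffs(d, min_pairs=min_pairs)
    res.index = table.meta.index
    res["fdr"] = bh_adjust(res["p_value"])
    return res


def flag_immunoglobulins(
    accessions: Iterable[str],
    keyword_map: Mapping[str, frozenset[str]],
    keywords: Iterable[str] = IG_KEYWORDS,
) -> pd.Series:
    """True iff the protein's keyword set contains the immunoglobulin
    keyword (UniProt KW-1280) by id or name."""
    targets = set(keywords)
    idx = pd.Index(accessions, name="accession")
    flags = [bool(targets & set(keyword_map.get(acc, ()))) for acc in idx]
    return pd.Series(flags, index=idx, name="is_immunoglobulin")


def zscore_fc_flag(
    median_fc: pd.Series, is_immunoglobulin: pd.Series, alpha_z: float = 0.05
) -> pd.DataFrame:
    """Fold-change cutoff via z-scores of the median log2 fold change.

    The reference mean and standard deviation are estimated over
    non-immunoglobulin proteins only (the Ig class distorts the fold-change
    distribution); immunoglobulins still receive a z relative to that
    reference. ``high_fc`` flags two-sided normal tail probability < alpha_z.
    """
    ref = median_fc[~is_immunoglobulin.reindex(median_fc.index).fillna(False)]
    if len(ref) < 3:
        raise ValueError("need at least 3 non-immunoglobulin proteins to estimate the reference")
    sd = float(ref.std(ddof=1))
    if sd == 0:
        raise ValueError("zero spread of non-immunoglobulin median fold changes")
    z = (median_fc - float(ref.mean())) / sd
    z_p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"z_score": z, "z_p": z_p, "high_fc": z_p < alpha_z}, index=median_fc.index
    )


def select_candidates(
    records: pd.DataFrame,
    discovery_fdr: float = 0.01,
    z_alpha: float = 0.05,
    concordance_pct: float = 80.0,
    force_include: Sequence[str] = (),
) -> pd.Series:
    """Verification candidates: FDR < alpha1, z-score tail < alpha2 and
    concordance strictly above the cutoff; configured proteins of special
    interest are force-included."""
    cand = (
        (records["fdr"] < discovery_fdr)
        & (records["z_p"] < z_alpha)
        & (records["pct_changed"] > concordance_pct)
    )
    cand = cand.fillna(False)
    forced = records.index.isin(set(force_include))
    return pd.Series(cand.to_numpy() | forced, index=records.index, name="candidate")


def run_discovery(
    table: ProteinQuantTable,
    manifest: SampleManifest,
    keyword_map: Mapping[str, frozenset[str]],
    discovery_fdr: float = 0.01,
    z_alpha: float = 0.05,
    concordance_pct: float = 80.0,
    min_pairs: int = 2,
    force_include: Sequence[str] = (),
    ig_keywords: Iterable[str] = IG_KEYWORDS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Full discovery pass: filter, per-patient fold changes, summaries,
    paired tests with BH, Ig flags, z-score cutoff, candidate selection.

    Returns one differential record per retained protein.
    """
    filtered, report = filter_proteins(table, manifest, min_pairs=min_pairs)
    fc, pct_blanks = paired_fold_changes(filtered, manifest)
    summary = summarize_fc(fc)
    tests = paired_test(filtered, manifest, min_pairs=min_pairs)
    records = summary.join(tests.drop(columns="n_pairs")).join(pct_blanks)
    records["is_immunoglobulin"] = flag_immunoglobulins(
        records.index, keyword_map, keywords=ig_keywords
    )
    zres = zscore_fc_flag(records["median_log2_fc"], records["is_immunoglobulin"], alpha_z=z_alpha)
    records = records.join(zres)
    records["significant"] = (records["fdr"] < discovery_fdr).fillna(False)
    records["candidate"] = select_candidates(
        records,
        discovery_fdr=discovery_fdr,
        z_alpha=z_alpha,
        concordance_pct=concordance_pct,
        force_include=force_include,
    )
    records["neg_log10_p"] = -np.log10(records["p_value"])
    return records, report


# --- peptide-level prescreen for PRM assay design --------------------------------

def peptide_prescreen(
    peptides: pd.DataFrame,
    manifest: SampleManifest,
    p_threshold: float = 0.05,
    allow_list: Sequence[str] = (),
) -> pd.DataFrame:
    """Rank discovery peptides as PRM candidates.

    Intensities are log2-transformed and median-centered per sample, then a
    paired t-test is applied per peptide.  Peptides containing cysteine or
    methionine, or flagged as modified, are excluded (synthesis/stability
    rule) unless explicitly allow-listed.  Ranking: median intensity
    (descending) then p-value.

    ``peptides`` needs columns ``sequence``, ``accession``, optionally
    ``modified`` (boolean), plus one intensity column per manifest sample.
    """
    sample_cols = [s for s in manifest.sample_ids if s in peptides.columns]
    missing = set(manifest.sample_ids) - set(sample_cols)
    if missing:
        raise ValueError(f"peptide table missing sample columns: {sorted(missing)}")
    mat = peptides[sample_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log = np.where(mat > 0, np.log2(mat), np.nan)
    log = log - np.nanmedian(log, axis=0, keepdims=True)  # per-sample median centering

    pairs = manifest.pairs()
    b_idx = [sample_cols.index(s) for s in pairs["baseline"]]
    f_idx = [sample_cols.index(s) for s in pairs["followup"]]
    d = log[:, f_idx] - log[:, b_idx]
    n = (~np.isnan(d)).sum(axis=1).astype(float)
    p = np.full(len(d), np.nan)
    for i, row in enumerate(d):
        vals = row[~np.isnan(row)]
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            p[i] = stats.ttest_1samp(vals, 0.0).pvalue

    seq = peptides["sequence"].astype(str)
    allow = set(allow_list)
    has_cm = seq.str.contains("C") | seq.str.contains("M")
    modified = peptides["modified"].astype(bool) if "modified" in peptides.columns else pd.Series(False, index=peptides.index)
    eligible = (~has_cm | seq.isin(allow)) & ~modified & (p < p_threshold)

    out = pd.DataFrame(
        {
            "sequence": seq,
            "accession": peptides["accession"].astype(str),
            "median_log2_intensity": np.nanmedian(log, axis=1),
            "n_pairs": n.astype(int),
            "p_value": p,
            "contains_cys_or_met": has_cm.to_numpy(),
            "eligible": eligible.fillna(False).to_numpy(),
        }
    )
    return out.sort_values(
        by=["eligible", "median_log2_intensity", "p_value"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 10_000, ci: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the median (non-canonical CI choice,
    provided for verification-result reporting)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least 2 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(vals, size=(n_boot, len(vals)), replace=True), axis=1)
    lo, hi = np.quantile(meds, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return float(lo), float(hi)
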