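"""Cross-study concordance: joint classification of each protein's direction
under treatment versus its direction in disease-vs-control reference data.

Categories (mutually exclusive, exhaustive):

======================  ==============================================
opposite                treatment and reference changed, opposite signs
equal                   treatment and reference changed, same sign
treatment_only          changed under treatment, unchanged in reference
disease_only            unchanged under treatment, changed in reference
not_changed             unchanged in both
unmatched               protein absent from the reference list
======================  ==============================================

"Changed under treatment" means FDR below the discovery threshold with a
nonzero median log2 fold change; direction is the fold-change sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CATEGORIES

__all__ = ["treatment_states", "categorize", "CATEGORIES"]


def treatment_states(records: pd.DataFrame, discovery_fdr: float = 0.01) -> pd.Series:
    """increased / decreased / unchanged per protein from the discovery result.

    Degenerate zero-noise limit: a protein whose paired differences were all
    identical and nonzero has an undefined t-test p-value but is changed with
    certainty, and is classed by its fold-change sign.
    """
    fdr = records["fdr"]
    fc = records["median_log2_fc"]
    sig = (fdr < discovery_fdr).fillna(False)
    if "zero_variance" in records.columns:
        sig = sig | (records["zero_variance"].fillna(False) & (fc != 0))
    state = np.where(
        sig & (fc > 0), "increased", np.where(sig & (fc < 0), "decreased", "unchanged")
    )
    return pd.Series(state, index=records.index, name="treatment_state")


def categorize(
    records: pd.DataFrame,
    reference: pd.DataFrame,
    discovery_fdr: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Assign every discovery protein one concordance category.

    Returns (assignments, summary).  ``summary`` carries per-category counts,
    a 3x4 treatment-state x reference-state contingency table, and the
    reference accessions that were never quantified in the treatment study.
    """
    treat = treatment_states(records, discovery_fdr=discovery_fdr)
    ref = reference.set_index("accession")["direction"]
    if ref.index.duplicated().any():
        raise ValueError("reference list has duplicate accessions")
    ref_state = ref.reindex(treat.index).fillna("absent").rename("reference_state")

    def classify(t: str, r: str) -> str:
        if r == "absent":
            return "unmatched"
        t_changed = t != "unchanged"
        r_changed = r != "unchanged"
        if t_changed and r_changed:
            return "equal" if t == r else "opposite"
        if t_changed:
            return "treatment_only"
        if r_changed:
            return "disease_only"
        return "not_changed"

    category = pd.Series(
        [classify(t, r) for t, r in zip(treat, ref_state)], index=treat.index, name="category"
    )
    assignments = pd.DataFrame(
        {"treatment_state": treat, "reference_state": ref_state, "category": category}
    )
    contingency = (
        assignments.groupby(["treatment_state", "reference_state"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(
            index=["increased", "decreased", "unchanged"],
            columns=["increased", "decreased", "unchanged", "absent"],
            fill_value=0,
        )
    )
    summary = {
        "category_counts": {c: int((category == c).sum()) for c in CATEGORIES},
        "contingency": {t: {r: int(v) for r, v in row.items()} for t, row in contingency.iterrows()},
        "reference_only_unquantified": sorted(set(ref.index) - set(treat.index)),
    }
    return assignments, summary
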