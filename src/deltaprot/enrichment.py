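"""Hypergeometric over-representation of flat term annotations within a
protein subset against the quantified background, with BH correction.

No ontology-graph propagation is performed: annotations are taken as given
flat term -> protein sets (the quantified background restricts them before
testing), and annotations with excluded evidence codes (IEA by default) are
removed before counting.
"""

from __future__ import annotations

from typing import Collection, Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .discovery import bh_adjust

__all__ = ["enrich"]


def enrich(
    subset: Iterable[str],
    background: Iterable[str],
    annotations: pd.DataFrame,
    exclude_evidence: Collection[str] = ("IEA",),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test per term: P[X >= k] for
    X ~ Hypergeometric(N, K, n) with N the background size, K the term's
    background annotation count, n the subset size and k the subset hits.

    Terms with no background annotation are skipped (and excluded from the
    BH denominator). Results are sorted by FDR then p.
    """
    bg = set(background)
    sub = set(subset)
    offenders = sorted(sub - bg)
    if offenders:
        raise ValueError(f"subset proteins missing from background: {offenders}")

    ann = annotations[~annotations["evidence_code"].isin(set(exclude_evidence))]
    ann = ann[ann["accession"].isin(bg)].drop_duplicates(subset=["term_id", "accession"])

    N, n = len(bg), len(sub)
    rows = []
    for (term_id, term_name), grp in ann.groupby(["term_id", "term_name"], sort=True):
        members = set(grp["accession"])
        K = len(members)
        k = len(members & sub)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term_id, "term_name": term_name, "k": k, "K": K, "n": n, "N": N,
             "p_value": min(p, 1.0)}
        )
    res = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    res["fdr"] = bh_adjust(res["p_value"]) if len(res) else pd.Series(dtype=float)
    res["significant"] = res["fdr"] < alpha
    return res.sort_values(["fdr", "p_value", "term_id"], kind="mergesort").reset_index(drop=True)
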