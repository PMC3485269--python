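"""Hypergeometric GO-term over-representation.

For a study set of n genes drawn from a background of N annotated genes,
a term carried by K background genes and k study genes is scored by the
upper-tail probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

i.e. the chance of seeing at least the observed overlap under random
sampling without replacement.  Raw p-values are reported, the form that
semantic-similarity viewers ingest; Benjamini-Hochberg adjustment is
optional.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .differential import bh_fdr


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study genes carrying the term
    K: int  # background genes carrying the term
    n: int  # study-set size
    N: int  # background size
    p: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), including the observed k."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def go_enrichment(
    gene_set,
    go_map: pd.DataFrame,
    background=None,
    bh: bool = False,
) -> pd.DataFrame:
    """Term-by-term over-representation of ``gene_set``.

    ``go_map`` maps gene_id -> term_id (+ optional term_name); the
    background defaults to every gene in the map.  Only terms present in
    the study set are reported, sorted by p.  With ``bh=True`` a q column
    of Benjamini-Hochberg adjusted values is appended.
    """
    background = set(background) if background is not None else set(go_map["gene_id"])
    study = set(gene_set) & background
    if len(set(gene_set)) > 0 and len(study) == 0:
        raise ValueError("gene_set does not intersect the background")
    n, N = len(study), len(background)
    rows = []
    gm = go_map[go_map["gene_id"].isin(background)]
    names = gm.drop_duplicates("term_id").set_index("term_id")["term_name"]
    for term_id, sub in gm.groupby("term_id"):
        carriers = set(sub["gene_id"])
        k = len(carriers & study)
        if k == 0:
            continue
        K = len(carriers)
        rows.append(
            {
                "term_id": term_id,
                "term_name": names.get(term_id, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_tail(k, K, n, N),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"]
    ).sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    if bh and len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out
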