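"""Genomic annotation of small-RNA clusters.

Each cluster is assigned one category — TE, gene, near-TE (within 500 bp),
near-gene (within 500 bp) or intergenic — from the abundance-weighted
fraction of its member reads overlapping transposable elements and
protein-coding genes (weights are the same 1/N multimapping weights used
for quantification; "majority" means strictly more than half).  Genic
clusters are additionally flagged when a TE lies within 1 kb of the
associated gene, the feature association the inheritance analysis turns on.
Intersections are strand-agnostic throughout: heterochromatic 24-nt siRNA
clusters span both strands.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .clustering import assign_reads
from .types import GenomeAnnotation, validate_design, validate_reads

logger = logging.getLogger(__name__)

DEFAULT_NEAR_WINDOW = 500
DEFAULT_TE_WINDOW = 1000

CATEGORIES = ("TE", "gene", "near_TE_500", "near_gene_500", "intergenic")

#: Small (20-22 nt) vs large (23-24 nt) read size classes.
SMALL_LENGTHS = (20, 21, 22)
LARGE_LENGTHS = (23, 24)

#: Feature kinds partitioning the genome for RPKM, highest precedence first.
RPKM_PRECEDENCE = (
    "transposable_element",
    "CDS",
    "five_prime_UTR",
    "three_prime_UTR",
    "intron",
    "intergenic",
)


def feature_trees(annotation: GenomeAnnotation, kinds=None) -> dict[str, dict[str, IntervalTree]]:
    """Per-kind, per-chromosome interval trees over the annotation."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for f in annotation.features:
        if kinds is not None and f.kind not in kinds:
            continue
        trees.setdefault(f.kind, {}).setdefault(f.chrom, IntervalTree())[f.start:f.end] = f
    return trees


def _gap_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two half-open intervals; 0 when they touch or overlap."""
    return max(a_start - b_end, b_start - a_end, 0)


def nearest_feature(
    trees_for_kind: dict[str, IntervalTree], chrom: str, start: int, end: int, window: int
):
    """Closest feature of one kind within ``window`` bp, or None.

    Returns ``(feature, gap_distance)``; ties broken by leftmost feature.
    """
    tree = trees_for_kind.get(chrom)
    if tree is None:
        return None
    best = None
    for iv in tree.overlap(start - window, end + window):
        dist = _gap_distance(start, end, iv.begin, iv.end)
        if dist > window:
            continue
        key = (dist, iv.begin, iv.data.feature_id)
        if best is None or key < best[0]:
            best = (key, iv.data, dist)
    if best is None:
        return None
    return best[1], best[2]


def size_class_profile(member_reads: pd.DataFrame) -> tuple[str, pd.Series]:
    """Dominant size class of a cluster plus its per-length abundance histogram.

    Distinct loci of a multimapping sequence each carry weight abundance/N.
    Dominance compares the summed weight on 20-22 nt vs 23-24 nt reads;
    a tie (including no reads in either class) is "other".
    """
    w = member_reads["abundance"] / member_reads["n_loci"]
    hist = w.groupby(member_reads["length"]).sum().sort_index()
    small = float(hist.reindex(SMALL_LENGTHS, fill_value=0.0).sum())
    large = float(hist.reindex(LARGE_LENGTHS, fill_value=0.0).sum())
    if small > large:
        dominant = "small"
    elif large > small:
        dominant = "large"
    else:
        dominant = "other"
    return dominant, hist


def te_within_1kb(
    gene, annotation: GenomeAnnotation, window: int = DEFAULT_TE_WINDOW, trees=None
) -> bool:
    """True iff any TE lies within ``window`` bp of the gene's interval.

    Distance is measured from the gene interval itself (not the cluster);
    an overlapping TE counts.
    """
    if trees is None:
        trees = feature_trees(annotation, kinds=("transposable_element",))
    tree = trees.get("transposable_element", {}).get(gene.chrom)
    if tree is None:
        return False
    for iv in tree.overlap(gene.start - window, gene.end + window):
        if _gap_distance(gene.start, gene.end, iv.begin, iv.end) <= window:
            return True
    return False


def assign_category(
    cluster, member_reads: pd.DataFrame, annotation: GenomeAnnotation,
    near_window: int = DEFAULT_NEAR_WINDOW, te_window: int = DEFAULT_TE_WINDOW,
    trees=None,
) -> dict:
    """Categorise one cluster and assemble its annotation record.

    ``cluster`` needs ``chrom/start/end`` attributes; ``member_reads`` holds
    the cluster's read loci pooled over libraries.  Reads overlapping both a
    TE and a gene count for the TE (TE precedence).
    """
    if trees is None:
        trees = feature_trees(annotation, kinds=("transposable_element", "gene"))
    te_tree = trees.get("transposable_element", {}).get(cluster.chrom, IntervalTree())
    gene_tree = trees.get("gene", {}).get(cluster.chrom, IntervalTree())

    w = (member_reads["abundance"] / member_reads["n_loci"]).to_numpy(float)
    total = w.sum()
    te_w = gene_w = 0.0
    for weight, (start, end) in zip(w, member_reads[["start", "end"]].itertuples(index=False)):
        if te_tree.overlap(start, end):
            te_w += weight
        elif gene_tree.overlap(start, end):
            gene_w += weight
    te_frac = te_w / total if total > 0 else 0.0
    gene_frac = gene_w / total if total > 0 else 0.0

    category = None
    majority = float("nan")
    nearest_id, nearest_dist = "", np.nan
    gene_feature = None
    if te_frac > 0.5:
        category, majority = "TE", te_frac
    elif gene_frac > 0.5:
        category, majority = "gene", gene_frac
        hits = [iv.data for iv in gene_tree.overlap(cluster.start, cluster.end)]
        if hits:
            gene_feature = min(hits, key=lambda g: (g.start, g.feature_id))
    else:
        near_te = nearest_feature(
            trees.get("transposable_element", {}), cluster.chrom, cluster.start, cluster.end, near_window
        )
        near_gene = nearest_feature(
            trees.get("gene", {}), cluster.chrom, cluster.start, cluster.end, near_window
        )
        # closest feature wins; exact ties go to the TE
        if near_te is not None and (near_gene is None or near_te[1] <= near_gene[1]):
            category = "near_TE_500"
            nearest_id, nearest_dist = near_te[0].feature_id, near_te[1]
        elif near_gene is not None:
            category = "near_gene_500"
            nearest_id, nearest_dist = near_gene[0].feature_id, near_gene[1]
            gene_feature = near_gene[0]
        else:
            category = "intergenic"

    if category == "gene" and gene_feature is not None:
        nearest_id, nearest_dist = gene_feature.feature_id, 0

    te_flag: bool | None = None
    if category in ("gene", "near_gene_500") and gene_feature is not None:
        te_flag = te_within_1kb(gene_feature, annotation, window=te_window, trees=trees)

    dominant, _hist = size_class_profile(member_reads)
    return {
        "category": category,
        "majority_fraction": majority,
        "nearest_feature_id": nearest_id,
        "nearest_distance": nearest_dist,
        "te_within_1kb": te_flag,
        "dominant_size_class": dominant,
    }


def annotate_clusters(
    clusters: pd.DataFrame, reads: pd.DataFrame, annotation: GenomeAnnotation,
    near_window: int = DEFAULT_NEAR_WINDOW, te_window: int = DEFAULT_TE_WINDOW,
) -> pd.DataFrame:
    """Annotation calls for every cluster, indexed by cluster_id."""
    validate_reads(reads)
    trees = feature_trees(annotation, kinds=("transposable_element", "gene"))
    loci = reads.drop_duplicates(subset=["seq_id", "chrom", "start", "strand", "library_id"])
    # pool each distinct locus's abundance over libraries
    pooled = (
        loci.groupby(["seq_id", "chrom", "start", "end", "length", "n_loci"], as_index=False)[
            "abundance"
        ].sum()
    )
    pooled["library_id"] = "pooled"
    pooled["strand"] = "+"
    pooled["_cluster"] = assign_reads(clusters, pooled)
    rows = []
    for cluster in clusters.itertuples():
        members = pooled[pooled["_cluster"] == cluster.cluster_id]
        rec = assign_category(
            cluster, members, annotation, near_window=near_window, te_window=te_window, trees=trees
        )
        rec["cluster_id"] = cluster.cluster_id
        rows.append(rec)
    return pd.DataFrame(rows).set_index("cluster_id")


# ---------------------------------------------------------------------------
# Per-feature-kind RPKM
# ---------------------------------------------------------------------------

def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total, prev_end = 0, None
    for start, end in sorted(intervals):
        if prev_end is None or start >= prev_end:
            total += end - start
            prev_end = end
        elif end > prev_end:
            total += end - prev_end
            prev_end = end
    return total


def feature_rpkm(
    reads: pd.DataFrame, annotation: GenomeAnnotation, design: pd.DataFrame
) -> pd.DataFrame:
    """Weighted RPKM per feature kind and library.

    Reads are assigned to the highest-precedence kind they overlap
    (TE > CDS > UTR > intron > intergenic); RPKM divides the weighted
    abundance by the library's total mapped reads and the kind's merged
    genomic length:  rpkm = weight * 1e9 / (total_mapped * length_bp).
    """
    validate_reads(reads)
    validate_design(design)
    kinds = [k for k in RPKM_PRECEDENCE if k != "intergenic"]
    trees = feature_trees(annotation, kinds=kinds)
    lengths = {
        kind: _merged_length(
            [(f.start, f.end) for f in annotation.features if f.kind == kind]
        )
        for kind in kinds
    }
    genome_bp = sum(annotation.chromosomes.values())
    covered = _merged_length(
        [(f.start, f.end) for f in annotation.features if f.kind in kinds]
    )
    lengths["intergenic"] = genome_bp - covered

    def kind_of(chrom: str, start: int, end: int) -> str:
        for kind in kinds:
            tree = trees.get(kind, {}).get(chrom)
            if tree is not None and tree.overlap(start, end):
                return kind
        return "intergenic"

    work = reads.copy()
    keys = work[["chrom", "start", "end"]].drop_duplicates()
    keys["_kind"] = [kind_of(r.chrom, r.start, r.end) for r in keys.itertuples()]
    work = work.merge(keys, on=["chrom", "start", "end"], how="left")
    work["_w"] = work["abundance"] / work["n_loci"]
    weight = work.pivot_table(
        index="_kind", columns="library_id", values="_w", aggfunc="sum", fill_value=0.0
    )
    totals = design.set_index("library_id")["total_mapped_reads"].astype(float)
    rows = []
    for kind in RPKM_PRECEDENCE:
        if lengths.get(kind, 0) <= 0:
            warnings.warn(f"feature kind {kind!r} has zero total length; skipped", stacklevel=2)
            continue
        w = weight.loc[kind] if kind in weight.index else pd.Series(0.0, index=weight.columns)
        for lib in w.index:
            rows.append(
                {
                    "feature_kind": kind,
                    "library_id": lib,
                    "total_length_bp": lengths[kind],
                    "rpkm": float(w[lib]) * 1e9 / (totals[lib] * lengths[kind]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pattern-by-annotation association
# ---------------------------------------------------------------------------

def pattern_association(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    focal_category: str | tuple[str, ...],
    focal_patterns: str | tuple[str, ...],
) -> tuple[float, float]:
    """Association between a cluster category and an inheritance pattern set.

    Builds the 2x2 table of category membership vs pattern membership over
    the DE clusters and returns ``(hypergeometric upper-tail p, Pearson
    chi-squared p without continuity correction)`` — both, side by side.
    """
    if isinstance(focal_category, str):
        focal_category = (focal_category,)
    if isinstance(focal_patterns, str):
        focal_patterns = (focal_patterns,)
    de = calls[calls["is_de"] & (calls["pattern"] != "")]
    joined = de.join(annotations[["category"]], how="inner")
    n_total = len(joined)
    in_cat = joined["category"].isin(focal_category)
    in_pat = joined["pattern"].isin(focal_patterns)
    k = int((in_cat & in_pat).sum())
    big_k = int(in_pat.sum())
    n = int(in_cat.sum())
    if n_total == 0 or n == 0 or big_k == 0:
        warnings.warn("pattern_association: empty margin, p = 1", stacklevel=2)
        return 1.0, 1.0
    p_hyper = float(stats.hypergeom.sf(k - 1, n_total, big_k, n))
    table = np.array(
        [
            [k, n - k],
            [big_k - k, n_total - n - (big_k - k)],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("pattern_association: empty margin, chi-squared p = 1", stacklevel=2)
        return p_hyper, 1.0
    p_chi2 = float(stats.chi2_contingency(table, correction=False)[1])
    return p_hyper, p_chi2
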