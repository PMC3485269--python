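"""Proximity clustering of mapped small RNAs and cluster-level quantification.

Reads from all libraries are pooled to define the clusters: a single sweep
per chromosome opens a new cluster whenever the next read start is at least
``gap`` bp beyond the previous read start ("less than 500 bp apart" joins,
exactly 500 splits).  Quantification then proceeds per library with 1/N
multimapping weights, reads-per-million normalisation against the library's
total mapped reads, arithmetic averaging of technical replicates, and a
keep-if-any-sample >= 5 RPM expression filter.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import ClusterCountMatrix, bio_sample_id, validate_design, validate_reads

logger = logging.getLogger(__name__)

DEFAULT_GAP = 500
DEFAULT_MIN_RPM = 5.0

CLUSTER_COLUMNS = ["cluster_id", "chrom", "start", "end", "n_loci_members"]


def build_clusters(reads: pd.DataFrame, gap: int = DEFAULT_GAP) -> pd.DataFrame:
    """Partition pooled read loci into proximity clusters.

    ``reads`` should contain the union of loci over all libraries (duplicate
    loci across libraries are fine; they collapse to one position).  A
    cluster joins consecutive loci whose start positions differ by less than
    ``gap``; its interval runs from the first member start to the last
    member end.

    Returns a frame with ``cluster_id, chrom, start, end, n_loci_members``
    sorted by genomic position.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    if len(reads) == 0:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    loci = (
        reads[["chrom", "start", "end"]]
        .drop_duplicates()
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )
    new_chrom = loci["chrom"].ne(loci["chrom"].shift())
    start_jump = loci["start"].diff() >= gap  # exactly `gap` apart splits
    boundary = (new_chrom | start_jump).to_numpy()
    boundary[0] = True
    cluster_idx = np.cumsum(boundary) - 1
    loci["_cluster"] = cluster_idx
    grouped = loci.groupby("_cluster", sort=True)
    clusters = pd.DataFrame(
        {
            "chrom": grouped["chrom"].first(),
            "start": grouped["start"].min(),
            "end": grouped["end"].max(),
            "n_loci_members": grouped.size(),
        }
    ).reset_index(drop=True)
    clusters["cluster_id"] = [
        f"cl_{row.chrom}_{row.start}" for row in clusters.itertuples()
    ]
    return clusters[CLUSTER_COLUMNS]


def assign_reads(clusters: pd.DataFrame, reads: pd.DataFrame, strict: bool = True) -> pd.Series:
    """Map each read locus to the cluster containing its start position.

    With ``strict=True`` every locus must fall inside a cluster; a locus
    outside all clusters violates the clustering postcondition (clusters
    were built from the pooled loci) and raises.  With ``strict=False``
    loci outside the given clusters map to NA — the mode used when working
    with a subset of clusters, e.g. screening only the DE ones.
    """
    result = pd.Series(index=reads.index, dtype=object)
    for chrom, sub in reads.groupby("chrom", sort=False):
        cl = clusters[clusters["chrom"] == chrom].sort_values("start")
        if len(cl) == 0:
            if strict:
                raise ValueError(f"read loci on {chrom} outside every cluster")
            continue
        starts = cl["start"].to_numpy()
        ends = cl["end"].to_numpy()
        ids = cl["cluster_id"].to_numpy()
        pos = np.searchsorted(starts, sub["start"].to_numpy(), side="right") - 1
        ok = pos >= 0
        inside = ok.copy()
        inside[ok] = sub["start"].to_numpy()[ok] < ends[pos[ok]]
        if strict and not inside.all():
            raise ValueError(
                f"{int((~inside).sum())} read loci on {chrom} fall outside every cluster"
            )
        result.loc[sub.index[inside]] = ids[pos[inside]]
    return result


def weighted_counts(clusters: pd.DataFrame, reads: pd.DataFrame) -> ClusterCountMatrix:
    """Per-cluster, per-library weighted counts.

    Each locus of a sequence mapping to N genomic loci contributes
    abundance/N to its cluster, so a sequence's total abundance is conserved
    across the clusters holding its loci.
    """
    validate_reads(reads)
    if len(reads) == 0:
        raise ValueError("no reads to quantify")
    work = reads.copy()
    work["_cluster"] = assign_reads(clusters, work)
    work["_w"] = work["abundance"] / work["n_loci"]
    table = (
        work.pivot_table(
            index="_cluster", columns="library_id", values="_w", aggfunc="sum", fill_value=0.0
        )
        .reindex(clusters["cluster_id"], fill_value=0.0)
    )
    table.index.name = "cluster_id"
    table.columns.name = None
    return ClusterCountMatrix(values=table.astype(float), stage="raw_weighted")


def normalize_rpm(matrix: ClusterCountMatrix, design: pd.DataFrame) -> ClusterCountMatrix:
    """Scale raw weighted counts to reads per million mapped reads."""
    if matrix.stage != "raw_weighted":
        raise ValueError(f"expected raw_weighted matrix, got {matrix.stage}")
    validate_design(design)
    totals = design.set_index("library_id")["total_mapped_reads"]
    missing = [lib for lib in matrix.library_ids if lib not in totals.index]
    if missing:
        raise ValueError(f"libraries missing from design: {missing}")
    scale = 1e6 / totals.loc[matrix.library_ids].astype(float)
    return ClusterCountMatrix(values=matrix.values * scale, stage="rpm")


def average_tech_reps(matrix: ClusterCountMatrix, design: pd.DataFrame) -> ClusterCountMatrix:
    """Arithmetic mean of cluster counts over each sample's technical replicates."""
    if matrix.stage != "rpm":
        raise ValueError(f"expected rpm matrix, got {matrix.stage}")
    validate_design(design)
    design = design[design["library_id"].isin(matrix.library_ids)]
    cols = {}
    for (genotype, bio_rep), sub in design.groupby(["genotype", "bio_rep"], sort=True):
        libs = list(sub["library_id"])
        if len(libs) < sub["tech_rep"].nunique():
            warnings.warn(
                f"{genotype} bio_rep {bio_rep}: missing technical replicate, "
                f"averaging over {len(libs)} available",
                stacklevel=2,
            )
        cols[bio_sample_id(genotype, bio_rep)] = matrix.values[libs].mean(axis=1)
    return ClusterCountMatrix(values=pd.DataFrame(cols), stage="tech_averaged")


def filter_low_expression(
    matrix: ClusterCountMatrix, min_rpm: float = DEFAULT_MIN_RPM
) -> ClusterCountMatrix:
    """Drop clusters whose expression is below ``min_rpm`` in every sample.

    A cluster reaching exactly ``min_rpm`` in at least one sample is kept.
    Kept/removed totals are recorded in ``meta["filter_report"]``.
    """
    if matrix.stage != "tech_averaged":
        raise ValueError(f"expected tech_averaged matrix, got {matrix.stage}")
    keep = matrix.values.max(axis=1) >= min_rpm
    report = {
        "n_total": int(len(keep)),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "min_rpm": float(min_rpm),
    }
    logger.info(
        "expression filter: kept %d of %d clusters (removed %d below %.3g RPM)",
        report["n_kept"], report["n_total"], report["n_removed"], min_rpm,
    )
    return ClusterCountMatrix(
        values=matrix.values[keep], stage="filtered", meta={"filter_report": report}
    )


def quantify(
    clusters: pd.DataFrame,
    reads: pd.DataFrame,
    design: pd.DataFrame,
    min_rpm: float = DEFAULT_MIN_RPM,
) -> tuple[ClusterCountMatrix, ClusterCountMatrix]:
    """Full quantification chain.

    Returns ``(rpm_by_sample, filtered)`` where the first element is the
    technically-averaged RPM matrix for all clusters and the second the
    expression-filtered matrix differential analysis runs on.
    """
    raw = weighted_counts(clusters, reads)
    rpm = normalize_rpm(raw, design)
    averaged = average_tech_reps(rpm, design)
    return averaged, filter_low_expression(averaged, min_rpm=min_rpm)
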