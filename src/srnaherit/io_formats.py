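"""Readers and writers for every external file format.

All coordinates are converted at this boundary: GFF3 is 1-based inclusive on
disk, BED is 0-based half-open, and everything in memory is 0-based
half-open.

BED6 alignment dialect
----------------------
Aligned small-RNA reads travel as standard BED6 so files stay loadable in a
genome browser.  Per-sequence abundance and the genome-wide locus count N
ride in the name field::

    chrom  start  end  <seq_id>|<abundance>|<n_loci>  0  strand

One row is one mapping locus; a sequence mapping to N loci appears in N rows
sharing seq_id, abundance and n_loci.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    DESIGN_COLUMNS,
    FEATURE_KINDS,
    MAX_READ_LEN,
    MIN_READ_LEN,
    READ_COLUMNS,
    Feature,
    GenomeAnnotation,
    ClusterCountMatrix,
    validate_design,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 annotation into a validated :class:`GenomeAnnotation`.

    Chromosome lengths are taken from ``##sequence-region`` directives.
    Feature types outside the recognised vocabulary are skipped with a
    logged warning.  Coordinates are converted from 1-based inclusive to
    0-based half-open.
    """
    chromosomes: dict[str, int] = {}
    features: list[Feature] = []
    skipped: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) != 4:
                        raise ValueError(f"{path}:{lineno}: malformed sequence-region directive")
                    chromosomes[parts[1]] = int(parts[3])
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            chrom, _source, kind, start, end, _score, strand, _frame, attrs = cols
            if kind not in FEATURE_KINDS:
                skipped[kind] = skipped.get(kind, 0) + 1
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr_map = _parse_attributes(attrs, path, lineno)
            feature_id = attr_map.get("ID")
            if feature_id is None:
                raise ValueError(f"{path}:{lineno}: feature without ID attribute")
            features.append(
                Feature(
                    feature_id=feature_id,
                    kind=kind,
                    chrom=chrom,
                    start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                    end=end_i,
                    strand=strand,
                    parent_id=attr_map.get("Parent"),
                )
            )
    if skipped:
        logger.warning("read_gff(%s): skipped feature kinds %s", path, skipped)
    if not chromosomes:
        # fall back to feature extents when no directives are present
        for f in features:
            chromosomes[f.chrom] = max(chromosomes.get(f.chrom, 0), f.end)
    ann = GenomeAnnotation(chromosomes=chromosomes, features=features)
    ann.validate()
    return ann


def _parse_attributes(attrs: str, path, lineno: int) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"{path}:{lineno}: malformed attribute {item!r}")
        key, value = item.split("=", 1)
        out[key] = value
    return out


def write_gff(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write an annotation back out as GFF3 (inverse of :func:`read_gff`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for f in annotation.features:
            attrs = f"ID={f.feature_id}"
            if f.parent_id is not None:
                attrs += f";Parent={f.parent_id}"
            fh.write(
                f"{f.chrom}\tsrnaherit\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Alignments (BED6 dialect)
# ---------------------------------------------------------------------------

def read_alignments(
    path: str | Path,
    blocklist: frozenset[str] | set[str] = frozenset(),
    library_id: str | None = None,
) -> pd.DataFrame:
    """Read one library's mapped reads from the BED6 dialect.

    Reads whose seq_id is on ``blocklist`` (e.g. rRNA/tRNA sequences) are
    dropped.  Records outside the 16-31 nt size range are rejected with a
    warning reporting how many were discarded.  Duplicate (seq_id, locus)
    rows are an error because the per-sequence abundance would be ambiguous.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        bed = pd.read_csv(path, sep="\t", header=None, names=names, comment="#", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=names)
    if len(bed) == 0:
        return pd.DataFrame(columns=READ_COLUMNS)
    name_parts = bed["name"].str.split("|", expand=True)
    if name_parts.shape[1] != 3 or name_parts.isna().any().any():
        raise ValueError(f"{path}: name field must be 'seqid|abundance|nloci'")
    reads = pd.DataFrame(
        {
            "seq_id": name_parts[0],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
            "abundance": name_parts[1].astype(float),
            "n_loci": name_parts[2].astype(int),
        }
    )
    reads["length"] = reads["end"] - reads["start"]
    bad = ~reads["length"].between(MIN_READ_LEN, MAX_READ_LEN)
    if bad.any():
        warnings.warn(
            f"{path}: rejected {int(bad.sum())} reads outside the "
            f"{MIN_READ_LEN}-{MAX_READ_LEN} nt size range",
            stacklevel=2,
        )
        reads = reads[~bad]
    dup = reads.duplicated(subset=["seq_id", "chrom", "start", "strand"])
    if dup.any():
        raise ValueError(f"{path}: duplicate (seq_id, locus) rows (ambiguous abundance)")
    if blocklist:
        reads = reads[~reads["seq_id"].isin(blocklist)]
    reads = reads.reset_index(drop=True)
    reads["library_id"] = library_id if library_id is not None else Path(path).stem
    return reads[READ_COLUMNS]


def write_alignments(reads: pd.DataFrame, path: str | Path) -> None:
    """Write one library's reads back to the BED6 dialect."""
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"].astype(int),
            "end": reads["end"].astype(int),
            "name": reads["seq_id"].astype(str)
            + "|"
            + reads["abundance"].map(_num_str)
            + "|"
            + reads["n_loci"].astype(int).astype(str),
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def _num_str(x) -> str:
    # abundances are integral in practice; avoid "5.0" in BED names
    return str(int(x)) if float(x) == int(x) else repr(float(x))


# ---------------------------------------------------------------------------
# Design table, blocklist, GO map
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"library_id": str, "genotype": str})
    return validate_design(design[DESIGN_COLUMNS])


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design)[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_blocklist(path: str | Path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_blocklist(seq_ids, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(seq_ids):
            fh.write(f"{sid}\n")


def read_go_map(path: str | Path) -> pd.DataFrame:
    """TSV of gene_id, term_id and optional term_name."""
    go = pd.read_csv(path, sep="\t", dtype=str)
    if "term_name" not in go.columns:
        go["term_name"] = ""
    return go[["gene_id", "term_id", "term_name"]]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Cluster BED and count matrices
# ---------------------------------------------------------------------------

def write_clusters_bed(clusters: pd.DataFrame, path: str | Path) -> None:
    clusters[["chrom", "start", "end", "cluster_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_clusters_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "cluster_id"],
        dtype={"chrom": str, "cluster_id": str},
    )
    return df[["cluster_id", "chrom", "start", "end"]]


def write_count_matrix(matrix: ClusterCountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={matrix.stage}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="cluster_id")


def read_count_matrix(path: str | Path) -> ClusterCountMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# stage="):
            raise ValueError(f"{path}: missing '# stage=' header")
        stage = header.split("=", 1)[1]
        values = pd.read_csv(fh, sep="\t", index_col="cluster_id")
    values.index = values.index.astype(str)
    return ClusterCountMatrix(values=values, stage=stage)


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

def write_results(
    calls: pd.DataFrame,
    annotations: pd.DataFrame,
    path: str | Path,
    rpm: pd.DataFrame | None = None,
) -> None:
    """Join per-cluster inheritance calls and annotation calls into one TSV.

    Both frames must be indexed by cluster_id and cover the same clusters;
    orphan keys on either side are an error.  ``rpm`` optionally appends the
    per-sample expression columns.
    """
    only_calls = calls.index.difference(annotations.index)
    only_ann = annotations.index.difference(calls.index)
    if len(only_calls) or len(only_ann):
        raise ValueError(
            "mismatched cluster keys; only in calls: "
            f"{sorted(only_calls)[:5]}, only in annotations: {sorted(only_ann)[:5]}"
        )
    merged = calls.join(annotations)
    if rpm is not None:
        merged = merged.join(rpm.add_prefix("rpm_"))
    merged.to_csv(path, sep="\t", index_label="cluster_id")


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cluster_id")
    df.index = df.index.astype(str)
    return df
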