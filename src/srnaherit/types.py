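"""Core in-memory containers shared across the pipeline.

Coordinate convention: every interval held in memory is 0-based half-open
``[start, end)``.  Conversion to and from 1-based inclusive coordinates
(GFF3) happens only in :mod:`srnaherit.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Feature kinds recognised in annotations.  Anything else in a GFF file is
#: ignored with a warning.
FEATURE_KINDS = frozenset(
    {
        "gene",
        "transposable_element",
        "CDS",
        "intron",
        "five_prime_UTR",
        "three_prime_UTR",
    }
)

#: Genotype codes.  The first letter is the maternal parent, the second the
#: paternal parent; CC and LL are the inbred parents, CL and LC the
#: reciprocal F1 hybrids.
GENOTYPES = ("CC", "LL", "CL", "LC")

#: Acceptable small-RNA read lengths (nt), inclusive.
MIN_READ_LEN = 16
MAX_READ_LEN = 31

#: Columns of a read table.  One row is one mapping locus of one distinct
#: small-RNA sequence in one library; ``abundance`` is the raw read count of
#: that sequence in the library and ``n_loci`` the number of genomic loci the
#: sequence maps to (each locus carries the full abundance; quantification
#: divides by ``n_loci``).
READ_COLUMNS = [
    "seq_id",
    "chrom",
    "start",
    "end",
    "strand",
    "length",
    "abundance",
    "n_loci",
    "library_id",
]

#: Columns of a library design table.
DESIGN_COLUMNS = ["library_id", "genotype", "bio_rep", "tech_rep", "total_mapped_reads"]


@dataclass(frozen=True)
class Feature:
    """A genomic feature from the annotation."""

    feature_id: str
    kind: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a flat list of features.

    Subfeatures (CDS, intron, UTRs) point at their parent gene via
    ``parent_id``; validation checks containment.
    """

    chromosomes: dict[str, int]
    features: list[Feature] = field(default_factory=list)

    def validate(self) -> None:
        by_id = {f.feature_id: f for f in self.features}
        for f in self.features:
            if f.chrom not in self.chromosomes:
                raise ValueError(f"feature {f.feature_id}: unknown chromosome {f.chrom}")
            if f.end > self.chromosomes[f.chrom]:
                raise ValueError(
                    f"feature {f.feature_id}: end {f.end} beyond chromosome "
                    f"{f.chrom} length {self.chromosomes[f.chrom]}"
                )
            if f.parent_id is not None:
                parent = by_id.get(f.parent_id)
                if parent is None:
                    raise ValueError(
                        f"subfeature {f.feature_id}: parent {f.parent_id} not found"
                    )
                if not (parent.chrom == f.chrom and parent.start <= f.start and f.end <= parent.end):
                    raise ValueError(
                        f"subfeature {f.feature_id} not contained in parent {f.parent_id}"
                    )

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def genes(self) -> list[Feature]:
        return self.of_kind("gene")

    @property
    def transposable_elements(self) -> list[Feature]:
        return self.of_kind("transposable_element")


#: Processing stages of a cluster count matrix, in pipeline order.
STAGES = ("raw_weighted", "rpm", "tech_averaged", "filtered")


@dataclass
class ClusterCountMatrix:
    """Clusters x libraries matrix of weighted small-RNA counts.

    ``values`` is indexed by cluster id; columns are library ids up to the
    ``rpm`` stage and biological-sample ids (``"<genotype>_b<bio_rep>"``)
    from ``tech_averaged`` on.  ``stage`` records how far along the
    quantification pipeline the matrix is; ``meta`` carries stage reports
    such as filter bookkeeping.
    """

    values: pd.DataFrame
    stage: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("cluster counts must be non-negative")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.values.columns)


def validate_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Check the read-table invariants and return the frame unchanged."""
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table missing columns: {missing}")
    if len(reads) == 0:
        return reads
    if (reads["abundance"] <= 0).any():
        raise ValueError("read abundance must be positive")
    if (reads["n_loci"] < 1).any():
        raise ValueError("n_loci must be >= 1")
    bad_len = ~reads["length"].between(MIN_READ_LEN, MAX_READ_LEN)
    if bad_len.any():
        raise ValueError(
            f"{int(bad_len.sum())} reads outside the {MIN_READ_LEN}-{MAX_READ_LEN} nt range"
        )
    if not (reads["end"] - reads["start"] == reads["length"]).all():
        raise ValueError("read interval width must equal read length")
    return reads


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check the design-table invariants and return the frame unchanged."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    bad_gt = set(design["genotype"]) - set(GENOTYPES)
    if bad_gt:
        raise ValueError(f"unknown genotypes: {sorted(bad_gt)}")
    key = design[["genotype", "bio_rep", "tech_rep"]]
    if key.duplicated().any():
        raise ValueError("(genotype, bio_rep, tech_rep) must be unique")
    if design["library_id"].duplicated().any():
        raise ValueError("library_id must be unique")
    if (design["total_mapped_reads"] <= 0).any():
        raise ValueError("total_mapped_reads must be positive")
    return design


def bio_sample_id(genotype: str, bio_rep: int) -> str:
    """Column label used for a biological sample after technical averaging."""
    return f"{genotype}_b{bio_rep}"
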